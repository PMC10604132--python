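"""Shared helpers for randomized tree construction in tests."""


def random_binary_newick(rng, n):
    """Random binary topology over n leaves with branch lengths 0.1;
    returns (newick, leaf names)."""
    names = [f"L{i}" for i in range(n)]
    nodes = [f"{name}:0.1" for name in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):0.1")
    return f"({nodes[0]},{nodes[1]});", names
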