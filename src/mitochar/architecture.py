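"""Gene order, overlap/spacer detection and arrangement comparison on
circular genomes.

Intervals are 1-based inclusive; an interval with end < start wraps the
origin. Overlap motifs are reported in the H-strand frame regardless of the
member genes' strands, which keeps the report well-defined when the two
genes sit on opposite strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .genome_io import GeneFeature, MitoGenome, feature_length


@dataclass
class OverlapRecord:
    gene_a: str
    gene_b: str
    length: int
    motif: str | None = None  # H-strand frame; None when no sequence


@dataclass
class SpacerRecord:
    gene_a: str
    gene_b: str
    length: int
    start: int
    end: int


def _segments(f: GeneFeature, glen: int) -> list[tuple[int, int]]:
    """Closed 1-based segments of a (possibly origin-spanning) feature."""
    if f.end >= f.start:
        return [(f.start, f.end)]
    return [(f.start, glen), (1, f.end)]


def _positions(f: GeneFeature, glen: int) -> set[int]:
    out: set[int] = set()
    for s, e in _segments(f, glen):
        out.update(range(s, e + 1))
    return out


def gene_order(g: MitoGenome) -> list[tuple[str, str]]:
    """Features in coordinate order as (gene, strand) pairs."""
    seen: dict[tuple[str, int, int], None] = {}
    names = [f.name for f in g.features]
    for f in g.features:
        if names.count(f.name) > 1:
            dup = [x for x in g.features if x.name == f.name]
            if any(
                _positions(a, g.length) & _positions(b, g.length)
                for i, a in enumerate(dup)
                for b in dup[i + 1 :]
            ):
                raise ValueError(f"overlapping duplicate features named {f.name}")
    return [(f.name, f.strand) for f in g.features]


def find_overlaps(g: MitoGenome) -> list[OverlapRecord]:
    """All pairs of features whose intervals intersect (circular-aware).

    Touching features (end_a + 1 == start_b) do not overlap. Three-way
    overlaps are reported pairwise.
    """
    glen = g.length
    recs: list[OverlapRecord] = []
    feats = g.features
    pos_sets = [_positions(f, glen) for f in feats]
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            inter = pos_sets[i] & pos_sets[j]
            if not inter:
                continue
            motif = None
            if g.sequence is not None:
                # H-strand frame, contiguous on the circle
                ordered = _circular_sort(sorted(inter), glen)
                motif = "".join(g.sequence[p - 1] for p in ordered)
            recs.append(
                OverlapRecord(
                    gene_a=feats[i].name,
                    gene_b=feats[j].name,
                    length=len(inter),
                    motif=motif,
                )
            )
    return recs


def _circular_sort(positions: list[int], glen: int) -> list[int]:
    """Order a contiguous circular run of positions along the circle."""
    s = set(positions)
    if 1 in s and glen in s and len(s) < glen:
        # wraps the origin: start after the gap
        start = max(p for p in range(1, glen + 1) if p not in s) + 1
        return [(start - 1 + k) % glen + 1 for k in range(len(s))]
    return sorted(s)


def find_spacers(g: MitoGenome, min_len: int = 1) -> list[SpacerRecord]:
    """Maximal uncovered gaps between features, circular-aware."""
    glen = g.length
    covered = [False] * (glen + 1)  # 1-based
    for f in g.features:
        for s, e in _segments(f, glen):
            for p in range(s, e + 1):
                covered[p] = True
    gaps: list[tuple[int, int]] = []
    p = 1
    while p <= glen:
        if not covered[p]:
            q = p
            while q < glen and not covered[q + 1]:
                q += 1
            gaps.append((p, q))
            p = q + 1
        else:
            p += 1
    # merge a wrap-around gap
    if g.circular and len(gaps) >= 2 and gaps[0][0] == 1 and gaps[-1][1] == glen:
        first, last = gaps.pop(0), gaps.pop()
        gaps.append((last[0], first[1]))  # end < start encodes the wrap
    recs = []
    for s, e in gaps:
        length = (e - s + 1) if e >= s else (glen - s + 1) + e
        if length < min_len:
            continue
        before = s - 1 if s > 1 else glen
        after = e + 1 if e < glen else 1
        gene_a = _feature_ending_at(g, before)
        gene_b = _feature_starting_at(g, after)
        recs.append(SpacerRecord(gene_a=gene_a, gene_b=gene_b, length=length,
                                 start=s, end=e))
    return recs


def _feature_ending_at(g: MitoGenome, pos: int) -> str:
    cands = [f for f in g.features if pos in _positions(f, g.length)]
    for f in cands:
        if f.end == pos:
            return f.name
    return cands[0].name if cands else ""


def _feature_starting_at(g: MitoGenome, pos: int) -> str:
    cands = [f for f in g.features if pos in _positions(f, g.length)]
    for f in cands:
        if f.start == pos:
            return f.name
    return cands[0].name if cands else ""


def locate_control_region(g: MitoGenome, min_cr: int = 200) -> SpacerRecord:
    """The control region: an explicit CR feature if annotated, else the
    longest inter-gene spacer (>= min_cr bp). Warns when its flanks are not
    trnP/trnF, the canonical location in fish mitogenomes."""
    cr_feats = g.features_of("control_region")
    if cr_feats:
        f = cr_feats[0]
        others = [x for x in g.features if x is not f]
        prev = max(others, key=lambda x: (x.end <= f.start, x.end), default=None)
        nxt = min(others, key=lambda x: (x.start < f.end, x.start), default=None)
        return SpacerRecord(
            gene_a=prev.name if prev else "",
            gene_b=nxt.name if nxt else "",
            length=feature_length(f, g.length, g.circular),
            start=f.start,
            end=f.end,
        )
    spacers = [s for s in find_spacers(g) if s.length >= min_cr]
    if not spacers:
        raise ValueError("no control region candidate (no spacer >= "
                         f"{min_cr} bp)")
    best = max(spacers, key=lambda s: s.length)
    if {best.gene_a, best.gene_b} != {"trnP", "trnF"}:
        warnings.warn(
            f"control-region candidate flanked by {best.gene_a}/{best.gene_b}, "
            "not trnP/trnF"
        )
    return best


def _signed(order: list[tuple[str, str]]) -> list[tuple[str, int]]:
    return [(name, 1 if strand == "H" else -1) for name, strand in order]


def _adjacencies(signed: list[tuple[str, int]]) -> set[tuple]:
    """Signed circular adjacencies; (u,v) is equivalent to (-v,-u)."""
    adj = set()
    n = len(signed)
    for i in range(n):
        u, v = signed[i], signed[(i + 1) % n]
        adj.add((u, v))
    return adj


def _has_adjacency(adj: set, u, v) -> bool:
    if (u, v) in adj:
        return True
    ru = (u[0], -u[1])
    rv = (v[0], -v[1])
    return (rv, ru) in adj


def compare_orders(a: MitoGenome, b: MitoGenome) -> tuple[bool, int]:
    """(identical up to circular rotation, breakpoint count).

    Breakpoints = signed circular adjacencies of `a` absent from `b`.
    """
    sa, sb = _signed(gene_order(a)), _signed(gene_order(b))
    if {x[0] for x in sa} != {x[0] for x in sb}:
        diff = {x[0] for x in sa} ^ {x[0] for x in sb}
        raise ValueError(f"gene sets differ: {sorted(diff)}")
    identical = len(sa) == len(sb) and (
        len(sa) == 0 or _is_rotation(sa, sb)
    )
    adj_b = _adjacencies(sb)
    breakpoints = sum(
        0 if _has_adjacency(adj_b, sa[i], sa[(i + 1) % len(sa)]) else 1
        for i in range(len(sa))
    )
    return identical, breakpoints


def _is_rotation(x: list, y: list) -> bool:
    if len(x) != len(y):
        return False
    doubled = y + y
    return any(doubled[i : i + len(x)] == x for i in range(len(y)))
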