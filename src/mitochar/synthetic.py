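"""Synthetic mitogenomes and sequence evolution with known truth.

The generator emulates the structure of a holocentrid-style vertebrate
mitogenome: the canonical 37-gene arrangement (gene order, sizes, strands,
start/stop classes and inter-gene gaps are taken from the shipped
M. kuntee reference table), a configurable A+T content and strand skews,
the three conserved protein-gene overlaps with their motifs, a control
region carrying five seeded conserved sequence blocks, and a G-C-rich
stem-loop (light-strand replication origin) in the WANCY tRNA cluster.

Where the printed annotation and the printed atp8/atp6 overlap motif
conflict (the motif's first and last triplets are incompatible with the
annotated atp6 start and atp8 stop at the same coordinates), the start and
stop codons win; overlap lengths are always realized exactly.

Codon-level evolution is an MG94-style continuous-time simulation: the
rate of a single-nucleotide codon change is kappa-weighted for
transitions, multiplied by omega when nonsynonymous, and zero into stop
codons. Every substitution event is logged with its branch, site and
syn/nonsyn label, so counting machinery can be cross-validated against
the exact truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .genetics import (
    BASES,
    DEFAULT_CODE,
    is_synonymous,
    is_transition,
    reverse_complement,
    sense_codons,
    stop_codons,
)
from .genome_io import GeneFeature, MitoGenome, reference_feature_table
from .phylogeny import Node, Tree
from .selection import CodonAlignment

DEFAULT_OVERLAP_MOTIFS = {
    ("atp8", "atp6"): "AGCTTCTTCG",
    ("nad4l", "nad4"): "ATGCTAA",
    ("nad5", "nad6"): "CCTAA",
}

# Five control-region blocks with distinctive compositions (T/A-rich,
# AT+C, T/C-rich, C-rich at 70%, A/C-rich), 20 columns each.
DEFAULT_CSB_MOTIFS = (
    "TATTAATGTATTAAACTTAT",
    "ACCTACCCATAACTCCTAAC",
    "TTCCTTCTTACTCCTTTCGT",
    "CCCACCCCGCCTCCCACCTA",
    "ACAACCACAAACCCAAACCA",
)


@dataclass
class GenomeSpec:
    at_content: float = 0.547
    at_skew: float = 0.08
    gc_skew: float = -0.26
    cr_length: int = 862
    csb_motifs: tuple[str, ...] = DEFAULT_CSB_MOTIFS
    ol_stem_gc: int = 8
    ol_stem_len: int = 12
    ol_loop_len: int = 9
    overlap_motifs: dict = field(
        default_factory=lambda: dict(DEFAULT_OVERLAP_MOTIFS)
    )
    seed: int = 0
    code_id: int = DEFAULT_CODE

    @property
    def ol_length(self) -> int:
        return 2 * self.ol_stem_len + self.ol_loop_len


@dataclass
class EvolSpec:
    tree: Tree
    kappa: float = 4.0
    omega_per_site: float | list[float] = 1.0
    code_id: int = DEFAULT_CODE
    seed: int = 0
    frozen_sites: frozenset[int] = frozenset()  # 0-based codon sites


@dataclass
class Substitution:
    branch: str  # child-node label
    site: int    # 0-based codon site
    from_codon: str
    to_codon: str
    synonymous: bool


@dataclass
class EvolveResult:
    alignment: CodonAlignment
    log: list[Substitution]
    node_states: list[dict[int, str]]  # per site: id(node) -> codon
    tree: Tree


def _template() -> list[GeneFeature]:
    return reference_feature_table().features


def genome_layout(spec: GenomeSpec) -> list[GeneFeature]:
    """Template features with coordinates rebuilt so that the trnP-trnF
    gap equals cr_length and the trnN-trnC gap equals the hairpin length;
    all other gaps/overlaps match the reference table."""
    ref = _template()
    out: list[GeneFeature] = []
    pos = 1
    prev_end_ref = None
    for f in ref:
        if prev_end_ref is None:
            start = 1
        else:
            gap = f.start - prev_end_ref - 1
            if out[-1].name == "trnP" and f.name == "trnF":
                gap = spec.cr_length
            elif out[-1].name == "trnN" and f.name == "trnC":
                gap = spec.ol_length
            start = out[-1].end + gap + 1
        size = f.end - f.start + 1
        out.append(
            GeneFeature(
                name=f.name,
                category=f.category,
                start=start,
                end=start + size - 1,
                strand=f.strand,
                anticodon=f.anticodon,
                start_codon=f.start_codon,
                stop_codon=f.stop_codon,
            )
        )
        prev_end_ref = f.end
    return out


def _base_probs(spec: GenomeSpec) -> np.ndarray:
    at, gc = spec.at_content, 1.0 - spec.at_content
    return np.array(
        [
            at * (1 + spec.at_skew) / 2,   # A
            gc * (1 - spec.gc_skew) / 2,   # C
            gc * (1 + spec.gc_skew) / 2,   # G
            at * (1 - spec.at_skew) / 2,   # T
        ]
    )


def _sample_codon(rng, probs, stops) -> str:
    while True:
        c = "".join(rng.choice(list("ACGT"), size=3, p=probs))
        if c not in stops:
            return c


def _pcg_positions(f: GeneFeature) -> list[int]:
    return list(range(f.start, f.end + 1))


def _sense_codon_at(seq: list[str], f: GeneFeature, k: int) -> str:
    """k-th (0-based) sense codon of a PCG."""
    if f.strand == "H":
        s = f.start - 1 + 3 * k
        return "".join(seq[s : s + 3])
    e = f.end - 1 - 3 * k
    return reverse_complement("".join(seq[e - 2 : e + 1]))


def _write_sense_codon(seq: list[str], f: GeneFeature, k: int, codon: str):
    if f.strand == "H":
        s = f.start - 1 + 3 * k
        seq[s : s + 3] = list(codon)
    else:
        e = f.end - 1 - 3 * k
        seq[e - 2 : e + 1] = list(reverse_complement(codon))


def _sense_positions_of_codon(f: GeneFeature, k: int) -> list[int]:
    if f.strand == "H":
        s = f.start + 3 * k
        return [s, s + 1, s + 2]
    e = f.end - 3 * k
    return [e - 2, e - 1, e]


def make_genome(spec: GenomeSpec | None = None, id: str = "synthetic",
                species: str = "synthetic taxon") -> MitoGenome:
    """Generate a fully annotated synthetic mitogenome."""
    spec = spec or GenomeSpec()
    if any(
        len(m) != _overlap_len(pair, spec)
        for pair, m in spec.overlap_motifs.items()
        if _overlap_len(pair, spec) is not None
    ):
        raise ValueError("overlap motif length does not match planned overlap")
    rng = np.random.default_rng(spec.seed)
    feats = genome_layout(spec)
    L = max(f.end for f in feats)
    probs = _base_probs(spec)
    stops = stop_codons(spec.code_id)
    seq = list(rng.choice(list("ACGT"), size=L, p=probs))

    pcgs = [f for f in feats if f.category == "PCG"]
    # 1) protein-coding genes: start codon + sampled sense codons + stop/tail
    for f in pcgs:
        size = f.end - f.start + 1
        ncod = size // 3
        tail = size % 3
        # L-strand genes sample sense codons from complement-swapped
        # probabilities so the stored (heavy) strand keeps the genome-wide
        # composition; their sense strands then show the inverted skews
        # characteristic of light-strand genes such as nad6
        p = probs if f.strand == "H" else probs[::-1]
        for k in range(ncod):
            _write_sense_codon(seq, f, k, _sample_codon(rng, p, stops))
        _write_sense_codon(seq, f, 0, f.start_codon)
        if tail == 0:
            _write_sense_codon(seq, f, ncod - 1, f.stop_codon)
        # incomplete tail: set to T (polyadenylation-completed stop)
        if tail:
            if f.strand == "H":
                for t in range(tail):
                    seq[f.start - 1 + 3 * ncod + t] = "T"
            else:
                for t in range(tail):
                    seq[f.end - 1 - 3 * ncod - t] = "A"

    # 2) overlap motifs (H-strand frame), then re-enforce starts/stops
    by_name = {f.name: f for f in feats}
    locked: set[int] = set()
    for (a, b), motif in spec.overlap_motifs.items():
        fa, fb = by_name[a], by_name[b]
        lo, hi = max(fa.start, fb.start), min(fa.end, fb.end)
        if hi < lo:
            continue
        seq[lo - 1 : hi] = list(motif)
        locked.update(range(lo, hi + 1))
    for f in pcgs:
        size = f.end - f.start + 1
        ncod, tail = size // 3, size % 3
        _write_sense_codon(seq, f, 0, f.start_codon)
        locked.update(_sense_positions_of_codon(f, 0))
        if tail == 0:
            _write_sense_codon(seq, f, ncod - 1, f.stop_codon)
            locked.update(_sense_positions_of_codon(f, ncod - 1))
        else:
            if f.strand == "H":
                locked.update(range(f.start + 3 * ncod, f.end + 1))
            else:
                locked.update(range(f.start, f.end - 3 * ncod + 1))

    # 3) repair any internal stop created by motif/start/stop writes
    _repair_internal_stops(seq, pcgs, locked, stops)

    # 4) control region CSBs and the light-strand origin hairpin; their
    # placement uses a dedicated seeded stream so other modules can
    # recompute the coordinates without replaying genome construction
    ranges = _seeded_conserved_ranges(spec, by_name)
    for motif, (lo, hi) in zip(spec.csb_motifs, ranges):
        seq[lo - 1 : hi] = list(motif)
        locked.update(range(lo, hi + 1))
    ol_start = by_name["trnN"].end + 1
    hp = _build_hairpin(spec, rng)
    seq[ol_start - 1 : ol_start - 1 + len(hp)] = list(hp)
    locked.update(range(ol_start, ol_start + len(hp)))

    # 6) polish composition toward the targets
    _polish_composition(seq, spec, pcgs, locked, stops, rng)

    g = MitoGenome(
        id=id, species=species, sequence="".join(seq),
        features=[copy.deepcopy(f) for f in feats],
    )
    return g


def _overlap_len(pair: tuple[str, str], spec: GenomeSpec) -> int | None:
    feats = {f.name: f for f in genome_layout(spec)}
    if pair[0] not in feats or pair[1] not in feats:
        return None
    fa, fb = feats[pair[0]], feats[pair[1]]
    lo, hi = max(fa.start, fb.start), min(fa.end, fb.end)
    return hi - lo + 1 if hi >= lo else None


def _build_hairpin(spec: GenomeSpec, rng) -> str:
    stem, gc = spec.ol_stem_len, spec.ol_stem_gc
    if gc > stem:
        raise ValueError("ol_stem_gc exceeds stem length")
    arm = []
    gcpat = ["G", "C"]
    for k in range(stem):
        if k < gc:
            arm.append(gcpat[k % 2])
        else:
            arm.append("A")
    arm5 = "".join(arm)
    # loop: A/C only (T notably limited in these loops)
    loop = "".join(rng.choice(["A", "C"], size=spec.ol_loop_len, p=[0.7, 0.3]))
    return arm5 + loop + reverse_complement(arm5)


def _gene_of_position(pcgs, pos) -> list[GeneFeature]:
    return [f for f in pcgs if f.start <= pos <= f.end]


def _codon_index_of(f: GeneFeature, pos: int) -> int | None:
    size = f.end - f.start + 1
    ncod = size // 3
    k = (pos - f.start) // 3 if f.strand == "H" else (f.end - pos) // 3
    return k if k < ncod else None  # None: incomplete-tail base


def _repair_internal_stops(seq, pcgs, locked, stops):
    for f in pcgs:
        size = f.end - f.start + 1
        ncod = size // 3
        # the final complete codon is a stop only for complete-stop genes;
        # with an incomplete tail it is ordinary coding sequence
        last_coding = ncod - 1 if size % 3 == 0 else ncod
        for k in range(1, last_coding):
            codon = _sense_codon_at(seq, f, k)
            if codon not in stops:
                continue
            fixed = False
            for j, pos in enumerate(_sense_positions_of_codon(f, k)):
                if pos in locked:
                    continue
                for b in BASES:
                    cand = codon[:j] + b + codon[j + 1 :]
                    if cand not in stops:
                        _write_sense_codon(seq, f, k, cand)
                        fixed = True
                        break
                if fixed:
                    break


def _polish_composition(seq, spec, pcgs, locked, stops, rng, tol=0.001):
    L = len(seq)
    target = {b: spec_count for b, spec_count in zip(
        "ACGT", np.round(_base_probs(spec) * L).astype(int))}
    pcg_by_pos: dict[int, GeneFeature] = {}
    for f in pcgs:
        for p in range(f.start, f.end + 1):
            pcg_by_pos[p] = f
    counts = {b: 0 for b in "ACGT"}
    for b in seq:
        counts[b] += 1
    order = rng.permutation(L)
    for zero_idx in order:
        pos = int(zero_idx) + 1
        if pos in locked:
            continue
        b = seq[pos - 1]
        if counts[b] <= target[b]:
            continue
        deficit = [c for c in "ACGT" if counts[c] < target[c]]
        if not deficit:
            break
        done = False
        for c in sorted(deficit, key=lambda x: counts[x] - target[x]):
            f = pcg_by_pos.get(pos)
            if f is not None:
                k = _codon_index_of(f, pos)
                if k is None:
                    continue
                codon = _sense_codon_at(seq, f, k)
                jpos = _sense_positions_of_codon(f, k).index(pos)
                # genome positions ascend, but an L-strand sense codon
                # reads them in reverse complement
                j = jpos if f.strand == "H" else 2 - jpos
                nb = c if f.strand == "H" else reverse_complement(c)
                cand = codon[:j] + nb + codon[j + 1 :]
                if cand in stops:
                    continue
            seq[pos - 1] = c
            counts[b] -= 1
            counts[c] += 1
            done = True
            break
        if done and all(abs(counts[x] - target[x]) <= tol * L for x in "ACGT"):
            break


# --- evolution ----------------------------------------------------------


def _codon_neighbors(code_id: int):
    stops = stop_codons(code_id)
    out: dict[str, list[tuple[str, bool, bool]]] = {}
    for c in sense_codons(code_id):
        lst = []
        for pos in range(3):
            for b in BASES:
                if b == c[pos]:
                    continue
                alt = c[:pos] + b + c[pos + 1 :]
                if alt in stops:
                    continue
                lst.append(
                    (alt, is_transition(c[pos], b), is_synonymous(c, alt, code_id))
                )
        out[c] = lst
    return out


def label_nodes(tree: Tree) -> None:
    """Give unnamed internal nodes stable labels n0, n1, ... (preorder)."""
    k = 0
    for node in tree.root.walk():
        if node.name is None:
            node.name = f"n{k}"
            k += 1


def evolve(root_cds: list[str] | str, spec: EvolSpec) -> EvolveResult:
    """Simulate codon evolution along a tree; returns the leaf alignment,
    the exact substitution log and the true internal states."""
    if isinstance(root_cds, str):
        if len(root_cds) % 3:
            raise ValueError("root CDS length not a multiple of 3")
        root_codons = [root_cds[i : i + 3] for i in range(0, len(root_cds), 3)]
    else:
        root_codons = list(root_cds)
    stops = stop_codons(spec.code_id)
    for c in root_codons:
        if c in stops:
            raise ValueError(f"stop codon {c} in root sequence")
    n_sites = len(root_codons)
    omega = spec.omega_per_site
    omegas = (
        [float(omega)] * n_sites if np.isscalar(omega) else [float(w) for w in omega]
    )
    if len(omegas) != n_sites:
        raise ValueError("omega_per_site length mismatch")
    neighbors = _codon_neighbors(spec.code_id)
    # normalize so that at omega=1 the mean rate over sense codons is 1
    scale = np.mean(
        [
            sum(spec.kappa if ts else 1.0 for _, ts, _ in neighbors[c])
            for c in sense_codons(spec.code_id)
        ]
    )
    rng = np.random.default_rng(spec.seed)
    label_nodes(spec.tree)
    log: list[Substitution] = []
    node_states: list[dict[int, str]] = [dict() for _ in range(n_sites)]

    def sim_branch(state: str, t: float, site: int, branch: str) -> str:
        if site in spec.frozen_sites:
            return state
        w = omegas[site]
        elapsed = 0.0
        cur = state
        while True:
            moves = neighbors[cur]
            rates = [
                (spec.kappa if ts else 1.0) * (1.0 if syn else w) / scale
                for _, ts, syn in moves
            ]
            total = sum(rates)
            if total <= 0:
                return cur
            elapsed += rng.exponential(1.0 / total)
            if elapsed >= t:
                return cur
            r = rng.random() * total
            acc = 0.0
            for (alt, _, syn), rate in zip(moves, rates):
                acc += rate
                if r <= acc:
                    log.append(Substitution(branch, site, cur, alt, syn))
                    cur = alt
                    break

    def walk(node: Node, state_vec: list[str]):
        for s, st in enumerate(state_vec):
            node_states[s][id(node)] = st
        for child in node.children:
            child_vec = [
                sim_branch(st, child.length, s, child.name or "")
                for s, st in enumerate(state_vec)
            ]
            walk(child, child_vec)

    walk(spec.tree.root, root_codons)
    leaves = spec.tree.leaves()
    taxa = [lf.name for lf in leaves]
    cols = [
        [node_states[s][id(lf)] for lf in leaves] for s in range(n_sites)
    ]
    aln = CodonAlignment(taxa=taxa, codon_columns=cols)
    return EvolveResult(alignment=aln, log=log, node_states=node_states,
                        tree=spec.tree)


def evolve_nucleotides(
    root_seq: str,
    tree: Tree,
    rates: np.ndarray,
    kappa: float = 4.0,
    seed: int = 0,
) -> dict[str, str]:
    """Per-site nucleotide CTMC (K2P-style, uniform frequencies) along the
    tree; rates is a per-position multiplier (0 = frozen). Returns leaf
    sequences keyed by taxon."""
    rng = np.random.default_rng(seed)
    label_nodes(tree)
    idx = {b: i for i, b in enumerate(BASES)}
    # per-base rate rows under K2P with mean rate 1
    scale = kappa + 2.0
    out: dict[str, str] = {}

    def mutate(b: str, t: float, mult: float) -> str:
        if mult <= 0 or t <= 0:
            return b
        cur = b
        elapsed = 0.0
        while True:
            elapsed += rng.exponential(scale / (mult * (kappa + 2.0)))
            # total rate = mult * (kappa + 2)/scale = mult
            if elapsed >= t:
                return cur
            r = rng.random() * (kappa + 2.0)
            acc = 0.0
            for nb in BASES:
                if nb == cur:
                    continue
                acc += kappa if is_transition(cur, nb) else 1.0
                if r <= acc:
                    cur = nb
                    break

    def walk(node: Node, seqv: list[str]):
        if node.is_leaf():
            out[node.name] = "".join(seqv)
        for child in node.children:
            child_seq = [
                mutate(b, child.length, float(rates[i]))
                for i, b in enumerate(seqv)
            ]
            walk(child, child_seq)

    walk(tree.root, list(root_seq))
    return out


# --- study set ----------------------------------------------------------


@dataclass
class StudySet:
    genomes: dict[str, MitoGenome]
    tree: Tree
    clades: dict[str, list[str]]
    outgroup: list[str]
    gene_truth: dict[str, EvolveResult]
    spec: GenomeSpec


def _study_tree(n_ingroup: int, n_outgroup: int) -> tuple[Tree, dict, list]:
    if n_ingroup < 4:
        raise ValueError("need at least 4 ingroup taxa")
    nA = n_ingroup // 2
    nB = n_ingroup - nA
    genA1 = max(1, nA // 2)
    genB1 = max(1, nB // 2)
    cladeA = [f"Myr_{i+1}" for i in range(genA1)] + [
        f"Ost_{i+1}" for i in range(nA - genA1)
    ]
    cladeB = [f"Neo_{i+1}" for i in range(genB1)] + [
        f"Sar_{i+1}" for i in range(nB - genB1)
    ]
    outg = [f"Out_{i+1}" for i in range(n_outgroup)]

    def genus_clade(names: list[str], tip: float, stem: float) -> str:
        inner = ",".join(f"{n}:{tip}" for n in names)
        return f"({inner}):{stem}" if len(names) > 1 else f"{names[0]}:{tip+stem}"

    a1 = genus_clade(cladeA[:genA1], 0.04, 0.08)
    a2 = genus_clade(cladeA[genA1:], 0.04, 0.08)
    b1 = genus_clade(cladeB[:genB1], 0.04, 0.08)
    b2 = genus_clade(cladeB[genB1:], 0.04, 0.08)
    ing = f"(({a1},{a2}):0.15,({b1},{b2}):0.15):0.12"
    if n_outgroup == 0:
        newick = f"{ing};"
    else:
        og = ",".join(f"{n}:0.25" for n in outg)
        newick = f"({ing},{og});"
    tree = Tree.from_newick(newick)
    return tree, {"cladeA": cladeA, "cladeB": cladeB}, outg


def make_study_set(
    n_ingroup: int = 14,
    n_outgroup: int = 3,
    seed: int = 0,
    spec: GenomeSpec | None = None,
    kappa: float = 4.0,
    omega: float = 0.1,
    cr_rate: float = 3.0,
) -> StudySet:
    """Generate a set of related mitogenomes evolved on a known tree with
    two reciprocally monophyletic ingroup clades of two 'genera' each."""
    spec = spec or GenomeSpec(seed=seed)
    tree, clades, outg = _study_tree(n_ingroup, n_outgroup)
    label_nodes(tree)
    root = make_genome(spec, id="root")
    seq = root.sequence
    feats = root.features
    by_name = {f.name: f for f in feats}
    pcgs = [f for f in feats if f.category == "PCG"]
    rng = np.random.default_rng(seed)

    # evolve PCGs in codon space (start/stop and overlap codons frozen)
    overlap_ranges = []
    for (a, b) in spec.overlap_motifs:
        fa, fb = by_name[a], by_name[b]
        lo, hi = max(fa.start, fb.start), min(fa.end, fb.end)
        if hi >= lo:
            overlap_ranges.append((lo, hi))
    gene_truth: dict[str, EvolveResult] = {}
    seq_list = list(seq)
    for f in pcgs:
        size = f.end - f.start + 1
        ncod = size // 3
        codons = [_sense_codon_at(seq_list, f, k) for k in range(ncod)]
        # complete-stop genes: the final (stop) codon is not evolved and
        # stays at its root value; incomplete tails likewise
        sub_codons = codons[:-1] if size % 3 == 0 else codons
        frozen = {0}
        for k in range(len(sub_codons)):
            pos = _sense_positions_of_codon(f, k)
            if any(lo <= p <= hi for p in pos for lo, hi in overlap_ranges):
                frozen.add(k)
        es = EvolSpec(
            tree=tree,
            kappa=kappa,
            omega_per_site=omega,
            code_id=spec.code_id,
            seed=int(rng.integers(0, 2**31 - 1)),
            frozen_sites=frozenset(frozen),
        )
        gene_truth[f.name] = evolve(sub_codons, es)

    # evolve everything outside PCG spans at nucleotide level
    pcg_mask = np.zeros(len(seq), dtype=bool)
    for f in pcgs:
        pcg_mask[f.start - 1 : f.end] = True
    rates = np.ones(len(seq))
    rates[pcg_mask] = 0.0
    cr_start = by_name["trnP"].end + 1
    cr_end = by_name["trnF"].start - 1
    rates[cr_start - 1 : cr_end] = cr_rate
    # freeze seeded conserved blocks and the hairpin
    for lo, hi in _seeded_conserved_ranges(spec, by_name):
        rates[lo - 1 : hi] = 0.0
    nuc = evolve_nucleotides(seq, tree, rates, kappa=kappa,
                             seed=int(rng.integers(0, 2**31 - 1)))

    genomes: dict[str, MitoGenome] = {}
    taxa = [lf.name for lf in tree.leaves()]
    for t in taxa:
        arr = list(nuc[t])
        for f in pcgs:
            res = gene_truth[f.name]
            ti = res.alignment.taxa.index(t)
            for k in range(len(res.alignment.codon_columns)):
                _write_sense_codon(arr, f, k, res.alignment.codon_columns[k][ti])
        genomes[t] = MitoGenome(
            id=t, species=t, sequence="".join(arr),
            features=[copy.deepcopy(f) for f in feats],
        )
    return StudySet(
        genomes=genomes,
        tree=tree,
        clades=clades,
        outgroup=outg,
        gene_truth=gene_truth,
        spec=spec,
    )


def _seeded_conserved_ranges(spec: GenomeSpec, by_name) -> list[tuple[int, int]]:
    """CSB motif and hairpin coordinate ranges (recomputed from the spec's
    deterministic layout/seed, mirroring make_genome)."""
    rng = np.random.default_rng([spec.seed, 101])
    cr_start = by_name["trnP"].end + 1
    cr_end = by_name["trnF"].start - 1
    n_m = len(spec.csb_motifs)
    slot = (cr_end - cr_start + 1) // n_m
    ranges = []
    for i, motif in enumerate(spec.csb_motifs):
        lo = cr_start + i * slot
        jitter = int(rng.integers(0, max(1, slot - len(motif) - 1)))
        s = lo + jitter
        ranges.append((s, s + len(motif) - 1))
    ol_start = by_name["trnN"].end + 1
    ranges.append((ol_start, ol_start + spec.ol_length - 1))
    return ranges
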