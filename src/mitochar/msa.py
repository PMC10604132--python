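"""Global pairwise and progressive multiple alignment, block trimming and
supermatrix concatenation.

Scoring is affine: a gap of length k costs gap_open + k * gap_extend.
The dynamic program is a standard three-state Gotoh recursion with a fixed
traceback preference (diagonal, then vertical, then horizontal) so that
tied optima resolve identically on every run. Progressive alignment uses a
UPGMA guide tree on pairwise p-distances and merges profiles leaf-to-root
with the same DP on average-of-pairs column scores; input order never
changes the result because the guide tree is built over canonically sorted
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Alignment:
    taxa: list[str]
    rows: list[str]
    partition: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n")
                for i in range(0, len(r), 70):
                    fh.write(r[i : i + 70] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa=taxa, rows=rows)


@njit(cache=True)
def _gotoh(S, gap_open, gap_extend):
    """Affine-gap global DP on a precomputed column-similarity matrix.

    Returns (score, path) where path is an (L,2) array of 0-based column
    indices, -1 meaning a gap in that dimension. Traceback prefers the
    diagonal, then the vertical (gap in the second profile), then the
    horizontal move.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # a-column vs gap (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap vs b-column (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = best_prev + S[i - 1, j - 1]
            xo = M[i - 1, j] + gap_open + gap_extend
            xe = X[i - 1, j] + gap_extend
            yo_ = Y[i - 1, j] + gap_open + gap_extend
            X[i, j] = max(xo, xe, yo_)
            yo = M[i, j - 1] + gap_open + gap_extend
            ye = Y[i, j - 1] + gap_extend
            xo2 = X[i, j - 1] + gap_open + gap_extend
            Y[i, j] = max(yo, ye, xo2)
    # traceback
    i, j = n, m
    score = max(M[n, m], X[n, m], Y[n, m])
    if M[n, m] >= X[n, m] and M[n, m] >= Y[n, m]:
        state = 0
    elif X[n, m] >= Y[n, m]:
        state = 1
    else:
        state = 2
    path = np.empty((n + m, 2), dtype=np.int64)
    k = 0
    while (i > 0 or j > 0) and k < n + m:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            path[k, 0] = i - 1
            path[k, 1] = j - 1
            prev = M[i - 1, j - 1]
            px = X[i - 1, j - 1]
            py = Y[i - 1, j - 1]
            if prev >= px and prev >= py:
                state = 0
            elif px >= py:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            path[k, 0] = i - 1
            path[k, 1] = -1
            xo = M[i - 1, j] + gap_open + gap_extend
            xe = X[i - 1, j] + gap_extend
            yo_ = Y[i - 1, j] + gap_open + gap_extend
            if xo >= xe and xo >= yo_:
                state = 0
            elif xe >= yo_:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            path[k, 0] = -1
            path[k, 1] = j - 1
            yo = M[i, j - 1] + gap_open + gap_extend
            ye = Y[i, j - 1] + gap_extend
            xo2 = X[i, j - 1] + gap_open + gap_extend
            if yo >= ye and yo >= xo2:
                state = 0
            elif ye >= xo2:
                state = 2
            else:
                state = 1
            j -= 1
        k += 1
    return score, path[:k][::-1].copy()


def _profile_counts(rows: list[str]) -> np.ndarray:
    """(ncol, 4) base counts per column (gaps/N excluded)."""
    ncol = len(rows[0]) if rows else 0
    counts = np.zeros((ncol, 4), dtype=np.float64)
    for r in rows:
        for j, b in enumerate(r):
            k = _BASE_IDX.get(b, -1)
            if k >= 0:
                counts[j, k] += 1.0
    return counts


def _column_scores(rows_a, rows_b, match, mismatch) -> np.ndarray:
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    W = np.full((4, 4), float(mismatch))
    np.fill_diagonal(W, float(match))
    S = ca @ W @ cb.T
    return S / (len(rows_a) * len(rows_b))


def _apply_path(rows_a, rows_b, path) -> list[str]:
    out_a = ["".join(r[j] if j >= 0 else "-" for j, _ in path) for r in rows_a]
    out_b = ["".join(r[j] if j >= 0 else "-" for _, j in path) for r in rows_b]
    return out_a + out_b


def pairwise_align(
    a: str,
    b: str,
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -5,
    gap_extend: float = -1,
    taxa: tuple[str, str] = ("a", "b"),
) -> tuple[Alignment, float]:
    """Optimal global alignment of two sequences under affine gap costs."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    S = _column_scores([a], [b], match, mismatch)
    score, path = _gotoh(S, float(gap_open), float(gap_extend))
    rows = _apply_path([a], [b], path)
    return Alignment(taxa=list(taxa), rows=rows), float(score)


def _p_distance(r1: str, r2: str) -> float:
    pairs = [
        (x, y) for x, y in zip(r1, r2) if x in _BASE_IDX and y in _BASE_IDX
    ]
    if not pairs:
        return 1.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def progressive_align(
    seqs: dict[str, str],
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -5,
    gap_extend: float = -1,
) -> Alignment:
    """Progressive multiple alignment (UPGMA guide tree, profile merging)."""
    if len(seqs) != len(set(seqs)):
        raise ValueError("duplicate labels")
    labels = sorted(seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(labels)
    # guide distances from pairwise alignments
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            aln, _ = pairwise_align(
                seqs[labels[i]], seqs[labels[j]], match, mismatch, gap_open,
                gap_extend,
            )
            cond.append(_p_distance(aln.rows[0], aln.rows[1]))
    Z = linkage(np.asarray(cond), method="average")
    # merge leaf-to-root
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([labels[i]], [seqs[labels[i]]]) for i in range(n)
    }
    for k, (ia, ib, _, _) in enumerate(Z):
        ta, ra = clusters.pop(int(ia))
        tb, rb = clusters.pop(int(ib))
        S = _column_scores(ra, rb, match, mismatch)
        _, path = _gotoh(S, float(gap_open), float(gap_extend))
        merged = _apply_path(ra, rb, path)
        clusters[n + k] = (ta + tb, merged)
    taxa, rows = clusters.popitem()[1]
    order = sorted(range(len(taxa)), key=lambda i: taxa[i])
    return Alignment(taxa=[taxa[i] for i in order], rows=[rows[i] for i in order])


def trim_blocks(
    aln: Alignment,
    min_conserved_frac: float = 0.5,
    min_flank_frac: float = 0.85,
    max_contig_nonconserved: int = 8,
    min_block: int = 10,
    allow_gaps: str = "none",
) -> tuple[Alignment, list[int]]:
    """Remove ambiguously aligned columns, block-wise.

    Columns are conserved when the majority base reaches min_conserved_frac
    of the rows (flank-grade at min_flank_frac); with allow_gaps='none' any
    gap-containing column is nonconserved and is never retained. Runs of
    nonconserved columns longer than max_contig_nonconserved split blocks;
    blocks are trimmed to flank-grade ends and dropped below min_block.
    Returns the trimmed alignment and the retained original column indices
    (0-based, in order).
    """
    if min_block > aln.ncol:
        raise ValueError("min_block exceeds alignment length")
    nrow = len(aln.rows)
    grade = []  # 0 nonconserved, 1 conserved, 2 flank-grade
    for j in range(aln.ncol):
        col = [r[j] for r in aln.rows]
        gaps = sum(1 for b in col if b not in _BASE_IDX)
        if allow_gaps == "none" and gaps > 0:
            grade.append(0)
            continue
        from collections import Counter

        top = Counter(b for b in col if b in _BASE_IDX).most_common(1)
        frac = top[0][1] / nrow if top else 0.0
        if frac >= min_flank_frac:
            grade.append(2)
        elif frac >= min_conserved_frac:
            grade.append(1)
        else:
            grade.append(0)
    # split at long nonconserved runs, then trim to flank-grade ends
    kept: list[int] = []
    seg: list[int] = []
    run0 = 0
    segments = []
    for j in range(aln.ncol):
        if grade[j] == 0:
            run0 += 1
            if run0 > max_contig_nonconserved and seg:
                segments.append(seg)
                seg = []
        else:
            run0 = 0
            seg.append(j)
    if seg:
        segments.append(seg)
    for seg in segments:
        # segments may still contain interior nonconserved gaps shorter than
        # the cap only between retained columns; columns listed are all >=1
        while seg and grade[seg[0]] != 2:
            seg.pop(0)
        while seg and grade[seg[-1]] != 2:
            seg.pop()
        if len(seg) >= min_block:
            kept.extend(seg)
    if not kept:
        raise ValueError("no columns survive trimming")
    rows = ["".join(r[j] for j in kept) for r in aln.rows]
    return Alignment(taxa=list(aln.taxa), rows=rows), kept


def concatenate(alns: list[tuple[str, Alignment]]) -> Alignment:
    """Concatenate per-gene alignments into a partitioned supermatrix.

    Taxa missing from a gene get all-gap rows for that gene's columns.
    """
    if not alns:
        raise ValueError("no alignments to concatenate")
    all_taxa = sorted({t for _, a in alns for t in a.taxa})
    parts: list[tuple[str, int, int]] = []
    rows = {t: [] for t in all_taxa}
    pos = 0
    for gene, a in alns:
        for t in all_taxa:
            if t in a.taxa:
                rows[t].append(a.row(t))
            else:
                import warnings

                warnings.warn(f"taxon {t} missing gene {gene}; gap-filled")
                rows[t].append("-" * a.ncol)
        parts.append((gene, pos + 1, pos + a.ncol))
        pos += a.ncol
    return Alignment(
        taxa=all_taxa,
        rows=["".join(rows[t]) for t in all_taxa],
        partition=parts,
    )
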