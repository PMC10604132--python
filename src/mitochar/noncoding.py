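"""Control-region conserved sequence blocks (CSBs) and stem-loop search.

CSBs are called from an alignment of control regions by sliding-window
majority-base identity: a column's score is the frequency of its most
common base over ALL rows (gaps count against identity); a window qualifies
when its mean column score reaches the identity threshold and its gap
fraction stays below the cap. Qualifying windows are merged into blocks and
numbered CSB-I, CSB-II, ... in coordinate order.

The stem-loop (hairpin) finder enumerates inverted repeats; only exact
Watson-Crick pairs are counted toward the stem (G-U wobble ignored), and
hairpins are ranked by (G-C pairs, stem length) descending, matching how
replication-origin hairpins are described (G-C content of the stem is the
stability proxy).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .composition import CompositionStats, base_stats, round_half_up
from .genetics import reverse_complement

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
_PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass
class ConservedBlock:
    name: str
    aln_start: int  # 1-based inclusive alignment column
    aln_end: int
    mean_identity: float
    consensus: str
    composition: CompositionStats


@dataclass
class Hairpin:
    stem_len: int
    gc_pairs: int
    start: int      # 1-based position of the first arm base
    loop_start: int
    loop_end: int
    loop_seq: str
    arm5: str
    arm3: str

    def dot_bracket(self) -> str:
        return "(" * self.stem_len + "." * len(self.loop_seq) + ")" * self.stem_len


def column_identity(column: list[str]) -> float:
    """Majority-base frequency with a gap-inclusive denominator."""
    counts = Counter(b for b in column if b in "ACGT")
    if not counts:
        return 0.0
    return max(counts.values()) / len(column)


def detect_csbs(
    rows: list[str],
    window: int = 15,
    min_identity: float = 0.85,
    min_block: int = 12,
    max_gap_frac: float = 0.2,
) -> list[ConservedBlock]:
    """Call conserved blocks from aligned control-region sequences."""
    if len(rows) < 3:
        raise ValueError("CSB detection needs at least 3 aligned sequences")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("rows have unequal lengths")
    cols = [[r[j] for r in rows] for j in range(ncol)]
    ident = [column_identity(c) for c in cols]
    gapf = [sum(1 for b in c if b not in "ACGT") / len(c) for c in cols]
    keep = [False] * ncol
    for s in range(0, ncol - window + 1):
        w_ident = sum(ident[s : s + window]) / window
        w_gap = sum(gapf[s : s + window]) / window
        if w_ident >= min_identity and w_gap <= max_gap_frac:
            for j in range(s, s + window):
                keep[j] = True
    blocks: list[ConservedBlock] = []
    j = 0
    while j < ncol:
        if keep[j]:
            k = j
            while k + 1 < ncol and keep[k + 1]:
                k += 1
            nxt = k + 1
            # trim block ends to columns that individually meet the
            # threshold, so boundary windows cannot drag in flanking
            # low-identity columns
            while j <= k and ident[j] < min_identity:
                j += 1
            while k >= j and ident[k] < min_identity:
                k -= 1
            if k - j + 1 >= min_block:
                block_cols = cols[j : k + 1]
                consensus = "".join(
                    Counter(
                        b for b in c if b in "ACGT"
                    ).most_common(1)[0][0] if any(b in "ACGT" for b in c) else "-"
                    for c in block_cols
                )
                pooled = "".join(
                    b for c in block_cols for b in c if b in "ACGT"
                )
                blocks.append(
                    ConservedBlock(
                        name="",
                        aln_start=j + 1,
                        aln_end=k + 1,
                        mean_identity=sum(ident[j : k + 1]) / (k - j + 1),
                        consensus=consensus,
                        composition=base_stats(pooled),
                    )
                )
            j = nxt
        else:
            j += 1
    for i, b in enumerate(blocks):
        b.name = f"CSB-{_ROMAN[i] if i < len(_ROMAN) else str(i + 1)}"
    return blocks


def block_composition_table(blocks: list[ConservedBlock]) -> pd.DataFrame:
    """Per-block base composition in percent (pooled residues)."""
    rows = []
    for b in blocks:
        c = b.composition
        n = c.n_A + c.n_T + c.n_G + c.n_C
        rows.append(
            {
                "block": b.name,
                "A%": round_half_up(100 * c.n_A / n),
                "T%": round_half_up(100 * c.n_T / n),
                "G%": round_half_up(100 * c.n_G / n),
                "C%": round_half_up(100 * c.n_C / n),
            }
        )
    return pd.DataFrame(rows)


def _arm_mismatches(arm5: str, arm3: str) -> int:
    """Mismatched pairs between arm5 and arm3 read as its reverse."""
    return sum(1 for a, b in zip(arm5, arm3[::-1]) if _PAIR.get(a) != b)


def find_stem_loops(
    seq: str,
    min_stem: int = 5,
    loop_min: int = 3,
    loop_max: int = 20,
    max_mismatch: int = 0,
) -> list[Hairpin]:
    """All maximal hairpins (inverted repeats) in seq.

    A hairpin is maximal when its stem cannot be extended outward or inward
    by one more pair within the mismatch budget, the loop bounds and the
    sequence bounds. Exhaustive search; intended for short regions
    (replication-origin scale, |seq| <= a few hundred).
    """
    n = len(seq)
    found: list[Hairpin] = []
    for i in range(n):
        for stem in range(min_stem, (n - i) // 2 + 1):
            for loop in range(loop_min, loop_max + 1):
                end = i + 2 * stem + loop
                if end > n:
                    break
                arm5 = seq[i : i + stem]
                arm3 = seq[i + stem + loop : end]
                if _arm_mismatches(arm5, arm3) > max_mismatch:
                    continue
                if _extendable(seq, i, stem, loop, loop_min, max_mismatch):
                    continue
                gc = sum(
                    1
                    for a, b in zip(arm5, arm3[::-1])
                    if _PAIR.get(a) == b and a in "GC"
                )
                found.append(
                    Hairpin(
                        stem_len=stem,
                        gc_pairs=gc,
                        start=i + 1,
                        loop_start=i + stem + 1,
                        loop_end=i + stem + loop,
                        loop_seq=seq[i + stem : i + stem + loop],
                        arm5=arm5,
                        arm3=arm3,
                    )
                )
    found.sort(key=lambda h: (-h.gc_pairs, -h.stem_len, h.start))
    return found


def _extendable(seq: str, i: int, stem: int, loop: int, loop_min: int,
                max_mismatch: int) -> bool:
    """Can the stem grow outward (i-1) or inward (loop-2) and still satisfy
    the constraints?"""
    n = len(seq)
    # outward: add pair (i-1, i + 2*stem + loop)
    j = i + 2 * stem + loop
    if i >= 1 and j < n:
        arm5 = seq[i - 1 : i + stem]
        arm3 = seq[i + stem + loop : j + 1]
        if _arm_mismatches(arm5, arm3) <= max_mismatch:
            return True
    # inward: consume two loop bases
    if loop - 2 >= loop_min:
        arm5 = seq[i : i + stem + 1]
        arm3 = seq[i + stem + loop - 1 : i + 2 * stem + loop]
        if _arm_mismatches(arm5, arm3) <= max_mismatch:
            return True
    return False


def hairpin_table(hairpins: list[Hairpin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start": h.start,
                "stem_len": h.stem_len,
                "gc_pairs": h.gc_pairs,
                "loop": h.loop_seq,
                "arm5": h.arm5,
                "arm3": h.arm3,
                "dot_bracket": h.dot_bracket(),
            }
            for h in hairpins
        ]
    )


def verify_hairpin(h: Hairpin, max_mismatch: int = 0) -> bool:
    """Self-check: arm3 is the reverse complement of arm5 up to the allowed
    mismatches."""
    rc = reverse_complement(h.arm5)
    return sum(1 for a, b in zip(rc, h.arm3) if a != b) <= max_mismatch
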