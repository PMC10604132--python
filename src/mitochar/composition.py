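"""Base composition and strand-skew statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C), computed over
non-N bases. A skew whose denominator is zero is reported as None
(undefined), never as 0. Vertebrate mitogenomes typically show a positive
AT-skew and a negative GC-skew on the heavy strand; nad6, encoded on the
light strand, inverts the pattern when read on its own sense strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .genome_io import MitoGenome, extract_feature_sequence


@dataclass
class CompositionStats:
    n_A: int
    n_T: int
    n_G: int
    n_C: int
    at_percent: float
    gc_percent: float
    at_skew: float | None
    gc_skew: float | None


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (reporting convention for percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def base_stats(seq: str) -> CompositionStats:
    if not seq:
        raise ValueError("empty sequence")
    a, t, gg, c = seq.count("A"), seq.count("T"), seq.count("G"), seq.count("C")
    n = a + t + gg + c
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return CompositionStats(
        n_A=a,
        n_T=t,
        n_G=gg,
        n_C=c,
        at_percent=100.0 * (a + t) / n,
        gc_percent=100.0 * (gg + c) / n,
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(gg - c) / (gg + c) if gg + c else None,
    )


def _row(region: str, seq: str) -> dict:
    s = base_stats(seq)
    return {
        "region": region,
        "nA": s.n_A,
        "nT": s.n_T,
        "nG": s.n_G,
        "nC": s.n_C,
        "AT%": round_half_up(s.at_percent),
        "GC%": round_half_up(s.gc_percent),
        "AT-skew": s.at_skew,
        "GC-skew": s.gc_skew,
    }


def region_report(g: MitoGenome, sense_strand: bool = True) -> pd.DataFrame:
    """Composition table: whole genome, concatenated PCGs, each PCG,
    concatenated tRNAs, concatenated rRNAs, and the control region.

    Per-gene rows use the gene's sense (coding) strand by default; with
    sense_strand=False all slices are taken in the H-strand frame.
    """
    if g.sequence is None:
        raise ValueError("region_report requires a genome sequence")

    def seq_of(f):
        if sense_strand:
            return extract_feature_sequence(g, f)
        fw = f if f.strand == "H" else type(f)(
            name=f.name, category=f.category, start=f.start, end=f.end,
            strand="H",
            anticodon=f.anticodon if f.category == "tRNA" else None,
        )
        return extract_feature_sequence(g, fw)

    rows = [_row("genome", g.sequence)]
    for cat, label in [("PCG", "PCGs"), ("tRNA", "tRNAs"), ("rRNA", "rRNAs")]:
        feats = g.features_of(cat)
        if not feats:
            warnings.warn(f"no {cat} features; row omitted")
            continue
        rows.append(_row(label, "".join(seq_of(f) for f in feats)))
    for f in g.features_of("PCG"):
        rows.append(_row(f.name, seq_of(f)))
    cr = g.features_of("control_region")
    if cr:
        rows.append(_row("CR", seq_of(cr[0])))
    return pd.DataFrame(rows)
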