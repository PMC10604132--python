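"""Codon extraction, start/stop classification, codon counts and RSCU.

All operations default to the vertebrate mitochondrial code (NCBI table 2).
Mitochondrial CDSs frequently end in an incomplete stop (T or TA) that is
completed to TAA by polyadenylation; such tails are annotated but never
counted as codons.

RSCU for codon j of a synonymous family i with n_i members:
    RSCU_ij = X_ij * n_i / sum_j X_ij
so a uniformly used family has RSCU = 1 for every member and every nonzero
family satisfies sum RSCU = n_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genetics import (
    DEFAULT_CODE,
    sense_codons,
    stop_codons,
    synonymous_families,
    translate_codon,
)
from .genome_io import MitoGenome, extract_feature_sequence


@dataclass
class CdsCodons:
    gene: str
    codons: list[str]
    incomplete_tail: str
    start_codon: str
    stop_codon: str  # final complete stop codon, or the incomplete tail


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    rscu: dict[str, float] = field(default_factory=dict)
    code_id: int = DEFAULT_CODE
    total_triplets: int = 0          # sum of PCG lengths / 3 (reporting convention)
    total_complete_codons: int = 0   # complete non-stop codons actually counted


def split_codons(cds: str, gene: str = "", code_id: int = DEFAULT_CODE) -> CdsCodons:
    """Split a CDS into codons from position 1; a trailing 1-2 nt remainder
    becomes the incomplete tail (incomplete stop)."""
    if len(cds) < 6:
        raise ValueError(f"{gene or 'CDS'}: length {len(cds)} < 6")
    n = len(cds) - len(cds) % 3
    codons = [cds[i : i + 3] for i in range(0, n, 3)]
    tail = cds[n:]
    stops = stop_codons(code_id)
    for i, c in enumerate(codons[:-1]):
        if c in stops:
            warnings.warn(f"{gene or 'CDS'}: internal stop {c} at codon {i + 1}")
    stop = codons[-1] if not tail and codons[-1] in stops else tail
    return CdsCodons(
        gene=gene,
        codons=codons,
        incomplete_tail=tail,
        start_codon=codons[0],
        stop_codon=stop,
    )


def classify_start_stop(c: CdsCodons, code_id: int = DEFAULT_CODE) -> tuple[str, str]:
    start = c.start_codon if c.start_codon in ("ATG", "GTG") else "other"
    if c.incomplete_tail:
        stop = "incomplete"
    elif c.codons[-1] in stop_codons(code_id):
        stop = c.codons[-1]
    else:
        stop = "incomplete"
    return start, stop


def count_codons(cds_list: list[CdsCodons], code_id: int = DEFAULT_CODE
                 ) -> CodonUsageTable:
    """Pool codon counts over CDSs; stop codons and incomplete tails are
    excluded from the counts."""
    stops = stop_codons(code_id)
    counts: dict[str, int] = {c: 0 for c in sense_codons(code_id)}
    total_nt = 0
    complete = 0
    for cc in cds_list:
        total_nt += 3 * len(cc.codons) + len(cc.incomplete_tail)
        for codon in cc.codons:
            if codon in stops or "N" in codon:
                continue
            counts[codon] += 1
            complete += 1
    return CodonUsageTable(
        counts=counts,
        code_id=code_id,
        total_triplets=total_nt // 3,
        total_complete_codons=complete,
    )


def genome_codon_counts(g: MitoGenome, code_id: int = DEFAULT_CODE
                        ) -> CodonUsageTable:
    """Codon usage pooled over the sense strands of the 13 PCGs."""
    pcgs = g.features_of("PCG")
    if len(pcgs) < 13:
        warnings.warn(f"only {len(pcgs)} PCGs present; proceeding")
    cds_list = [
        split_codons(extract_feature_sequence(g, f), gene=f.name, code_id=code_id)
        for f in pcgs
    ]
    return count_codons(cds_list, code_id=code_id)


def rscu(t: CodonUsageTable) -> CodonUsageTable:
    """Fill the rscu map; zero-total families get RSCU 0 (flagged undefined
    by the zero family total)."""
    out = dict.fromkeys(t.counts, 0.0)
    for fam in synonymous_families(t.code_id).values():
        present = [c for c in fam if c in t.counts]
        total = sum(t.counts[c] for c in present)
        if total == 0:
            continue
        n_i = len(fam)
        for c in present:
            out[c] = t.counts[c] * n_i / total
    t.rscu = out
    return t


def amino_acid_usage(t: CodonUsageTable) -> pd.DataFrame:
    """Amino-acid counts/frequencies under the code; stops excluded."""
    rows: dict[str, int] = {}
    for codon, n in t.counts.items():
        aa = translate_codon(codon, t.code_id)
        if aa == "*":
            continue
        rows[aa] = rows.get(aa, 0) + n
    total = sum(rows.values())
    df = pd.DataFrame(
        [{"aa": aa, "count": n, "frequency": n / total if total else 0.0}
         for aa, n in rows.items()]
    )
    return df.sort_values("count", ascending=False).reset_index(drop=True)


def usage_table(t: CodonUsageTable) -> pd.DataFrame:
    """TSV-ready table: codon, amino acid, count, RSCU."""
    if not t.rscu:
        rscu(t)
    return pd.DataFrame(
        [
            {
                "codon": c,
                "aa": translate_codon(c, t.code_id),
                "count": t.counts[c],
                "RSCU": t.rscu.get(c, 0.0),
            }
            for c in sorted(t.counts)
        ]
    )
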