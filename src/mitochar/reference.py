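"""Published reference values for the holocentrid study system.

These quantities come from the real, deposited mitogenomes (accessions
OR148894-OR148901 plus six comparators) and from analyses of the full
14-genome alignment; they can only be recomputed after downloading those
sequences, so the package records them here for qualitative comparison in
reports and documentation. Nothing in the test suite asserts equality
against these numbers.
"""

ACCESSIONS_NEW = [f"OR1488{n}" for n in range(94, 102)]
ACCESSIONS_COMPARATORS = [
    "NC_063501.1",
    "KX254549.1",
    "NC_004395.1",
    "NC_063496.1",
    "AP002940.1",
    "AP004431.1",
]

REFERENCE_STUDY_VALUES = {
    "genome_length_bp": {"min": 16507, "max": 16639},
    "whole_genome_at_percent": {"min": 53.12, "max": 56.85},
    "rrna_at_percent_mkuntee": 53.93,
    "rrna_at_skew_mkuntee": 0.27,
    "rrna_gc_skew_mkuntee": -0.12,
    "most_used_codon": {"codon": "GCC", "rscu": 1.75},
    "control_region_length_bp": {"min": 838, "max": 960},
    "ol_length_bp": {"min": 28, "max": 37},
    "ol_stem_gc_pairs": {"Myripristis": 8, "other_genera": 7},
    "selection_site_totals": {
        "analyzed_sites": 3381,
        "dn_minus_ds_positive_ns": 378,
        "purifying_significant": 1784,
        "fel_omega_lt_1": 2459,
    },
}
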