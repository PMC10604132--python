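"""Conserved-block detection and stem-loop search, against brute-force
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitochar.genetics import reverse_complement
from mitochar.noncoding import (
    block_composition_table,
    column_identity,
    detect_csbs,
    find_stem_loops,
    verify_hairpin,
)

PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _oracle_csbs(rows, window=15, min_identity=0.85, min_block=12,
                 max_gap_frac=0.2):
    """Independent per-window scorer: returns kept (start, end) blocks."""
    ncol = len(rows[0])
    keep = np.zeros(ncol, dtype=bool)
    for s in range(ncol - window + 1):
        idents, gaps = [], []
        for j in range(s, s + window):
            col = [r[j] for r in rows]
            bases = [b for b in col if b in "ACGT"]
            idents.append(
                max((bases.count(b) for b in set(bases)), default=0) / len(col)
            )
            gaps.append((len(col) - len(bases)) / len(col))
        if np.mean(idents) >= min_identity and np.mean(gaps) <= max_gap_frac:
            keep[s : s + window] = True
    def col_ident(j):
        col = [r[j] for r in rows]
        bases = [b for b in col if b in "ACGT"]
        return max((bases.count(b) for b in set(bases)), default=0) / len(col)

    blocks = []
    j = 0
    while j < ncol:
        if keep[j]:
            k = j
            while k + 1 < ncol and keep[k + 1]:
                k += 1
            nxt = k + 1
            while j <= k and col_ident(j) < min_identity:
                j += 1
            while k >= j and col_ident(k) < min_identity:
                k -= 1
            if k - j + 1 >= min_block:
                blocks.append((j + 1, k + 1))
            j = nxt
        else:
            j += 1
    return blocks


def _oracle_hairpins(seq, min_stem=5, loop_min=3, loop_max=20, max_mismatch=0):
    """Exhaustive enumeration of maximal inverted repeats."""
    n = len(seq)

    def mism(i, stem, loop):
        a5 = seq[i : i + stem]
        a3 = seq[i + stem + loop : i + 2 * stem + loop]
        return sum(1 for x, y in zip(a5, a3[::-1]) if PAIR[x] != y)

    found = set()
    for i in range(n):
        for stem in range(min_stem, n):
            for loop in range(loop_min, loop_max + 1):
                if i + 2 * stem + loop > n:
                    continue
                if mism(i, stem, loop) > max_mismatch:
                    continue
                grow_out = (
                    i >= 1
                    and i + 2 * stem + loop + 1 <= n
                    and mism(i - 1, stem + 1, loop) <= max_mismatch
                )
                grow_in = (
                    loop - 2 >= loop_min
                    and mism(i, stem + 1, loop - 2) <= max_mismatch
                )
                if not grow_out and not grow_in:
                    found.add((i + 1, stem, loop))
    return found


class TestDetectCsbs:
    def test_identical_sequences_single_full_block(self):
        rows = ["ACGTTGCA" * 8] * 5
        blocks = detect_csbs(rows)
        assert len(blocks) == 1
        assert (blocks[0].aln_start, blocks[0].aln_end) == (1, 64)
        assert blocks[0].mean_identity == pytest.approx(1.0)
        assert blocks[0].name == "CSB-I"

    def test_embedded_invariant_motif_found(self):
        rng = np.random.default_rng(42)
        ncol, nrow = 120, 8
        # ~60% column identity background
        cols = []
        for _ in range(ncol):
            maj = rng.choice(list("ACGT"))
            cols.append([
                maj if rng.random() < 0.55 else rng.choice(list("ACGT"))
                for _ in range(nrow)
            ])
        motif = "ACGTTGCAACGTTGCAACGT"
        for k, b in enumerate(motif):
            for r in range(nrow):
                cols[50 + k][r] = b
        rows = ["".join(cols[j][r] for j in range(ncol)) for r in range(nrow)]
        blocks = detect_csbs(rows)
        assert len(blocks) == 1
        assert blocks[0].aln_start <= 51 and blocks[0].aln_end >= 70
        # agrees with the independent window scorer
        assert [(b.aln_start, b.aln_end) for b in blocks] == _oracle_csbs(rows)

    def test_no_conserved_columns_empty(self):
        rows = ["A" * 40, "C" * 40, "G" * 40, "T" * 40]
        assert detect_csbs(rows) == []

    def test_fewer_than_three_sequences_errors(self):
        with pytest.raises(ValueError):
            detect_csbs(["ACGT" * 10] * 2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_matches_oracle_on_random_alignments(self, seed):
        rng = np.random.default_rng(seed)
        nrow = int(rng.integers(3, 9))
        ncol = int(rng.integers(20, 120))
        rows = []
        anchor = "".join(rng.choice(list("ACGT"), size=ncol))
        for _ in range(nrow):
            rows.append("".join(
                anchor[j] if rng.random() < 0.8
                else rng.choice(list("ACGT-"))
                for j in range(ncol)
            ))
        got = [(b.aln_start, b.aln_end) for b in detect_csbs(rows)]
        assert got == _oracle_csbs(rows)


class TestBlockComposition:
    def test_simple_pooled_percentages(self):
        blocks = detect_csbs(["AATTCC" * 4] * 3, window=6, min_block=6)
        df = block_composition_table(blocks)
        assert df.loc[0, "A%"] == pytest.approx(33.33)
        assert df.loc[0, "G%"] == 0

    def test_all_a_block(self):
        blocks = detect_csbs(["A" * 30] * 3)
        df = block_composition_table(blocks)
        assert df.loc[0, "A%"] == 100

    def test_seeded_c_rich_csb_recovered(self, study_set):
        """The C-rich seeded block keeps ~70% C across the study set."""
        from mitochar.architecture import locate_control_region

        crs = []
        for g in study_set.genomes.values():
            cr = locate_control_region(g)
            crs.append(g.sequence[cr.start - 1 : cr.end])
        blocks = detect_csbs(crs)
        assert len(blocks) == 5
        df = block_composition_table(blocks).set_index("block")
        assert df.loc["CSB-IV", "C%"] == pytest.approx(70, abs=5)


class TestStemLoops:
    def test_canonical_example(self):
        hps = find_stem_loops("GGGGGAAAACCCCC")
        assert len(hps) == 1
        h = hps[0]
        assert (h.stem_len, h.gc_pairs, h.loop_seq) == (5, 5, "AAAA")
        assert h.dot_bracket() == "(((((....)))))"

    def test_no_hairpin_below_min_stem(self):
        assert find_stem_loops("ACACACACAC") == []

    def test_all_outputs_verify_revcomp_relation(self):
        rng = np.random.default_rng(3)
        s = "".join(rng.choice(list("ACGT"), size=80))
        for h in find_stem_loops(s, min_stem=4):
            assert verify_hairpin(h)
            assert h.arm3 == reverse_complement(h.arm5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30)
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 50))
        s = "".join(rng.choice(list("ACGT"), size=n, p=[0.3, 0.2, 0.2, 0.3]))
        got = {(h.start, h.stem_len, len(h.loop_seq))
               for h in find_stem_loops(s, min_stem=3)}
        assert got == _oracle_hairpins(s, min_stem=3)

    def test_synthetic_ol_top_hairpin_gc(self):
        from mitochar.synthetic import GenomeSpec, make_genome

        for gc in (7, 8):
            g = make_genome(GenomeSpec(seed=9, ol_stem_gc=gc))
            trnn, trnc = g.feature("trnN"), g.feature("trnC")
            region = g.sequence[trnn.end : trnc.start - 1]
            assert find_stem_loops(region)[0].gc_pairs == gc


def test_column_identity_counts_gaps_against():
    assert column_identity(list("AAAA")) == 1.0
    assert column_identity(list("AA--")) == 0.5
    assert column_identity(list("----")) == 0.0
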