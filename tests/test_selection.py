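"""Site counting, ancestral reconstruction, SLAC and FEL-lite."""

from itertools import product

import numpy as np
import pytest

from mitochar.genetics import (
    BASES,
    is_synonymous,
    sense_codons,
    stop_codons,
    translate_codon,
)
from mitochar.phylogeny import Tree
from mitochar.selection import (
    CodonAlignment,
    backtranslate,
    classify_summary,
    fel_lite,
    fitch_ancestral,
    ng_sites,
    pathway_counts,
    slac,
)
from mitochar.synthetic import EvolSpec, evolve

STOPS = stop_codons(2)


def _oracle_sites(codon):
    """Independent per-position enumeration of synonymous fractions."""
    S = N = 0.0
    for pos in range(3):
        syn = nonsyn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOPS:
                continue
            if translate_codon(alt) == translate_codon(codon):
                syn += 1
            else:
                nonsyn += 1
        if syn + nonsyn:
            S += syn / (syn + nonsyn)
            N += nonsyn / (syn + nonsyn)
    return S, N


class TestNgSites:
    def test_phe_example(self):
        assert ng_sites("TTT") == pytest.approx((1 / 3, 8 / 3))

    def test_fourfold_third_position_fully_synonymous(self):
        S, N = ng_sites("GCT")
        assert S >= 1.0  # third position contributes exactly 1

    def test_atg_first_two_positions_nonsynonymous(self):
        S, N = ng_sites("ATG")
        # no synonymous change at positions 1-2 (ATA is Met under code 2,
        # so position 3 does contribute)
        assert S == pytest.approx(_oracle_sites("ATG")[0])

    @pytest.mark.parametrize("codon", sense_codons(2))
    def test_all_sense_codons_match_enumeration(self, codon):
        assert ng_sites(codon) == pytest.approx(_oracle_sites(codon))

    def test_stop_or_gap_rejected(self):
        with pytest.raises(ValueError):
            ng_sites("TAA")
        with pytest.raises(ValueError):
            ng_sites("A-A")


class TestPathways:
    def test_single_step(self):
        assert pathway_counts("TTT", "TTC") == (1.0, 0.0)

    def test_two_step_average(self):
        # TTT->GTA: via GTT (nonsyn, then syn) or via TTA (nonsyn, nonsyn)
        assert pathway_counts("TTT", "GTA") == pytest.approx((0.5, 1.5))

    def test_total_equals_hamming_distance(self):
        rng = np.random.default_rng(2)
        codons = list(sense_codons(2))
        for _ in range(200):
            a, b = rng.choice(codons, size=2)
            s, n = pathway_counts(a, b)
            assert s + n == sum(1 for x, y in zip(a, b) if x != y)


def _brute_force_changes(tree, column):
    """Minimum substitution count over all internal codon assignments
    (restricted to observed states, which is sufficient for parsimony)."""
    observed = sorted({c for c in column.values() if "-" not in c})
    if not observed:
        return 0
    internals = [n for n in tree.root.walk() if not n.is_leaf()]
    best = None
    for combo in product(observed, repeat=len(internals)):
        asn = {id(n): s for n, s in zip(internals, combo)}
        for leaf in tree.leaves():
            c = column.get(leaf.name, "---")
            asn[id(leaf)] = None if "-" in c else c
        changes = 0
        for node in tree.root.walk():
            for ch in node.children:
                a, b = asn[id(node)], asn[id(ch)]
                if a is not None and b is not None and a != b:
                    changes += 1
        best = changes if best is None else min(best, changes)
    return best


class TestFitch:
    def test_invariant_column(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        asn, changes, _ = fitch_ancestral(t, dict.fromkeys("ABCD", "ATG"))
        assert changes == 0
        assert set(asn.values()) == {"ATG"}

    def test_single_internal_change(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        col = {"A": "TTT", "B": "TTT", "C": "TTC", "D": "TTC"}
        _, changes, _ = fitch_ancestral(t, col)
        assert changes == 1
        assert changes == _brute_force_changes(t, col)

    def test_missing_leaf_does_not_add_changes(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        col = {"A": "TTT", "B": "TTT", "C": "TTC", "D": "TTC"}
        col_missing = dict(col, D="---")
        _, c1, _ = fitch_ancestral(t, col)
        _, c2, _ = fitch_ancestral(t, col_missing)
        assert c1 == c2 == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_small_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        from tests_support_trees import random_binary_newick

        nwk, names = random_binary_newick(rng, n)
        t = Tree.from_newick(nwk)
        codons = ["TTT", "TTC", "TTA", "CTT", "ATT"]
        col = {name: str(rng.choice(codons)) for name in names}
        _, changes, _ = fitch_ancestral(t, col)
        assert changes == _brute_force_changes(t, col)


class TestSlac:
    def _tree(self):
        return Tree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")

    def test_invariant_alignment_all_neutral(self):
        aln = CodonAlignment(taxa=list("ABCD"),
                             codon_columns=[["ATG"] * 4, ["GCT"] * 4])
        res = slac(aln, self._tree())
        for r in res:
            assert r.OS == r.ON == 0
            assert r.classification == "neutral/ns"
            assert r.ES + r.EN == pytest.approx(3)

    def test_single_synonymous_change(self):
        aln = CodonAlignment(
            taxa=list("ABCD"),
            codon_columns=[["TTT", "TTT", "TTT", "TTC"]],
        )
        r = slac(aln, self._tree())[0]
        assert (r.OS, r.ON) == (1.0, 0.0)

    def test_taxa_mismatch_errors(self):
        aln = CodonAlignment(taxa=list("ABCE"), codon_columns=[["ATG"] * 4])
        with pytest.raises(ValueError):
            slac(aln, self._tree())

    def test_counts_reconcile_with_simulation_truth(self):
        """With the true tree and true ancestral states, endpoint counting
        reproduces the simulator's event log exactly wherever a branch-site
        carries at most one event, and OS+ON equals the codon Hamming
        distance everywhere."""
        tree = Tree.from_newick(
            "((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05,(E:0.05,F:0.05):0.05);"
        )
        rng = np.random.default_rng(8)
        codons = list(sense_codons(2))
        root = [codons[i] for i in rng.integers(0, 60, size=300)]
        res = evolve(root, EvolSpec(tree=tree, kappa=2.0, omega_per_site=0.5,
                                    seed=9))
        out = slac(res.alignment, tree, ancestral=res.node_states)
        # per-branch-site event census from the log
        events = {}
        for s in res.log:
            events.setdefault((s.branch, s.site), []).append(s)
        multi = {k for k, v in events.items() if len(v) > 1}
        multi_sites = {site for _, site in multi}
        log_syn = {}
        log_non = {}
        for (br, site), evs in events.items():
            log_syn[site] = log_syn.get(site, 0) + sum(e.synonymous for e in evs)
            log_non[site] = log_non.get(site, 0) + sum(
                not e.synonymous for e in evs)
        for r in out:
            site = r.site - 1
            if site in multi_sites:
                continue
            assert r.OS == pytest.approx(log_syn.get(site, 0))
            assert r.ON == pytest.approx(log_non.get(site, 0))
        # conservation holds for every site, multi-hit or not
        by_id = {}
        for node in tree.root.walk():
            for ch in node.children:
                by_id[id(ch)] = id(node)
        for r in out:
            states = res.node_states[r.site - 1]
            hamming = sum(
                sum(1 for x, y in zip(states[c], states[p]) if x != y)
                for c, p in by_id.items()
            )
            assert r.OS + r.ON == pytest.approx(hamming)

    def test_purifying_data_classified_purifying(self):
        tree = Tree.from_newick(
            "((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2,(E:0.3,F:0.3):0.2);"
        )
        rng = np.random.default_rng(10)
        codons = list(sense_codons(2))
        root = [codons[i] for i in rng.integers(0, 60, size=150)]
        res = evolve(root, EvolSpec(tree=tree, kappa=4.0, omega_per_site=0.05,
                                    seed=13))
        out = slac(res.alignment, tree)
        sig = [r for r in out if r.p_value < 0.05]
        assert sig
        assert all(r.dn_minus_ds < 0 for r in sig)


class TestBacktranslate:
    def test_gap_becomes_gap_codon(self):
        caln = backtranslate(["t1"], ["M-K"], {"t1": "ATGAAA"})
        assert caln.codon_columns == [["ATG"], ["---"], ["AAA"]]

    def test_translation_mismatch_errors(self):
        with pytest.raises(ValueError, match="t1"):
            backtranslate(["t1"], ["MK"], {"t1": "ATGCCC"})

    def test_terminal_stop_trimmed(self):
        caln = backtranslate(["t1"], ["MK"], {"t1": "ATGAAATAA"})
        assert caln.n_sites == 2

    def test_column_count_matches_protein_length(self, study_set):
        gene = study_set.gene_truth["atp8"]
        aln = gene.alignment
        taxa = aln.taxa
        prots = [
            "".join(translate_codon(aln.codon_columns[s][i])
                    for s in range(aln.n_sites))
            for i in range(len(taxa))
        ]
        cds = {
            t: "".join(aln.codon_columns[s][i] for s in range(aln.n_sites))
            for i, t in enumerate(taxa)
        }
        caln = backtranslate(taxa, prots, cds)
        assert caln.n_sites == len(prots[0])


class TestFelLite:
    def _small(self):
        tree = Tree.from_newick(
            "((A:0.15,B:0.15):0.1,(C:0.15,D:0.15):0.1,(E:0.15,F:0.15):0.1);"
        )
        return tree

    def test_invariant_site_not_significant(self):
        tree = self._small()
        aln = CodonAlignment(taxa=list("ABCDEF"),
                             codon_columns=[["GCT"] * 6])
        df = fel_lite(aln, tree)
        assert df.loc[0, "beta_rate"] < 1e-3
        assert df.loc[0, "p_value"] > 0.05

    def test_purifying_sites_give_beta_below_alpha(self):
        tree = Tree.from_newick(
            "((A:0.3,B:0.3):0.15,(C:0.3,D:0.3):0.15,((E:0.3,F:0.3):0.1,"
            "(G:0.3,H:0.3):0.1):0.05);"
        )
        rng = np.random.default_rng(14)
        codons = list(sense_codons(2))
        root = [codons[i] for i in rng.integers(0, 60, size=60)]
        res = evolve(root, EvolSpec(tree=tree, kappa=1.0, omega_per_site=0.2,
                                    seed=15))
        df = fel_lite(res.alignment, tree)
        ratio = df.beta_rate / np.maximum(df.alpha_rate, 1e-12)
        assert float(np.median(ratio)) < 1


def test_classify_summary():
    empty_counts, _ = classify_summary([])
    assert empty_counts == {"positive_sig": 0, "purifying_sig": 0, "other": 0}
    from mitochar.selection import SiteSelectionResult

    res = [
        SiteSelectionResult(site=i + 1, ES=1, EN=2, OS=3, ON=0, dN=0, dS=3,
                            dn_minus_ds=-3, p_value=0.01,
                            classification="purifying")
        for i in range(4)
    ]
    counts, per_gene = classify_summary(res, site_genes=["g1", "g1", "g2", "g2"])
    assert counts["purifying_sig"] == 4
    assert set(per_gene["gene"]) == {"g1", "g2"}
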