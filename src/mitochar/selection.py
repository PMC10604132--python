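"""Per-codon-site selection analysis.

Two per-site tests are provided:

* ``slac`` — a counting test in the Suzuki-Gojobori tradition: ancestral
  codons are reconstructed by Fitch parsimony over the 60 sense codons of
  the genetic code, observed substitutions along each branch are classified
  synonymous/nonsynonymous (multi-step codon changes averaged with equal
  weight over all shortest stop-free mutational pathways), expected site
  counts come from per-codon single-change enumeration, and significance
  from a two-tailed binomial test of the nonsynonymous count against its
  neutral expectation. The binomial test is an approximation to the
  extended counting-test procedure and is documented as such.

* ``fel_lite`` — a per-site likelihood-ratio test under a simplified
  MG94-style codon model with equal nucleotide exchangeabilities: the
  synonymous rate alpha and nonsynonymous rate beta are fit per site on a
  fixed tree, the null constrains beta = alpha, and the p-value is the
  chi-square(1) tail halved to account for the boundary.

Expected-site convention: at each codon position, single-nucleotide changes
that would create a stop codon are excluded from both numerator and
denominator (set ``stops_as_nonsyn=True`` in :func:`ng_sites` for the
alternative convention that counts them as nonsynonymous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import binom, chi2

from .genetics import (
    BASES,
    DEFAULT_CODE,
    is_synonymous,
    is_transition,
    sense_codons,
    stop_codons,
    translate_codon,
)
from .phylogeny import Node, Tree

GAP_CODON = "---"


@dataclass
class CodonAlignment:
    taxa: list[str]
    codon_columns: list[list[str]]  # [site][taxon]
    genes: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for col in self.codon_columns:
            if len(col) != len(self.taxa):
                raise ValueError("codon column width != number of taxa")

    @property
    def n_sites(self) -> int:
        return len(self.codon_columns)

    def site(self, i: int) -> dict[str, str]:
        return dict(zip(self.taxa, self.codon_columns[i]))

    @classmethod
    def from_nucleotide(cls, taxa: list[str], rows: list[str],
                        code_id: int = DEFAULT_CODE) -> "CodonAlignment":
        if any(len(r) % 3 for r in rows):
            raise ValueError("row length not a multiple of 3")
        stops = stop_codons(code_id)
        cols = []
        for i in range(0, len(rows[0]), 3):
            col = [r[i : i + 3] for r in rows]
            for t, c in zip(taxa, col):
                if c in stops and i + 3 < len(rows[0]):
                    raise ValueError(f"internal stop {c} in {t} at codon "
                                     f"{i // 3 + 1}")
            cols.append([c if "-" not in c else GAP_CODON for c in col])
        # terminal stop columns are trimmed, as in codon-aware aligners
        if cols and any(c in stops for c in cols[-1]):
            cols.pop()
        return cls(taxa=list(taxa), codon_columns=cols)


@dataclass
class SiteSelectionResult:
    site: int
    ES: float
    EN: float
    OS: float
    ON: float
    dN: float
    dS: float
    dn_minus_ds: float
    p_value: float
    classification: str  # positive | purifying | neutral/ns


def backtranslate(
    protein_aln_taxa: list[str],
    protein_rows: list[str],
    cds: dict[str, str],
    code_id: int = DEFAULT_CODE,
) -> CodonAlignment:
    """Map an aligned protein back onto its source codons.

    Each CDS must translate (under the code) to its ungapped protein row;
    a terminal stop (complete or incomplete) is trimmed first. Protein gaps
    become the gap codon '---'.
    """
    stops = stop_codons(code_id)
    codon_rows: dict[str, list[str]] = {}
    for taxon, prot in zip(protein_aln_taxa, protein_rows):
        seq = cds[taxon]
        seq = seq[: len(seq) - len(seq) % 3]  # drop incomplete tail
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in stops:
            codons.pop()
        ungapped = prot.replace("-", "")
        trans = "".join(translate_codon(c, code_id) for c in codons)
        if trans != ungapped:
            k = next(
                (i for i, (x, y) in enumerate(zip(trans, ungapped)) if x != y),
                min(len(trans), len(ungapped)),
            )
            raise ValueError(
                f"{taxon}: CDS translation differs from protein row at "
                f"position {k + 1}"
            )
        it = iter(codons)
        codon_rows[taxon] = [GAP_CODON if aa == "-" else next(it) for aa in prot]
    n_cols = len(protein_rows[0])
    cols = [[codon_rows[t][j] for t in protein_aln_taxa] for j in range(n_cols)]
    return CodonAlignment(taxa=list(protein_aln_taxa), codon_columns=cols)


@lru_cache(maxsize=None)
def ng_sites(codon: str, code_id: int = DEFAULT_CODE,
             stops_as_nonsyn: bool = False) -> tuple[float, float]:
    """Expected synonymous/nonsynonymous site counts (S, N) of one codon.

    Per position, the synonymous fraction of admissible single-nucleotide
    changes contributes to S and the remainder to N; changes to stop codons
    are excluded (or counted as nonsynonymous with stops_as_nonsyn=True).
    A position whose three changes all create stops contributes 0.
    """
    stops = stop_codons(code_id)
    if codon in stops or "-" in codon:
        raise ValueError(f"not a sense codon: {codon!r}")
    S = N = 0.0
    for pos in range(3):
        syn = nonsyn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in stops:
                if stops_as_nonsyn:
                    nonsyn += 1
                continue
            if is_synonymous(codon, alt, code_id):
                syn += 1
            else:
                nonsyn += 1
        tot = syn + nonsyn
        if tot:
            S += syn / tot
            N += nonsyn / tot
    return S, N


@lru_cache(maxsize=None)
def pathway_counts(a: str, b: str, code_id: int = DEFAULT_CODE
                   ) -> tuple[float, float]:
    """(syn, nonsyn) substitution counts for the codon change a -> b,
    averaged with equal weights over all shortest mutational pathways that
    avoid stop codons. Pathways through stops are discarded; if every
    pathway hits a stop, all are used (degenerate fallback, cannot occur
    for sense endpoints with <= 3 steps under code 2 in practice)."""
    stops = stop_codons(code_id)
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = a
        syn = nonsyn = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in stops:
                ok = False
                break
            if is_synonymous(cur, nxt, code_id):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            paths.append((syn, nonsyn))
    if not paths:
        return 0.0, float(len(diff))
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def fitch_ancestral(
    tree: Tree, column: dict[str, str], code_id: int = DEFAULT_CODE
) -> tuple[dict[int, str], int, int]:
    """Fitch parsimony over codon states on the (arbitrarily rooted) tree.

    Returns (assignment keyed by id(node), minimum change count, number of
    equally parsimonious resolution choices encountered). Leaves without a
    state (gap/missing) carry the full state set and receive no assignment
    constraint. Ambiguities resolve to the lexicographically smallest codon.
    """
    states = sense_codons(code_id)
    full = frozenset(states)
    sets: dict[int, frozenset] = {}
    changes = 0

    def down(node: Node) -> frozenset:
        nonlocal changes
        if node.is_leaf():
            c = column.get(node.name, GAP_CODON)
            s = full if c == GAP_CODON or "-" in c or "N" in c else frozenset([c])
            sets[id(node)] = s
            return s
        child_sets = [down(c) for c in node.children]
        # Hartigan-style vote count: exact minimum-change count on
        # arbitrary (also multifurcating) trees; reduces to Fitch on
        # binary nodes.
        union = frozenset.union(*child_sets)
        votes = {st: sum(1 for s in child_sets if st in s) for st in union}
        k_max = max(votes.values())
        winners = frozenset(st for st, v in votes.items() if v == k_max)
        changes += len(child_sets) - k_max
        sets[id(node)] = winners
        return winners

    down(tree.root)
    assignment: dict[int, str] = {}
    ambiguity = 0

    def up(node: Node, parent_state: str | None):
        nonlocal ambiguity
        s = sets[id(node)]
        if parent_state is not None and parent_state in s:
            choice = parent_state
        else:
            if len(s) > 1:
                ambiguity += 1
            choice = min(s)
        assignment[id(node)] = choice
        for c in node.children:
            up(c, choice)

    up(tree.root, None)
    return assignment, changes, ambiguity


def _branches(tree: Tree) -> list[tuple[Node, Node]]:
    out = []
    for node in tree.root.walk():
        for c in node.children:
            out.append((node, c))
    return out


def _binomial_two_tailed(on: float, n: int, p0: float) -> float:
    """Two-tailed binomial p for a (possibly fractional) observed count."""
    if n == 0:
        return 1.0
    lo = binom.cdf(np.floor(on), n, p0)
    hi = binom.sf(np.ceil(on) - 1, n, p0)
    return float(min(1.0, 2.0 * min(lo, hi)))


def slac(
    codon_aln: CodonAlignment,
    tree: Tree,
    alpha: float = 0.05,
    code_id: int = DEFAULT_CODE,
    ancestral: list[dict[int, str]] | None = None,
) -> list[SiteSelectionResult]:
    """Counting-based per-site selection test.

    ``ancestral`` optionally supplies known internal-node codons per site
    (keyed by id(node)), bypassing Fitch reconstruction — used to
    cross-validate the counting machinery against simulation truth.
    """
    if set(codon_aln.taxa) != set(tree.leaf_names()):
        raise ValueError("tree and alignment taxa differ")
    branches = _branches(tree)
    total_bl = sum(c.length for _, c in branches) or 1.0
    results = []
    for i in range(codon_aln.n_sites):
        column = codon_aln.site(i)
        if ancestral is not None:
            assignment = dict(ancestral[i])
            for leaf in tree.leaves():
                c = column.get(leaf.name, GAP_CODON)
                if "-" not in c:
                    assignment.setdefault(id(leaf), c)
        else:
            assignment, _, _ = fitch_ancestral(tree, column, code_id)
        OS = ON = 0.0
        ES = EN = 0.0
        wsum = 0.0
        for parent, child in branches:
            pa = assignment.get(id(parent))
            ch = assignment.get(id(child))
            if pa is None or ch is None:
                continue
            if child.is_leaf():
                c = column.get(child.name, GAP_CODON)
                if "-" in c:  # missing leaf: no observable change
                    continue
            s, n = pathway_counts(pa, ch, code_id)
            OS += s
            ON += n
            es_p, en_p = ng_sites(pa, code_id)
            es_c, en_c = ng_sites(ch, code_id)
            w = child.length
            ES += w * 0.5 * (es_p + es_c)
            EN += w * 0.5 * (en_p + en_c)
            wsum += w
        if wsum > 0:
            ES /= wsum
            EN /= wsum
        else:  # zero-length tree: plain average over nodes
            vals = [ng_sites(c, code_id) for c in assignment.values()]
            ES = sum(v[0] for v in vals) / len(vals)
            EN = sum(v[1] for v in vals) / len(vals)
        dS = OS / ES if ES > 0 else 0.0
        dN = ON / EN if EN > 0 else 0.0
        dnds = dN - dS
        ntot = int(round(OS + ON))
        p0 = EN / (ES + EN) if ES + EN > 0 else 0.5
        p = _binomial_two_tailed(ON, ntot, p0)
        if p < alpha and dnds > 0:
            cls_ = "positive"
        elif p < alpha and dnds < 0:
            cls_ = "purifying"
        else:
            cls_ = "neutral/ns"
        results.append(
            SiteSelectionResult(
                site=i + 1, ES=ES, EN=EN, OS=OS, ON=ON, dN=dN, dS=dS,
                dn_minus_ds=dnds, p_value=p, classification=cls_,
            )
        )
    return results


# --- FEL-lite -----------------------------------------------------------


@lru_cache(maxsize=None)
def _mg94_parts(code_id: int = DEFAULT_CODE) -> tuple:
    """Symmetric syn/nonsyn adjacency matrices over the sense codons."""
    codons = sense_codons(code_id)
    idx = {c: k for k, c in enumerate(codons)}
    n = len(codons)
    Smat = np.zeros((n, n))
    Nmat = np.zeros((n, n))
    for a in codons:
        for pos in range(3):
            for b in BASES:
                if b == a[pos]:
                    continue
                alt = a[:pos] + b + a[pos + 1 :]
                if alt not in idx:
                    continue
                tgt = Smat if is_synonymous(a, alt, code_id) else Nmat
                tgt[idx[a], idx[alt]] = 1.0
    return codons, idx, Smat, Nmat


def _site_loglik(
    alpha_rate: float,
    beta_rate: float,
    tree: Tree,
    leaf_states: dict[str, int | None],
    code_id: int = DEFAULT_CODE,
) -> float:
    codons, _, Smat, Nmat = _mg94_parts(code_id)
    n = len(codons)
    Q = alpha_rate * Smat + beta_rate * Nmat
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # Q is symmetric (uniform frequencies) -> orthogonal eigendecomposition
    w, U = np.linalg.eigh(Q)

    def prop(vec: np.ndarray, t: float) -> np.ndarray:
        return U @ (np.exp(w * t) * (U.T @ vec))

    def post(node: Node) -> np.ndarray:
        if node.is_leaf():
            v = np.zeros(n)
            s = leaf_states.get(node.name)
            if s is None:
                v[:] = 1.0
            else:
                v[s] = 1.0
            return v
        out = np.ones(n)
        for c in node.children:
            out *= prop(post(c), max(c.length, 1e-9))
        return out

    L = post(tree.root)
    lik = float(L.mean())  # uniform root frequencies
    return np.log(max(lik, 1e-300))


def fel_lite(
    codon_aln: CodonAlignment,
    tree: Tree,
    alpha: float = 0.05,
    code_id: int = DEFAULT_CODE,
) -> pd.DataFrame:
    """Per-site two-rate likelihood-ratio test (alpha_rate, beta_rate, p).

    Branch lengths are taken as fixed from the supplied tree. The null
    model ties beta (nonsynonymous rate) to alpha (synonymous rate); the
    p-value is chi-square(1) halved at the beta = alpha boundary.
    """
    codons, idx, _, _ = _mg94_parts(code_id)
    rows = []
    cache: dict[tuple, tuple] = {}
    for i in range(codon_aln.n_sites):
        col = codon_aln.codon_columns[i]
        key = tuple(col)
        if key in cache:
            a_hat, b_hat, p, conv = cache[key]
        else:
            leaf_states = {
                t: idx.get(c) for t, c in zip(codon_aln.taxa, col)
            }
            converged = True

            def nll_null(logr):
                r = np.exp(logr)
                return -_site_loglik(r, r, tree, leaf_states, code_id)

            res0 = minimize_scalar(nll_null, bounds=(-9.0, 4.0),
                                   method="bounded",
                                   options={"xatol": 1e-4})

            def nll_alt(x):
                lo, hi = -20.0, 6.0  # rates spanning e-20 .. e6 suffice
                a = float(np.exp(np.clip(x[0], lo, hi)))
                b = float(np.exp(np.clip(x[1], lo, hi)))
                return -_site_loglik(a, b, tree, leaf_states, code_id)

            res1 = minimize(
                nll_alt,
                x0=[res0.x, res0.x],
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-5, "maxiter": 200},
            )
            if not res1.success and res1.fun > res0.fun + 1e-6:
                converged = False
            # beta = alpha is an interior point of the two-rate space, so
            # the LRT null distribution is plain chi-square(1); halving is
            # only appropriate for boundary-constrained alternatives
            lrt = max(0.0, 2.0 * (res0.fun - res1.fun))
            p = float(chi2.sf(lrt, df=1))
            a_hat, b_hat = float(np.exp(res1.x[0])), float(np.exp(res1.x[1]))
            conv = converged
            cache[key] = (a_hat, b_hat, p, conv)
        rows.append(
            {
                "site": i + 1,
                "alpha_rate": a_hat,
                "beta_rate": b_hat,
                "p_value": p,
                "significant": p < alpha,
                "converged": conv,
            }
        )
    return pd.DataFrame(rows)


def classify_summary(
    results: list[SiteSelectionResult],
    alpha: float = 0.05,
    site_genes: list[str] | None = None,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Counts of significantly positive/purifying/other sites, overall and
    per gene when a site -> gene map is given."""
    counts = {"positive_sig": 0, "purifying_sig": 0, "other": 0}
    rows = []
    for k, r in enumerate(results):
        if r.p_value < alpha and r.dn_minus_ds > 0:
            cls_ = "positive_sig"
        elif r.p_value < alpha and r.dn_minus_ds < 0:
            cls_ = "purifying_sig"
        else:
            cls_ = "other"
        counts[cls_] += 1
        rows.append(
            {"gene": site_genes[k] if site_genes else "all", "class": cls_}
        )
    df = pd.DataFrame(rows)
    per_gene = (
        df.groupby(["gene", "class"]).size().unstack(fill_value=0).reset_index()
        if len(df)
        else pd.DataFrame()
    )
    if len(per_gene):
        for c in ("positive_sig", "purifying_sig", "other"):
            if c not in per_gene:
                per_gene[c] = 0
        tot = per_gene[["positive_sig", "purifying_sig", "other"]].sum(axis=1)
        per_gene["purifying_pct"] = 100.0 * per_gene["purifying_sig"] / tot
    return counts, per_gene
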