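"""Gene-set overrepresentation, kappa clustering and disease enrichment.

Fisher exact tests (one-sided overrepresentation for ontology/pathway runs,
two-sided for disease sets) with Benjamini-Hochberg adjustment within each
run; Cohen's kappa between term membership vectors to find redundant terms;
average-linkage hierarchical clustering on 1 - kappa with the reporting rule
that a term is shown only if no more-significant term overlaps it at
kappa >= 0.7 and it has fewer than 100 genes.

Hypergeometric probabilities are computed with exact integer arithmetic
(``math.comb``), so the two-sided convention — sum all tables whose
probability does not exceed the observed table's — is tie-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class TermGeneSets:
    """Flat term -> gene-set annotations over a background universe."""

    terms: dict                 # term id -> set of gene ids
    names: dict                 # term id -> display name
    universe: set

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        self.terms = {t: set(g) & self.universe for t, g in self.terms.items()}

    @classmethod
    def from_gmt(cls, path, universe=None) -> "TermGeneSets":
        terms, names = {}, {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            tid, name, *genes = line.rstrip("\n").split("\t")
            terms[tid] = set(genes)
            names[tid] = name
        if universe is None:
            universe = set().union(*terms.values()) if terms else set()
        return cls(terms, names, universe)

    def to_gmt(self, path) -> None:
        lines = [
            "\t".join([t, self.names.get(t, t), *sorted(genes)])
            for t, genes in sorted(self.terms.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int            # list ∩ term
    n: int            # list size
    K: int            # universe ∩ term
    N: int            # universe size
    fold: float
    log2_fold: float
    p_raw: float
    p_adjusted: float = float("nan")
    cluster_id: int = -1
    reported: bool = True


def hypergeom_pvalues(k: int, N: int, K: int, n: int) -> tuple:
    """(one-sided overrepresentation p, two-sided p) — exact rationals.

    One-sided: P(X >= k) for X ~ Hypergeom(N, K, n).  Two-sided: the sum of
    P(X = i) over all i whose probability is <= P(X = k); probabilities are
    compared as exact integer numerators, so ties are handled exactly.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("invalid hypergeometric parameters")
    lo, hi = max(0, n - (N - K)), min(n, K)
    if not lo <= k <= hi:
        raise ValueError("k outside the hypergeometric support")
    nums = [comb(K, i) * comb(N - K, n - i) for i in range(lo, hi + 1)]
    denom = comb(N, n)
    obs = nums[k - lo]
    p_one = sum(nums[k - lo:]) / denom
    p_two = sum(v for v in nums if v <= obs) / denom
    return float(p_one), float(min(p_two, 1.0))


def fisher_enrichment(gene_list, universe, term_sets: TermGeneSets,
                      sidedness: str = "one") -> list:
    """Exact-test overrepresentation of a gene list against every term.

    Genes outside the universe are intersected away; BH adjustment is applied
    across all tested terms of this run.  Fold enrichment is
    ``(k/n) / (K/N)``.
    """
    universe = set(universe)
    genes = set(gene_list) & universe
    if not genes or not universe:
        raise ValueError("gene list and universe must be nonempty")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    N, n = len(universe), len(genes)
    results = []
    for tid in sorted(term_sets.terms):
        members = term_sets.terms[tid] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(genes & members)
        p_one, p_two = hypergeom_pvalues(k, N, K, n)
        p = p_one if sidedness == "one" else p_two
        fold = (k / n) / (K / N)
        log2_fold = float(np.log2(fold)) if fold > 0 else float("-inf")
        results.append(EnrichmentResult(tid, term_sets.names.get(tid, tid),
                                        k, n, K, N, fold, log2_fold, p))
    if results:
        adjusted = multipletests([r.p_raw for r in results],
                                 method="fdr_bh")[1]
        for r, q in zip(results, adjusted):
            r.p_adjusted = float(q)
    return results


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]


def cohen_kappa(set_a, set_b, universe) -> float:
    """Chance-corrected agreement between two membership vectors.

    kappa = (P_o - P_e) / (1 - P_e) over the universe; undefined (NaN) when
    expected agreement is 1 (both sets equal to the whole universe or empty).
    """
    universe = set(universe)
    a = set_a & universe
    b = set_b & universe
    N = len(universe)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = N - n11 - n10 - n01
    p_o = (n11 + n00) / N
    pa = len(a) / N
    pb = len(b) / N
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_matrix(term_sets: TermGeneSets, term_ids=None) -> pd.DataFrame:
    """Symmetric kappa matrix between term membership vectors."""
    ids = sorted(term_sets.terms) if term_ids is None else list(term_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 terms")
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            kap = cohen_kappa(term_sets.terms[a], term_sets.terms[b],
                              term_sets.universe)
            mat.loc[a, b] = mat.loc[b, a] = kap
    return mat


def cluster_terms(results, kappa: pd.DataFrame, size_window: tuple = (5, 100),
                  report_kappa: float = 0.7, cut_kappa: float = 0.35) -> list:
    """Cluster redundant terms and mark which are reported.

    Terms outside the [min, max) gene-count window are excluded from
    clustering (and not reported).  Average-linkage clustering on 1 - kappa is
    cut at cophenetic distance 1 - ``cut_kappa``; within each cluster a term
    is reported iff no more-significant term (smaller raw p, ties broken
    lexicographically on term id) has kappa >= ``report_kappa`` with it.
    Cluster ids are assigned and the most significant member labels each
    cluster (exposed through its ``reported`` flag and ordering).
    """
    eligible = [r for r in results
                if size_window[0] <= r.K < size_window[1]]
    for r in results:
        r.reported = False
        r.cluster_id = -1
    if not eligible:
        return []
    ids = [r.term_id for r in eligible]
    if len(ids) == 1:
        eligible[0].cluster_id = 1
        eligible[0].reported = True
        return eligible
    sub = kappa.loc[ids, ids].to_numpy(dtype=float)
    dist = 1.0 - np.nan_to_num(sub, nan=-1.0)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    flat = fcluster(link, t=1.0 - cut_kappa, criterion="distance")
    order = {r.term_id: (r.p_raw, r.term_id) for r in eligible}
    for r, cid in zip(eligible, flat):
        r.cluster_id = int(cid)
    for r in eligible:
        suppressed = False
        for other in eligible:
            if other.term_id == r.term_id or other.cluster_id != r.cluster_id:
                continue
            if order[other.term_id] < order[r.term_id]:
                kap = kappa.loc[other.term_id, r.term_id]
                if np.isfinite(kap) and kap >= report_kappa:
                    suppressed = True
                    break
        r.reported = not suppressed
    eligible.sort(key=lambda r: (r.cluster_id, r.p_raw, r.term_id))
    return eligible


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "term_id": r.term_id, "term_name": r.term_name, "k": r.k, "n": r.n,
        "K": r.K, "N": r.N, "fold": r.fold, "log2_fold": r.log2_fold,
        "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
        "cluster_id": r.cluster_id, "reported": r.reported,
    } for r in results])
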