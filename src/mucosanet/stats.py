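"""Univariate group statistics for all omic layers.

Kruskal-Wallis (tie-corrected) with Benjamini-Hochberg adjustment is the
workhorse test for feature-by-feature contrasts across the three inflammation
groups (or the two Lactobacillus-dominance groups); Dunn's post hoc resolves
which pairs differ; fixed-margin Monte-Carlo Fisher tests handle categorical
demographics; hypergeometric over-representation provides pathway enrichment
for differential host-protein sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis outcome for one feature."""

    feature: str
    H: float
    df: int
    p: float
    p_adj: float | None = None


@dataclass(frozen=True)
class DunnResult:
    """One pairwise Dunn post-hoc comparison."""

    feature: str
    pair: tuple[str, str]
    z: float
    p: float
    p_adj: float


def _clean_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes == 0).any():
        raise ValueError("a group is empty after NA removal")
    return values, codes, labels, sizes


def _tie_term(ranks: np.ndarray) -> float:
    """Sum of t^3 - t over tied groups of the pooled midranks."""
    _, counts = np.unique(ranks, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def kruskal_wallis(values, groups, feature: str = "") -> KWResult:
    """Tie-corrected Kruskal-Wallis H test.

    Midranks over the pooled sample; H = [12/(N(N+1)) * sum R_g^2/n_g] - 3(N+1),
    divided by the tie-correction factor 1 - sum(t^3 - t)/(N^3 - N); the
    p-value is the upper chi-square tail with k-1 degrees of freedom. When all
    pooled values are identical the statistic is 0 with p = 1 (not an error).
    """
    values, codes, labels, sizes = _clean_groups(values, groups)
    N = len(values)
    k = len(labels)
    ranks = sps.rankdata(values)
    R = np.bincount(codes, weights=ranks)
    H = 12.0 / (N * (N + 1)) * float((R**2 / sizes).sum()) - 3.0 * (N + 1)
    tie = _tie_term(ranks)
    correction = 1.0 - tie / (N**3 - N)
    if correction == 0.0:  # all values identical
        return KWResult(feature, 0.0, k - 1, 1.0)
    H /= correction
    H = max(H, 0.0)
    p = float(sps.chi2.sf(H, k - 1))
    return KWResult(feature, float(H), k - 1, p)


def kruskal_wallis_table(values: pd.DataFrame, groups) -> pd.DataFrame:
    """Kruskal-Wallis per feature (column) with BH adjustment across features.

    Returns a frame indexed by feature with columns H, df, p, p_adj and
    per-group medians.
    """
    groups = pd.Series(np.asarray(groups), index=values.index)
    results = [kruskal_wallis(values[c], groups, feature=c) for c in values.columns]
    p_adj = benjamini_hochberg([r.p for r in results])
    out = pd.DataFrame(
        {
            "H": [r.H for r in results],
            "df": [r.df for r in results],
            "p": [r.p for r in results],
            "p_adj": p_adj,
        },
        index=pd.Index(values.columns, name="feature"),
    )
    medians = values.groupby(groups.to_numpy()).median().T
    medians.columns = [f"median_{g}" for g in medians.columns]
    return out.join(medians)


def dunn_posthoc(values, groups, adjust: str = "sidak", feature: str = "") -> list[DunnResult]:
    """Dunn's post-hoc pairwise comparisons after Kruskal-Wallis.

    For groups a, b the statistic is
    z = (Rbar_a - Rbar_b) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_a + 1/n_b)]
    with T the tie term sum(t^3 - t); two-sided normal p-values are adjusted
    across the k(k-1)/2 pairs by ``adjust`` in {"none", "sidak", "bonferroni",
    "bh"} ("sidak" is the Dunn-Sidak-family joint adjustment).
    """
    if adjust not in ("none", "sidak", "bonferroni", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    values, codes, labels, sizes = _clean_groups(values, groups)
    N = len(values)
    ranks = sps.rankdata(values)
    mean_ranks = np.bincount(codes, weights=ranks) / sizes
    tie = _tie_term(ranks)
    base_var = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    zs, ps = [], []
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        zs.append(z)
        ps.append(float(2.0 * sps.norm.sf(abs(z))))
    m = len(pairs)
    if adjust == "none":
        p_adj = ps
    elif adjust == "bonferroni":
        p_adj = [min(1.0, p * m) for p in ps]
    elif adjust == "sidak":
        p_adj = [float(1.0 - (1.0 - p) ** m) for p in ps]
    else:
        p_adj = list(benjamini_hochberg(ps))
    return [
        DunnResult(feature, (str(labels[i]), str(labels[j])), float(z), p, float(pa))
        for (i, j), z, p, pa in zip(pairs, zs, ps, p_adj)
    ]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log_table_probability(table: np.ndarray) -> float:
    """Log probability of an r x c table under fixed margins (Fisher's null)."""
    from scipy.special import gammaln

    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_monte_carlo(table, iterations: int = 2000, seed: int | None = None) -> float:
    """Monte-Carlo Fisher exact test for an r x c contingency table.

    Tables with the observed margins are simulated by Patefield sampling; the
    p-value is the +1/+1 estimator (1 + #{simulated at most as probable as
    observed}) / (iterations + 1), which never returns exactly 0.
    """
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValueError("contingency counts must be non-negative integers")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("degenerate margins: a row or column sums to zero")
    rng = np.random.default_rng(seed)
    sampler = sps.random_table(rows, cols, seed=rng)
    sims = sampler.rvs(iterations, method="patefield")
    logp_obs = _log_table_probability(table)
    logp_sim = np.array([_log_table_probability(s) for s in sims])
    hits = int((logp_sim <= logp_obs + 1e-9).sum())
    return (1 + hits) / (iterations + 1)


def hypergeometric_ora(
    hit_set, universe, annotation: dict[str, set]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation analysis.

    For each pathway with member set K (intersected with the universe of
    tested features), the p-value is the upper tail
    P(X >= |hits ∩ K|) with X ~ Hypergeom(M=|universe|, n=|K|, N=|hits|);
    BH adjustment is applied across pathways. Returns a frame indexed by
    pathway with columns overlap, pathway_size, p, p_adj.
    """
    universe = set(universe)
    hits = set(hit_set)
    if not hits:
        raise ValueError("empty hit set")
    if not hits <= universe:
        raise ValueError("hit set must be a subset of the universe")
    M, N = len(universe), len(hits)
    rows = []
    for pathway, members in annotation.items():
        K = set(members) & universe
        overlap = len(hits & K)
        p = float(sps.hypergeom.sf(overlap - 1, M, len(K), N)) if K else 1.0
        rows.append((pathway, overlap, len(K), min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["pathway", "overlap", "pathway_size", "p"]
    ).set_index("pathway")
    out["p_adj"] = benjamini_hochberg(out["p"]) if len(out) else []
    return out
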