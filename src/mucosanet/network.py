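"""Discrete Bayesian-network consensus over multi-omic features.

The inference stack mirrors the analysis design it implements: each omic
layer is screened to its top-5 features by random-forest Gini importance
against the 3-level inflammation label; all continuous features are
discretized above/below the cohort median; structures over the pooled
features (plus the inflammation variable) are learned by greedy hill
climbing under the likelihood-equivalent Bayesian Dirichlet (BDeu) score
with random restarts; participant-level bootstrap resampling yields
undirected arc strengths (the fraction of bootstrap networks containing an
edge between a pair in either direction); and the consensus network keeps
pairs whose strength clears a threshold estimated by minimizing the L1
distance between the empirical strength CDF and an ideal noiseless step CDF.

Edges of the consensus are read without directionality: the model is a
hypothesis-generating map of statistical dependence, not a causal diagram.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.ensemble import RandomForestClassifier

from .grouping import InflammationAssignment, assignments_to_frame
from .tables import OmicLayerTable

log = logging.getLogger(__name__)

INFLAMMATION_VARIABLE = "inflammation"
INFLAMMATION_LEVELS = ("low", "medium", "high")

_EPS = 1e-10  # minimum score gain counted as an improvement


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class DiscreteMatrix:
    """Complete-case discrete data: participants x variables, integer codes.

    ``arities`` gives the number of states per variable (2 for median-split
    features, 3 for the inflammation level); ``layer_of`` tags each variable
    with its source omic layer.
    """

    data: pd.DataFrame
    arities: pd.Series
    layer_of: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("discrete matrix must be complete-case (no missing entries)")
        self.data = self.data.astype(np.int64)
        self.arities = self.arities.reindex(self.data.columns).astype(int)
        if self.arities.isna().any():
            raise ValueError("every variable needs an arity")
        for v in self.data.columns:
            col = self.data[v]
            if col.min() < 0 or col.max() >= self.arities[v]:
                raise ValueError(f"variable {v!r}: codes outside [0, arity)")
        if self.layer_of is not None:
            self.layer_of = self.layer_of.reindex(self.data.columns)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def resample(self, rng: np.random.Generator, max_retries: int = 100) -> "DiscreteMatrix":
        """Bootstrap resample of participants (with replacement, same n).

        Resamples in which some variable collapses to a single observed level
        are redrawn, up to ``max_retries`` times.
        """
        n = self.n
        arr = self.data.to_numpy()
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            sub = arr[idx]
            if all(len(np.unique(sub[:, j])) > 1 for j in range(sub.shape[1])):
                df = pd.DataFrame(sub, columns=self.data.columns,
                                  index=pd.RangeIndex(n))
                return DiscreteMatrix(df, self.arities, self.layer_of)
        raise RuntimeError(
            f"could not draw a non-degenerate bootstrap resample in {max_retries} tries"
        )


@dataclass(frozen=True)
class DagStructure:
    """A directed acyclic graph over named variables."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r}")
            if u not in nodeset or v not in nodeset:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph contains a directed cycle")

    def parent_sets(self) -> dict[str, tuple[str, ...]]:
        parents: dict[str, list[str]] = {v: [] for v in self.nodes}
        for u, v in self.edges:
            parents[v].append(u)
        return {v: tuple(sorted(ps)) for v, ps in parents.items()}

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.edges)

    def v_structures(self) -> frozenset:
        """Immoralities (a -> c <- b with a, b non-adjacent), as (frozenset{a,b}, c)."""
        parents = self.parent_sets()
        skel = self.skeleton()
        out = set()
        for c, ps in parents.items():
            for a, b in combinations(ps, 2):
                if frozenset((a, b)) not in skel:
                    out.add((frozenset((a, b)), c))
        return frozenset(out)


def same_markov_class(a: DagStructure, b: DagStructure) -> bool:
    """Markov equivalence: identical skeleton and identical v-structures."""
    return a.skeleton() == b.skeleton() and a.v_structures() == b.v_structures()


def enumerate_dags(nodes: tuple[str, ...]):
    """Yield every DAG over the given nodes (feasible only for tiny node sets)."""
    arcs = [(u, v) for u in nodes for v in nodes if u != v]
    for bits in range(1 << len(arcs)):
        edges = frozenset(a for i, a in enumerate(arcs) if bits >> i & 1)
        try:
            yield DagStructure(nodes, edges)
        except ValueError:
            continue


def skeleton_f1(estimated: frozenset[frozenset[str]], truth: frozenset[frozenset[str]]) -> float:
    """F1 of an undirected edge set against a reference skeleton."""
    tp = len(estimated & truth)
    if tp == 0:
        return 0.0
    precision = tp / len(estimated)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# screening and discretization
# ---------------------------------------------------------------------------


def screen_top_features(
    layer: OmicLayerTable,
    labels: list[InflammationAssignment] | pd.Series,
    n_top: int = 5,
    seed: int | None = 0,
    n_estimators: int = 500,
    discretize: bool = False,
) -> list[str]:
    """Top features of a layer by random-forest Gini importance.

    A random-forest classifier of the 3-level inflammation label is fit on the
    layer's features (continuous values by default; ``discretize`` switches to
    the above/below-median codes) with a fixed seed and tree count, and the
    ``n_top`` features with the largest mean decrease in impurity are
    returned, ties broken lexicographically.
    """
    if isinstance(labels, list):
        labels = assignments_to_frame(labels)["group"]
    y = labels.reindex(layer.values.index)
    if y.isna().any():
        raise ValueError("every participant in the layer needs an inflammation label")
    if y.nunique() < 2:
        raise ValueError("inflammation label is constant; nothing to screen against")
    if n_top > len(layer.features):
        raise ValueError(f"n_top={n_top} exceeds feature count {len(layer.features)}")
    X = layer.values
    if discretize:
        X, _ = discretize_by_median(layer)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(X.to_numpy(), y.to_numpy())
    imp = pd.Series(rf.feature_importances_, index=X.columns)
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return order[:n_top]


def discretize_by_median(
    layer: OmicLayerTable, degenerate_tie_fraction: float = 0.9
) -> tuple[pd.DataFrame, list[str]]:
    """Binary codes per feature: 1 iff strictly above the cohort median.

    Features where more than ``degenerate_tie_fraction`` of values tie at the
    median carry almost no information after the split and are excluded;
    their names are returned alongside the coded frame.
    """
    values = layer.values
    if values.isna().any().any():
        raise ValueError("median discretization requires complete-case values")
    med = values.median(axis=0)
    tie_frac = values.eq(med, axis=1).mean(axis=0)
    degenerate = tie_frac.index[tie_frac > degenerate_tie_fraction].tolist()
    if degenerate:
        log.info("median discretization (%s): excluded degenerate features %s",
                 layer.layer_id, degenerate)
    keep = [f for f in values.columns if f not in degenerate]
    codes = values[keep].gt(med[keep], axis=1).astype(np.int64)
    return codes, degenerate


def build_discrete_matrix(
    layers: list[OmicLayerTable],
    assignments: list[InflammationAssignment],
) -> DiscreteMatrix:
    """Median-discretize each layer and append the 3-level inflammation variable.

    Layers must already be complete-case filtered to a common participant set.
    """
    frames, layer_tags, arities = [], {}, {}
    participants = layers[0].participants
    for layer in layers:
        if layer.participants != participants:
            raise ValueError("layers must share one participant order (complete-case filter first)")
        codes, _ = discretize_by_median(layer)
        for f in codes.columns:
            layer_tags[f] = layer.layer_id
            arities[f] = 2
        frames.append(codes)
    groups = assignments_to_frame(assignments)["group"].reindex(participants)
    if groups.isna().any():
        raise ValueError("inflammation assignment missing for some participants")
    level_code = {g: i for i, g in enumerate(INFLAMMATION_LEVELS)}
    frames.append(
        pd.DataFrame({INFLAMMATION_VARIABLE: groups.map(level_code)}, index=groups.index)
    )
    layer_tags[INFLAMMATION_VARIABLE] = INFLAMMATION_VARIABLE
    arities[INFLAMMATION_VARIABLE] = len(INFLAMMATION_LEVELS)
    data = pd.concat(frames, axis=1)
    return DiscreteMatrix(
        data,
        pd.Series(arities),
        pd.Series(layer_tags),
    )


# ---------------------------------------------------------------------------
# BDeu scoring
# ---------------------------------------------------------------------------


class BDeScorer:
    """Decomposable BDeu (likelihood-equivalent Bayesian Dirichlet) scorer.

    The log marginal likelihood of a DAG decomposes over families
    (node, parent set); each family contributes

        sum_j [ lnG(a_j) - lnG(a_j + N_j) + sum_k ( lnG(a_jk + N_jk) - lnG(a_jk) ) ]

    over parent configurations j and child states k, with uniform Dirichlet
    hyperparameters a_jk = ess / (q_i r_i) and a_j = ess / q_i, where ess is
    the imaginary sample size, r_i the child arity and q_i the number of
    parent configurations. Family scores are cached, so greedy search only
    pays for families it has not seen before.
    """

    #: guard against parent sets whose configuration table would not fit
    MAX_CONFIGURATIONS = 1_000_000

    def __init__(self, data: DiscreteMatrix, ess: float):
        if not ess > 0:
            raise ValueError("ess must be > 0")
        self.ess = float(ess)
        self.variables = list(data.variables)
        self._index = {v: i for i, v in enumerate(self.variables)}
        self._data = np.ascontiguousarray(data.data.to_numpy(dtype=np.int64).T)
        self._arities = data.arities.to_numpy(dtype=np.int64)
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family_score(self, node: int, parents: tuple[int, ...]) -> float:
        """Log family score for an (index-coded) node and sorted parent tuple."""
        key = (node, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        r = int(self._arities[node])
        q = 1
        idx = np.zeros(self._data.shape[1], dtype=np.int64)
        for p in parents:
            rp = int(self._arities[p])
            idx = idx * rp + self._data[p]
            q *= rp
            if q * r > self.MAX_CONFIGURATIONS:
                raise ValueError("parent configuration table too large; cap max_parents")
        flat = idx * r + self._data[node]
        counts = np.bincount(flat, minlength=q * r).reshape(q, r)
        a_jk = self.ess / (q * r)
        a_j = self.ess / q
        n_j = counts.sum(axis=1)
        score = float(
            (gammaln(a_j) - gammaln(a_j + n_j)).sum()
            + (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
        )
        self._cache[key] = score
        return score

    def score_dag(self, dag: DagStructure) -> float:
        """Total BDeu log score (sum of family scores)."""
        total = 0.0
        for v, ps in dag.parent_sets().items():
            total += self.family_score(
                self._index[v], tuple(sorted(self._index[p] for p in ps))
            )
        return total


def bde_score(dag: DagStructure, data: DiscreteMatrix, ess: float) -> float:
    """BDeu log marginal likelihood of ``dag`` given complete discrete data."""
    return BDeScorer(data, ess).score_dag(dag)


# ---------------------------------------------------------------------------
# greedy structure search
# ---------------------------------------------------------------------------


class _SearchState:
    """Mutable index-coded DAG for hill climbing (parents, children, scores)."""

    def __init__(self, scorer: BDeScorer, start: DagStructure, max_parents: int):
        self.scorer = scorer
        self.max_parents = max_parents
        self.p = len(scorer.variables)
        self.parents: list[set[int]] = [set() for _ in range(self.p)]
        self.children: list[set[int]] = [set() for _ in range(self.p)]
        idx = scorer._index
        for u, v in start.edges:
            self.parents[idx[v]].add(idx[u])
            self.children[idx[u]].add(idx[v])
        self.family: list[float] = [
            scorer.family_score(v, tuple(sorted(self.parents[v]))) for v in range(self.p)
        ]

    @property
    def score(self) -> float:
        return float(sum(self.family))

    def has_path(self, src: int, dst: int) -> bool:
        """Directed path src ~> dst (used to veto cycle-creating moves)."""
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            for w in self.children[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def _fam(self, v: int, parents: set[int]) -> float:
        return self.scorer.family_score(v, tuple(sorted(parents)))

    def candidate_moves(self):
        """Yield (delta, op, u, v) over admissible add/delete/reverse moves."""
        for u in range(self.p):
            for v in range(self.p):
                if u == v:
                    continue
                if u in self.parents[v]:
                    # delete u -> v
                    new = self._fam(v, self.parents[v] - {u})
                    yield new - self.family[v], "del", u, v
                    # reverse u -> v  (becomes v -> u)
                    if len(self.parents[u]) < self.max_parents:
                        self.children[u].discard(v)
                        creates_cycle = self.has_path(u, v)
                        self.children[u].add(v)
                        if not creates_cycle:
                            d = (
                                new
                                - self.family[v]
                                + self._fam(u, self.parents[u] | {v})
                                - self.family[u]
                            )
                            yield d, "rev", u, v
                elif (
                    v not in self.parents[u]
                    and len(self.parents[v]) < self.max_parents
                    and not self.has_path(v, u)
                ):
                    # add u -> v
                    d = self._fam(v, self.parents[v] | {u}) - self.family[v]
                    yield d, "add", u, v

    def apply(self, op: str, u: int, v: int) -> None:
        if op == "add":
            self.parents[v].add(u)
            self.children[u].add(v)
        elif op == "del":
            self.parents[v].discard(u)
            self.children[u].discard(v)
        else:  # reverse u -> v
            self.parents[v].discard(u)
            self.children[u].discard(v)
            self.parents[u].add(v)
            self.children[v].add(u)
            self.family[u] = self._fam(u, self.parents[u])
        self.family[v] = self._fam(v, self.parents[v])

    def to_dag(self) -> DagStructure:
        names = self.scorer.variables
        edges = frozenset(
            (names[u], names[v]) for v in range(self.p) for u in self.parents[v]
        )
        return DagStructure(tuple(names), edges)


def empty_dag(variables) -> DagStructure:
    return DagStructure(tuple(variables))


def hill_climb(
    data: DiscreteMatrix,
    ess: float,
    start: DagStructure | None = None,
    max_parents: int = 4,
    scorer: BDeScorer | None = None,
) -> DagStructure:
    """Greedy hill climbing over single-edge additions, deletions, reversals.

    At each step the highest-scoring admissible move is applied while the
    BDeu score strictly improves; the returned DAG is a local optimum. Ties
    between equal-gain moves are broken by a fixed move-enumeration order, so
    the search is deterministic.
    """
    if scorer is None:
        scorer = BDeScorer(data, ess)
    if start is None:
        start = empty_dag(scorer.variables)
    state = _SearchState(scorer, start, max_parents)
    while True:
        best = None
        for delta, op, u, v in state.candidate_moves():
            if delta > _EPS and (best is None or delta > best[0] + _EPS):
                best = (delta, op, u, v)
        if best is None:
            return state.to_dag()
        state.apply(*best[1:])


def _perturb(
    dag: DagStructure,
    rng: np.random.Generator,
    n_ops: int,
    max_parents: int,
) -> DagStructure:
    """Apply ``n_ops`` random valid edge operations (add/delete/reverse)."""
    nodes = list(dag.nodes)
    edges = set(dag.edges)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    parents = {v: {u for u, w in edges if w == v} for v in nodes}
    for _ in range(n_ops):
        candidates = []
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                if (u, v) in edges:
                    candidates.append(("del", u, v))
                    g.remove_edge(u, v)
                    if not nx.has_path(g, u, v) and len(parents[u]) < max_parents:
                        candidates.append(("rev", u, v))
                    g.add_edge(u, v)
                elif (v, u) not in edges and len(parents[v]) < max_parents:
                    if not nx.has_path(g, v, u):
                        candidates.append(("add", u, v))
        if not candidates:
            break
        op, u, v = candidates[rng.integers(len(candidates))]
        if op == "add":
            edges.add((u, v))
            g.add_edge(u, v)
            parents[v].add(u)
        elif op == "del":
            edges.discard((u, v))
            g.remove_edge(u, v)
            parents[v].discard(u)
        else:
            edges.discard((u, v))
            g.remove_edge(u, v)
            parents[v].discard(u)
            edges.add((v, u))
            g.add_edge(v, u)
            parents[u].add(v)
    return DagStructure(tuple(nodes), frozenset(edges))


def learn_with_restarts(
    data: DiscreteMatrix,
    ess: float,
    n_restarts: int = 10,
    perturb: int = 5,
    seed: int | None = 0,
    max_parents: int = 4,
    scorer: BDeScorer | None = None,
) -> DagStructure:
    """Hill climbing with random restarts; returns the best-scoring local optimum.

    Restart 1 starts from the empty DAG; each subsequent restart perturbs the
    incumbent best with ``perturb`` random valid edge operations and re-runs
    the greedy search, keeping the higher-scoring result. Deterministic given
    the seed.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    if scorer is None:
        scorer = BDeScorer(data, ess)
    best = hill_climb(data, ess, max_parents=max_parents, scorer=scorer)
    best_score = scorer.score_dag(best)
    for _ in range(n_restarts - 1):
        start = _perturb(best, rng, perturb, max_parents)
        candidate = hill_climb(data, ess, start=start, max_parents=max_parents, scorer=scorer)
        candidate_score = scorer.score_dag(candidate)
        if candidate_score > best_score + _EPS:
            best, best_score = candidate, candidate_score
    return best


# ---------------------------------------------------------------------------
# bootstrap consensus
# ---------------------------------------------------------------------------


@dataclass
class ArcStrengthTable:
    """Undirected bootstrap edge-support fractions per node pair."""

    nodes: tuple[str, ...]
    strengths: dict[frozenset, float]
    n_bootstraps: int
    n_restarts: int
    seed: int | None
    n_networks_learned: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "strength": self.strengths.get(frozenset((a, b)), 0.0)}
            for a, b in combinations(self.nodes, 2)
        ]
        return pd.DataFrame(rows)

    def values(self) -> np.ndarray:
        return np.array(
            [self.strengths.get(frozenset(p), 0.0) for p in combinations(self.nodes, 2)]
        )


def bootstrap_arc_strengths(
    data: DiscreteMatrix,
    ess: float,
    B: int = 200,
    n_restarts: int = 10,
    seed: int | None = 0,
    perturb: int = 5,
    max_parents: int = 4,
) -> ArcStrengthTable:
    """Bootstrap arc strengths: fraction of resampled networks with each edge.

    For each of ``B`` participant resamples (with replacement, same n), the
    best of ``n_restarts`` restarted hill climbs is recorded as an undirected
    skeleton; strength(pair) = fraction of the B skeletons containing the
    pair. B x n_restarts structures are learned in total (1,000,000 at the
    full-scale setting B = R = 1000).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ss = np.random.SeedSequence(seed)
    resample_rng = np.random.default_rng(ss.spawn(1)[0])
    restart_seeds = ss.generate_state(B)
    counts: dict[frozenset, int] = {}
    for b in range(B):
        boot = data.resample(resample_rng)
        dag = learn_with_restarts(
            boot, ess, n_restarts=n_restarts, perturb=perturb,
            seed=int(restart_seeds[b]), max_parents=max_parents,
        )
        for pair in dag.skeleton():
            counts[pair] = counts.get(pair, 0) + 1
    strengths = {pair: c / B for pair, c in counts.items()}
    return ArcStrengthTable(
        nodes=tuple(data.variables),
        strengths=strengths,
        n_bootstraps=B,
        n_restarts=n_restarts,
        seed=seed,
        n_networks_learned=B * n_restarts,
    )


def estimate_significance_threshold(strengths: ArcStrengthTable | np.ndarray) -> float:
    """Arc-strength significance threshold from the empirical strength CDF.

    In a noiseless world every pair's strength is 0 or 1, so the ideal CDF is
    a step function: F(x) = t on [0, 1) and 1 at 1, where t is the unknown
    fraction of non-edges. The estimator picks t minimizing the L1 distance
    between the empirical CDF of observed strengths and that step, then
    returns the smallest observed strength strictly above the t-quantile of
    the strengths (so the >=-threshold consensus rule keeps exactly the pairs
    the estimator deems significant). All-identical strengths return that
    common value.
    """
    if isinstance(strengths, ArcStrengthTable):
        s = strengths.values()
    else:
        s = np.asarray(strengths, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one strength value")
    if ((s < 0) | (s > 1)).any():
        raise ValueError("strengths must lie in [0, 1]")
    uniq, counts = np.unique(s, return_counts=True)
    if uniq.size == 1:
        log.info("all arc strengths identical (%.3f); threshold = that value", uniq[0])
        return float(uniq[0])
    cdf = np.cumsum(counts) / s.size  # F at each unique strength
    # piecewise-constant empirical CDF over [0, 1]: value before uniq[0] is 0
    grid = np.concatenate(([0.0], uniq, [1.0]))
    levels = np.concatenate(([0.0], cdf))  # F on [grid[i], grid[i+1])
    widths = np.diff(grid)
    candidates = np.unique(levels)
    objective = [(np.abs(levels - t) * widths).sum() for t in candidates]
    t_hat = float(candidates[int(np.argmin(objective))])
    # t-quantile of the strengths, then the smallest strength strictly above it
    q = uniq[np.searchsorted(cdf, t_hat - 1e-12)] if t_hat > 0 else uniq[0]
    above = uniq[uniq > q + 1e-12]
    threshold = float(above[0]) if above.size else float(q)
    return min(threshold, 1.0)


@dataclass
class ConsensusNetwork:
    """Thresholded undirected consensus graph with provenance."""

    graph: nx.Graph
    threshold: float
    n_bootstraps: int
    n_restarts: int
    seed: int | None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree)

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges)


def build_consensus_network(
    strengths: ArcStrengthTable,
    threshold: float,
    layer_of: pd.Series | None = None,
) -> ConsensusNetwork:
    """Keep node pairs with strength >= threshold as undirected consensus edges."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(strengths.nodes)
    for pair, s in strengths.strengths.items():
        if s >= threshold:
            a, b = sorted(pair)
            g.add_edge(a, b, strength=float(s))
    for node in g.nodes:
        if layer_of is not None and node in layer_of.index:
            g.nodes[node]["layer"] = str(layer_of[node])
        g.nodes[node]["degree"] = int(g.degree[node])
    log.info("consensus network: %d edges between %d nodes at threshold %.3f",
             g.number_of_edges(), g.number_of_nodes(), threshold)
    return ConsensusNetwork(
        g, float(threshold), strengths.n_bootstraps, strengths.n_restarts, strengths.seed
    )


# ---------------------------------------------------------------------------
# imaginary-sample-size estimation
# ---------------------------------------------------------------------------


def estimate_imaginary_sample_size(
    data: DiscreteMatrix,
    dag: DagStructure | None = None,
    grid_min: float = 2.0**-5,
    grid_max: float = 2.0**10,
    grid_points: int = 64,
) -> float:
    """ESS maximizing the BDeu score of ``dag`` (default: the empty DAG).

    The Dirichlet prior's total pseudo-count is chosen by profiling the score
    over a log-spaced grid and refining the best bracket with golden-section
    search on the log scale; deterministic.
    """
    if dag is None:
        dag = empty_dag(data.variables)
    grid = np.geomspace(grid_min, grid_max, grid_points)

    def score(ess: float) -> float:
        return BDeScorer(data, ess).score_dag(dag)

    values = np.array([score(e) for e in grid])
    if not np.isfinite(values).all():
        raise ValueError("non-finite BDeu scores across the ESS grid")
    best = int(np.argmax(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    # golden-section maximization on log(ess)
    a, b = math.log(lo), math.log(hi)
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc, fd = score(math.exp(c)), score(math.exp(d))
    for _ in range(60):
        if b - a < 1e-4:
            break
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = score(math.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = score(math.exp(d))
    x = math.exp((a + b) / 2.0)
    return float(x if score(x) >= values[best] else grid[best])


def estimate_ess(
    data: DiscreteMatrix,
    max_iterations: int = 4,
    max_parents: int = 4,
    start_ess: float = 1.0,
) -> float:
    """Imaginary sample size by alternating structure learning and profiling.

    Starting from a unit pseudo-count, the DAG is learned by hill climbing at
    the current ESS and the ESS re-optimized for that DAG, until the value
    stabilizes. Profiling against the empty graph is uninformative here:
    median-split variables are near-balanced, so the empty-graph score grows
    monotonically in the pseudo-count and the optimum escapes to the grid
    boundary; anchoring on the learned structure keeps the prior weight
    commensurate with the dependencies actually present.
    """
    ess = float(start_ess)
    for _ in range(max_iterations):
        dag = hill_climb(data, ess, max_parents=max_parents)
        new = estimate_imaginary_sample_size(data, dag)
        if abs(math.log(new / ess)) < 1e-3:
            return new
        ess = new
    return ess
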