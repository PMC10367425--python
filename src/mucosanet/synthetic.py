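"""Synthetic multi-omics cohort generator with known ground truth.

Emulates the statistical structure of a cervicovaginal multi-omics study:
log-normal positive abundances with limit-of-detection censoring (cytokines,
metabolites), logistic-normal immune-cell percentages, compositional taxa
profiles drawn from a Lactobacillus-dominant / anaerobe-dominant Dirichlet
mixture, multinomial bacterial-protein spectral counts tagged with ko
pathways, three latent inflammation groups with planted log2 effects, and an
optional planted dependence DAG for exercising the network learner.

Defaults are sized to the study design the package analyzes: 43 participants
split 6/25/12 across low/medium/high inflammation, a 30-cytokine panel
containing the curated 10, 6 immune-cell types, 200 host proteins, 82
metabolites, 19 taxa, 33 ko pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grouping import CURATED_PANEL
from .metaproteome import UNDISTINGUISHABLE, SpectralCountTable
from .network import DiscreteMatrix
from .tables import OmicLayerTable, ReferenceReplicates

GROUPS = ("low", "medium", "high")

TAXA = (
    "L. crispatus",
    "L. iners",
    "Lactobacillus other",
    "Gardnerella",
    "Prevotella",
    "Atopobium",
    "Megasphaera",
    "Sneathia",
    "Mobiluncus",
    "Ruminococcus",
    "Streptococcus",
    "Staphylococcus",
    "Bifidobacterium",
    "Dialister",
    "Anaerococcus",
    "Peptoniphilus",
    "Finegoldia",
    "Corynebacterium",
    UNDISTINGUISHABLE,
)

IMMUNE_CELLS = ("APCs", "Neutrophils", "CD4_T_cells", "CD8_T_cells", "NK_cells", "B_cells")

KO_PATHWAYS = tuple(
    ["Glycolysis / Gluconeogenesis", "Carbon fixation", "RNA degradation",
     "Inositol phosphate metabolism", "Two-component system",
     "Amino sugar and nucleotide sugar metabolism", "Fructose and mannose metabolism",
     "Purine metabolism", "Pyruvate metabolism", "Pentose phosphate pathway"]
    + [f"pathway_{i:02d}" for i in range(11, 34)]
)

NAMED_METABOLITES = (
    "xanthine", "lactate", "succinate", "adenosine", "hexose", "hexose-phosphate",
    "homovanilate", "phenyllactate", "inosine", "glycine",
)

NAMED_HOST_PROTEINS = ("SCEL", "IVL", "SERPINB3")


@dataclass(frozen=True)
class PlantedDag:
    """A known DAG with full conditional probability tables, for sampling.

    ``cpts[node]`` is ``(parents, table)`` where ``table`` has one row per
    parent configuration (row-major in parent order) and one column per child
    state; rows sum to 1. ``arities`` gives states per node.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    cpts: dict[str, tuple[tuple[str, ...], np.ndarray]]
    arities: dict[str, int]

    def __post_init__(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("planted graph must be acyclic")
        for node, (parents, table) in self.cpts.items():
            q = int(np.prod([self.arities[p] for p in parents])) if parents else 1
            if table.shape != (q, self.arities[node]):
                raise ValueError(f"CPT shape mismatch for {node!r}")
            if not np.allclose(table.sum(axis=1), 1.0):
                raise ValueError(f"CPT rows must sum to 1 for {node!r}")

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.edges)


def default_planted_dag(n_nodes: int = 10, strength: float = 0.9) -> PlantedDag:
    """A sparse binary DAG (chains and a fork) with strong, symmetric CPTs.

    Each child copies its parent with probability ``strength``; roots are
    fair coins. One node is left isolated as a negative control.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    nodes = tuple(f"V{i}" for i in range(n_nodes))
    chain = [(nodes[i], nodes[i + 1]) for i in range(0, min(4, n_nodes - 1))]
    extra = []
    if n_nodes >= 9:
        extra = [(nodes[0], nodes[5]), (nodes[5], nodes[6]), (nodes[7], nodes[8])]
    edges = frozenset(chain + extra)
    arities = {v: 2 for v in nodes}
    cpts: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    parents_of: dict[str, list[str]] = {v: [] for v in nodes}
    for u, v in edges:
        parents_of[v].append(u)
    for v in nodes:
        ps = tuple(sorted(parents_of[v]))
        if not ps:
            cpts[v] = (ps, np.array([[0.5, 0.5]]))
        else:
            # single parent by construction
            cpts[v] = (ps, np.array([[strength, 1 - strength], [1 - strength, strength]]))
    return PlantedDag(nodes, edges, cpts, arities)


@dataclass
class SyntheticTruth:
    """Ground-truth configuration of a synthetic cohort.

    ``effects[layer][feature]`` is a (low, medium, high) triple of additive
    log2 shifts (pre-softmax logit shifts for the immune layer). The LOD
    censoring quantile is the per-feature fraction of samples pushed below
    the detection limit. Group proportions default to 6/25/12 of 43.
    """

    n_participants: int = 43
    group_proportions: tuple[float, float, float] = (6 / 43, 25 / 43, 12 / 43)
    n_extra_cytokines: int = 20
    n_host_proteins: int = 200
    n_metabolites: int = 82
    n_bact_proteins: int = 250
    sigma_log2: float = 1.0
    lod_quantile: dict = field(
        default_factory=lambda: {"cytokine": 0.10, "metabolite": 0.15}
    )
    #: per-group probability that a participant is Lactobacillus dominant
    ld_probability: tuple[float, float, float] = (1.0, 0.64, 0.58)
    #: multiplier on the L. crispatus Dirichlet concentration per group
    crispatus_boost: tuple[float, float, float] = (2.0, 1.0, 0.8)
    effects: dict = field(default_factory=dict)
    planted_dag: PlantedDag | None = None
    fraction_ko_annotated: float = 0.55
    total_spectral_counts: int = 2000
    seed: int = 0

    @staticmethod
    def default_effects() -> dict:
        """Planted group effects emulating the qualitative study signal:
        curated cytokines rise with inflammation, APCs rise, a handful of
        metabolites shift (xanthine up, lactate/succinate/adenosine down),
        epithelial-barrier proteins fall."""
        effects: dict = {"cytokine": {}, "immune_cell": {}, "host_protein": {}, "metabolite": {}}
        for c in CURATED_PANEL:
            effects["cytokine"][c] = (0.0, 1.5, 3.0)
        effects["immune_cell"]["APCs"] = (0.0, 0.8, 1.2)
        effects["metabolite"]["xanthine"] = (0.0, 1.0, 2.0)
        effects["metabolite"]["hexose"] = (0.0, 0.5, 1.2)
        effects["metabolite"]["hexose-phosphate"] = (0.0, 0.5, 1.2)
        effects["metabolite"]["lactate"] = (0.0, -0.8, -1.2)
        effects["metabolite"]["succinate"] = (0.0, -0.6, -1.0)
        effects["metabolite"]["adenosine"] = (0.0, -0.6, -1.0)
        for prot in NAMED_HOST_PROTEINS:
            effects["host_protein"][prot] = (0.0, -0.8, -1.6)
        for i in range(1, 11):
            effects["host_protein"][f"host_prot_{i:04d}"] = (0.0, 0.8, 1.6)
        return effects

    @classmethod
    def with_default_effects(cls, **kwargs) -> "SyntheticTruth":
        return cls(effects=cls.default_effects(), planted_dag=default_planted_dag(), **kwargs)


@dataclass
class SyntheticCohort:
    """A generated cohort: layer tables, spectral counts, and ground truth."""

    truth: SyntheticTruth
    participants: list[str]
    groups: pd.Series  # ground-truth inflammation group per participant
    ld: pd.Series  # ground-truth Lactobacillus dominance per participant
    layers: dict[str, OmicLayerTable]
    spectral: SpectralCountTable
    reference_replicates: ReferenceReplicates
    amsel: pd.DataFrame


def _group_labels(truth: SyntheticTruth, rng: np.random.Generator) -> np.ndarray:
    n = truth.n_participants
    props = np.asarray(truth.group_proportions, dtype=float)
    props = props / props.sum()
    counts = np.floor(props * n).astype(int)
    # largest-remainder allocation of the leftover participants
    rem = props * n - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(3), counts)
    rng.shuffle(labels)
    return labels


def _lognormal_layer(
    layer_id: str,
    features: list[str],
    participants: list[str],
    group_codes: np.ndarray,
    truth: SyntheticTruth,
    rng: np.random.Generator,
    base_mu_loc: float,
    censor_quantile: float,
) -> OmicLayerTable:
    """Log2-normal abundances with planted group shifts and LOD censoring."""
    n, m = len(participants), len(features)
    mu = rng.normal(base_mu_loc, 1.5, size=m)
    shifts = np.zeros((3, m))
    for j, f in enumerate(features):
        eff = truth.effects.get(layer_id, {}).get(f)
        if eff is not None:
            shifts[:, j] = eff
    log2x = mu + shifts[group_codes] + rng.normal(0.0, truth.sigma_log2, size=(n, m))
    x = np.exp2(log2x)
    values = pd.DataFrame(x, index=participants, columns=features)
    lod = None
    mask = None
    if censor_quantile > 0:
        lod_vals = np.quantile(x, censor_quantile, axis=0)
        lod_vals = np.maximum(lod_vals, 1e-12)
        mask = pd.DataFrame(x < lod_vals, index=participants, columns=features)
        values = values.mask(mask, 0.0)
        lod = pd.Series(lod_vals, index=features)
    return OmicLayerTable(layer_id, values, lod=lod, missing_mask=mask)


def _validate_truth(truth: SyntheticTruth) -> None:
    layer_features = {
        "cytokine": list(CURATED_PANEL)
        + [f"cytokine_extra_{i:02d}" for i in range(1, truth.n_extra_cytokines + 1)],
        "immune_cell": list(IMMUNE_CELLS),
        "host_protein": list(NAMED_HOST_PROTEINS)
        + [f"host_prot_{i:04d}"
           for i in range(1, truth.n_host_proteins - len(NAMED_HOST_PROTEINS) + 1)],
        "metabolite": list(NAMED_METABOLITES)
        + [f"metab_{i:03d}"
           for i in range(1, truth.n_metabolites - len(NAMED_METABOLITES) + 1)],
    }
    for layer, eff in truth.effects.items():
        if layer not in layer_features:
            raise ValueError(f"effects reference unknown layer {layer!r}")
        unknown = sorted(set(eff) - set(layer_features[layer]))
        if unknown:
            raise ValueError(
                f"effects for layer {layer!r} reference features not in the "
                f"configured cohort: {unknown[:5]}"
            )


def generate_cohort(truth: SyntheticTruth, seed: int | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort; identical seeds give identical cohorts."""
    _validate_truth(truth)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = truth.n_participants
    participants = [f"P{i + 1:03d}" for i in range(n)]
    group_codes = _group_labels(truth, rng)
    groups = pd.Series([GROUPS[g] for g in group_codes], index=participants, name="group")

    # --- cytokines: curated 10 plus extras, some heavily censored ----------
    cyto_features = list(CURATED_PANEL) + [
        f"cytokine_extra_{i:02d}" for i in range(1, truth.n_extra_cytokines + 1)
    ]
    cyto = _lognormal_layer(
        "cytokine", cyto_features, participants, group_codes, truth, rng,
        base_mu_loc=4.0, censor_quantile=truth.lod_quantile.get("cytokine", 0.0),
    )
    if truth.n_extra_cytokines:
        # extras get their own censoring quantiles, some beyond the 40% cut
        extra_q = rng.uniform(0.0, 0.6, size=truth.n_extra_cytokines)
        values, mask = cyto.values.copy(), cyto.mask().copy()
        lod = cyto.lod.copy() if cyto.lod is not None else pd.Series(
            np.nan, index=values.columns
        )
        for q, f in zip(extra_q, cyto_features[len(CURATED_PANEL):]):
            x = np.where(mask[f], lod[f] if np.isfinite(lod[f]) else 0.0, values[f])
            lo = max(float(np.quantile(x, q)), 1e-12)
            mask[f] = x < lo
            values[f] = np.where(mask[f], 0.0, x)
            lod[f] = lo
        cyto = OmicLayerTable("cytokine", values, lod=lod, missing_mask=mask)

    # --- immune cells: logistic-normal percentages of live cells ----------
    base_logits = np.array([1.0, 2.2, 1.8, 1.0, 0.3, -0.5])  # APC..B cells
    logits = np.tile(base_logits, (n, 1)) + rng.normal(0.0, 0.8, size=(n, len(IMMUNE_CELLS)))
    for j, cell in enumerate(IMMUNE_CELLS):
        eff = truth.effects.get("immune_cell", {}).get(cell)
        if eff is not None:
            logits[:, j] += np.asarray(eff)[group_codes]
    expl = np.exp(logits)
    pct = 100.0 * expl / expl.sum(axis=1, keepdims=True)
    immune = OmicLayerTable(
        "immune_cell", pd.DataFrame(pct, index=participants, columns=IMMUNE_CELLS)
    )

    # --- host proteome + technical reference replicates --------------------
    prot_features = list(NAMED_HOST_PROTEINS) + [
        f"host_prot_{i:04d}"
        for i in range(1, truth.n_host_proteins - len(NAMED_HOST_PROTEINS) + 1)
    ]
    host = _lognormal_layer(
        "host_protein", prot_features, participants, group_codes, truth, rng,
        base_mu_loc=6.0, censor_quantile=truth.lod_quantile.get("host_protein", 0.0),
    )
    ref_mean = host.values.mean(axis=0).to_numpy()
    cv = np.where(
        rng.random(len(prot_features)) < 0.85,
        rng.uniform(0.02, 0.20, len(prot_features)),
        rng.uniform(0.30, 0.80, len(prot_features)),
    )
    reps = rng.normal(
        ref_mean[:, None], (ref_mean * cv)[:, None], size=(len(prot_features), 7)
    )
    reps = np.clip(reps, 0.0, None)
    refs = ReferenceReplicates(
        pd.DataFrame(reps, index=prot_features, columns=[f"rep{j + 1}" for j in range(7)])
    )

    # --- metabolome --------------------------------------------------------
    metab_features = list(NAMED_METABOLITES) + [
        f"metab_{i:03d}"
        for i in range(1, truth.n_metabolites - len(NAMED_METABOLITES) + 1)
    ]
    metab = _lognormal_layer(
        "metabolite", metab_features, participants, group_codes, truth, rng,
        base_mu_loc=5.0, censor_quantile=truth.lod_quantile.get("metabolite", 0.0),
    )

    # --- metaproteome: taxa mixture + multinomial protein counts ----------
    ld_flags = rng.random(n) < np.asarray(truth.ld_probability)[group_codes]
    ld = pd.Series(ld_flags, index=participants, name="ld")
    taxa = list(TAXA)
    conc_ld = np.full(len(taxa), 0.15)
    conc_nld = np.full(len(taxa), 0.3)
    t_index = {t: i for i, t in enumerate(taxa)}
    conc_ld[t_index["L. crispatus"]] = 12.0
    conc_ld[t_index["L. iners"]] = 6.0
    conc_ld[t_index["Lactobacillus other"]] = 3.0
    conc_ld[t_index["Gardnerella"]] = 1.0
    conc_nld[t_index["Gardnerella"]] = 8.0
    conc_nld[t_index["Prevotella"]] = 4.0
    conc_nld[t_index["Atopobium"]] = 2.0
    conc_nld[t_index["L. iners"]] = 2.0

    proteins = [f"bact_prot_{i:04d}" for i in range(1, truth.n_bact_proteins + 1)]
    # proteins allocated to taxa with weight proportional to mean abundance
    mean_conc = (conc_ld / conc_ld.sum() + conc_nld / conc_nld.sum()) / 2.0
    protein_taxon = rng.choice(len(taxa), size=len(proteins), p=mean_conc / mean_conc.sum())
    annotated = rng.random(len(proteins)) < truth.fraction_ko_annotated
    protein_ko = np.where(
        annotated, rng.choice(len(KO_PATHWAYS), size=len(proteins)), -1
    )
    within_weight = rng.gamma(1.0, 1.0, size=len(proteins)) + 1e-6

    counts = np.zeros((len(proteins), n))
    for i in range(n):
        conc = conc_ld.copy() if ld_flags[i] else conc_nld.copy()
        conc[t_index["L. crispatus"]] *= truth.crispatus_boost[group_codes[i]]
        theta = rng.dirichlet(conc)
        probs = theta[protein_taxon] * within_weight
        probs = probs / probs.sum()
        counts[:, i] = rng.multinomial(truth.total_spectral_counts, probs)
    counts_df = pd.DataFrame(counts, index=proteins, columns=participants)
    spectral = SpectralCountTable(
        counts_df / counts_df.sum(axis=0),
        taxon=pd.Series([taxa[t] for t in protein_taxon], index=proteins),
        ko_pathway=pd.Series(
            [KO_PATHWAYS[k] if k >= 0 else None for k in protein_ko], index=proteins
        ),
    )

    # --- Amsel metadata (BV more likely in non-LD participants) ------------
    p_pos = np.where(ld_flags, 0.05, 0.55)
    amsel = pd.DataFrame(
        {
            crit: rng.random(n) < p_pos
            for crit in ("clue_cells", "whiff_positive", "ph_above_4_5", "abnormal_discharge")
        },
        index=participants,
    )

    return SyntheticCohort(
        truth=truth,
        participants=participants,
        groups=groups,
        ld=ld,
        layers={
            "cytokine": cyto,
            "immune_cell": immune,
            "host_protein": host,
            "metabolite": metab,
        },
        spectral=spectral,
        reference_replicates=refs,
        amsel=amsel,
    )


def sample_discrete_from_dag(
    dag: PlantedDag, n: int, seed: int | None = 0
) -> DiscreteMatrix:
    """Ancestral sampling of ``n`` complete rows from a planted DAG's CPTs."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    order = list(nx.topological_sort(g))
    data = {}
    for node in order:
        if node not in dag.cpts:
            raise ValueError(f"missing CPT for node {node!r}")
        parents, table = dag.cpts[node]
        r = dag.arities[node]
        if not parents:
            probs = np.tile(table[0], (n, 1))
        else:
            idx = np.zeros(n, dtype=np.int64)
            for p in parents:
                idx = idx * dag.arities[p] + data[p]
            probs = table[idx]
        u = rng.random(n)
        data[node] = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
    df = pd.DataFrame({v: data[v] for v in dag.nodes})
    return DiscreteMatrix(df, pd.Series(dag.arities))
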