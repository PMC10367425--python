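"""End-to-end orchestration: preprocess -> group -> summarize -> test -> network.

The pipeline consumes per-participant layer tables (from disk or from the
synthetic generator), applies the panel-hygiene filters, stratifies
participants into inflammation groups, derives taxa/function layers from the
metaproteome, runs the univariate contrasts, screens features, and learns
the bootstrapped consensus network. All outputs are delimited text plus a
YAML manifest; re-running with the same config and seed is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from . import metaproteome as mp
from . import network as net
from . import preprocess as pre
from . import stats as st
from .grouping import (
    assignments_to_frame,
    cluster_inflammation_groups,
    group_summary,
    select_curated_panel,
)
from .synthetic import SyntheticCohort
from .tables import OmicLayerTable

log = logging.getLogger(__name__)

SCALE_PRESETS = {
    "desk": {"n_bootstraps": 200, "n_restarts": 10},
    "full": {"n_bootstraps": 1000, "n_restarts": 1000},
}


@dataclass
class RunConfig:
    """All thresholds and sizes of one pipeline run, in one place."""

    seed: int = 0
    out_dir: str = "run"
    max_missing_fraction: float = 0.40
    max_cv: float = 0.25
    ld_threshold: float = 0.50
    n_top: int = 5
    k_groups: int = 3
    scale: str = "desk"
    n_bootstraps: int | None = None
    n_restarts: int | None = None
    perturb: int = 5
    max_parents: int = 4
    ess: float | None = None  # None -> estimate on the empty DAG
    consensus_threshold: float | None = None  # None -> L1-CDF estimator
    rf_trees: int = 500
    layer_paths: dict = field(default_factory=dict)
    lod_paths: dict = field(default_factory=dict)
    spectral_path: str | None = None
    reference_path: str | None = None

    def resolved_scale(self) -> tuple[int, int]:
        preset = SCALE_PRESETS[self.scale]
        B = self.n_bootstraps if self.n_bootstraps is not None else preset["n_bootstraps"]
        R = self.n_restarts if self.n_restarts is not None else preset["n_restarts"]
        return B, R


def load_inputs(config: RunConfig) -> dict:
    """Load layer tables, spectral counts and reference replicates from disk."""
    inputs: dict = {"layers": {}}
    for layer_id, path in config.layer_paths.items():
        inputs["layers"][layer_id] = mio.read_omic_table(
            path, layer_id, lod_path=config.lod_paths.get(layer_id)
        )
    if config.spectral_path:
        inputs["spectral"] = mio.read_spectral_counts(config.spectral_path)
    if config.reference_path:
        inputs["refs"] = mio.read_reference_replicates(config.reference_path)
    return inputs


def preprocess_layers(config: RunConfig, layers: dict, refs=None) -> dict:
    """Panel hygiene per layer: detection filter, imputation, CV filter."""
    out = {}
    for layer_id, table in layers.items():
        if layer_id == "cytokine":
            t = pre.filter_by_detection_rate(table, config.max_missing_fraction)
            t = pre.impute_half_min_lod(t)
        elif layer_id == "metabolite":
            t = pre.filter_by_detection_rate(table, config.max_missing_fraction)
            t = pre.impute_zero_replacement(t)
        elif layer_id == "host_protein" and refs is not None:
            t = pre.filter_by_technical_cv(table, refs, config.max_cv)
        else:
            t = table
        out[layer_id] = t
    return out


def derive_metaproteome_layers(spectral: mp.SpectralCountTable) -> dict:
    """Taxa, ko-function and bacterial-protein layers from spectral counts."""
    taxa_profiles = mp.compute_taxa_abundance(spectral)
    layers = {
        "taxa": OmicLayerTable("taxa", taxa_profiles),
        "bact_function": mp.bin_ko_pathways(spectral),
        "bact_protein": OmicLayerTable("bact_protein", spectral.counts.T),
    }
    return layers


def run_full_pipeline(config: RunConfig, cohort: SyntheticCohort | None = None) -> Path:
    """Run every stage and write results under ``config.out_dir``.

    ``cohort`` supplies in-memory inputs (typically from the synthetic
    generator); otherwise the tables referenced by ``config.layer_paths`` /
    ``spectral_path`` / ``reference_path`` are read from disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is not None:
        layers = dict(cohort.layers)
        spectral = cohort.spectral
        refs = cohort.reference_replicates
    else:
        inputs = load_inputs(config)
        layers = inputs["layers"]
        spectral = inputs.get("spectral")
        refs = inputs.get("refs")
    if "cytokine" not in layers:
        raise ValueError("pipeline requires a cytokine layer (inflammation grouping)")

    # --- stage 1: preprocessing -------------------------------------------
    layers = preprocess_layers(config, layers, refs=refs)
    for layer_id, t in layers.items():
        mio.write_omic_table(t, out / f"preprocessed_{layer_id}.tsv")

    # --- stage 2: inflammation grouping -----------------------------------
    panel = select_curated_panel(layers["cytokine"])
    assignments = cluster_inflammation_groups(panel, k=config.k_groups)
    assign_df = assignments_to_frame(assignments)
    assign_df.to_csv(out / "inflammation_assignments.tsv", sep="\t")
    group_summary(assignments).to_csv(out / "inflammation_group_summary.tsv", sep="\t")

    # --- stage 3: metaproteome summarization ------------------------------
    if spectral is not None:
        derived = derive_metaproteome_layers(spectral)
        layers.update(derived)
        taxa_profiles = derived["taxa"].values
        ld = mp.classify_lactobacillus_dominance(taxa_profiles, config.ld_threshold)
        ld.rename("lactobacillus_dominant").to_csv(out / "ld_assignments.tsv", sep="\t")
        mio.write_omic_table(derived["taxa"], out / "taxa_proportions.tsv")
        mio.write_omic_table(derived["bact_function"], out / "function_proportions.tsv")
    else:
        ld = None

    # --- stage 4: univariate contrasts -------------------------------------
    groups = assign_df["group"]
    for layer_id, t in layers.items():
        common = [p for p in t.participants if p in groups.index]
        res = st.kruskal_wallis_table(t.values.loc[common], groups.loc[common])
        res.to_csv(out / f"kw_by_inflammation_{layer_id}.tsv", sep="\t")
        if ld is not None:
            common_ld = [p for p in common if p in ld.index]
            labels = ld.loc[common_ld].map({True: "LD", False: "nLD"})
            if labels.nunique() == 2:
                res_ld = st.kruskal_wallis_table(t.values.loc[common_ld], labels)
                res_ld.to_csv(out / f"kw_by_ld_{layer_id}.tsv", sep="\t")

    # --- stage 5: screening, discretization, network -----------------------
    network_layers = [layers[l] for l in net_layer_order(layers)]
    complete = pre.complete_case_filter(network_layers)
    kept_participants = complete[0].participants
    screened = []
    for t in complete:
        top = net.screen_top_features(
            t, groups.loc[kept_participants], n_top=min(config.n_top, len(t.features)),
            seed=config.seed, n_estimators=config.rf_trees,
        )
        screened.append(t.select_features(top))
    kept_assign = [a for a in assignments if a.participant in kept_participants]
    disc = net.build_discrete_matrix(screened, kept_assign)
    disc.data.to_csv(out / "discretized_matrix.tsv", sep="\t")

    ess = config.ess
    if ess is None:
        ess = net.estimate_ess(disc, max_parents=config.max_parents)
    B, R = config.resolved_scale()
    strengths = net.bootstrap_arc_strengths(
        disc, ess, B=B, n_restarts=R, seed=config.seed,
        perturb=config.perturb, max_parents=config.max_parents,
    )
    mio.write_arc_strengths(strengths, out / "arc_strengths.tsv")
    threshold = config.consensus_threshold
    if threshold is None:
        threshold = net.estimate_significance_threshold(strengths)
    consensus = net.build_consensus_network(strengths, threshold, layer_of=disc.layer_of)
    mio.write_sif(consensus, out / "consensus.sif")
    mio.write_graphml(consensus, out / "consensus.graphml")

    manifest = {
        "config": {k: v for k, v in asdict(config).items() if k not in ("layer_paths", "lod_paths")},
        "seed": config.seed,
        "n_bootstraps": B,
        "n_restarts": R,
        "n_networks_learned": strengths.n_networks_learned,
        "ess": float(ess),
        "consensus_threshold": float(threshold),
        "n_nodes": len(disc.variables),
        "n_edges": consensus.n_edges,
        "n_participants_complete": len(kept_participants),
    }
    mio.write_manifest(manifest, out / "manifest.yaml")
    return out


def net_layer_order(layers: dict) -> list[str]:
    """Deterministic layer order for the network stage (all present layers)."""
    order = [
        "cytokine", "immune_cell", "host_protein", "metabolite",
        "taxa", "bact_function", "bact_protein",
    ]
    return [l for l in order if l in layers]
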