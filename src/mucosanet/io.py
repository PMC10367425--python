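"""Reading and writing the pipeline's delimited-text formats.

All tabular inputs and outputs are strict UTF-8 TSV (CSV selectable) with a
mandatory header row; participants are rows and features columns for layer
tables, with the first column holding the participant ID. Networks are
written as SIF and GraphML with layer/degree node attributes; run manifests
as YAML.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .metaproteome import SpectralCountTable
from .network import ArcStrengthTable, ConsensusNetwork
from .tables import OmicLayerTable, ReferenceReplicates

MISSING_TOKENS = ("", "NA", "NaN", "nan")


def _read_frame(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(MISSING_TOKENS),
                     keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate row IDs {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate column IDs {dups}")
    return df


def read_omic_table(
    path,
    layer_id: str,
    lod_path=None,
    sep: str = "\t",
    missing: str = "na",
) -> OmicLayerTable:
    """Read a participant-by-feature layer table.

    ``missing`` selects how below-LOD entries are encoded in the file:
    ``"na"`` (empty cell or NA token) or ``"zero"`` (0 entries are treated as
    censored for features that have an LOD). An optional sidecar TSV of
    per-feature LODs has columns ``feature`` and ``lod``.
    """
    df = _read_frame(path, sep=sep)
    for col in df.columns:
        bad = df[col].apply(lambda x: isinstance(x, str))
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    lod = None
    if lod_path is not None:
        lod_df = pd.read_csv(lod_path, sep=sep, index_col=0)
        lod = lod_df.iloc[:, 0].astype(float)
    if missing == "na":
        mask = df.isna()
    elif missing == "zero":
        if lod is None:
            raise ValueError("missing='zero' requires an LOD sidecar")
        with_lod = [c for c in df.columns if c in lod.index and np.isfinite(lod[c])]
        mask = pd.DataFrame(False, index=df.index, columns=df.columns)
        mask[with_lod] = df[with_lod] == 0
        mask |= df.isna()
    else:
        raise ValueError(f"unknown missing encoding {missing!r}")
    values = df.fillna(0.0).astype(float)
    return OmicLayerTable(layer_id, values, lod=lod,
                          missing_mask=mask if mask.to_numpy().any() else None)


def write_omic_table(table: OmicLayerTable, path, sep: str = "\t") -> None:
    """Write a layer table; masked entries are emitted as empty cells."""
    out = table.values.astype(object)
    mask = table.mask()
    out = out.mask(mask, other=np.nan)
    out.index.name = "participant"
    out.to_csv(path, sep=sep)
    if table.lod is not None:
        lod_path = Path(path).with_suffix(".lod.tsv")
        lod = table.lod.rename("lod")
        lod.index.name = "feature"
        lod.to_csv(lod_path, sep=sep)


def read_reference_replicates(path, sep: str = "\t") -> ReferenceReplicates:
    return ReferenceReplicates(_read_frame(path, sep=sep).astype(float))


def write_reference_replicates(refs: ReferenceReplicates, path, sep: str = "\t") -> None:
    out = refs.replicate_values.copy()
    out.index.name = "feature"
    out.to_csv(path, sep=sep)


def read_spectral_counts(path, sep: str = "\t") -> SpectralCountTable:
    """Read a Scaffold-style export: protein_id, taxon (or semicolon-separated
    candidate genera), optional ko_pathway, then one count column per
    participant."""
    df = _read_frame(path, sep=sep)
    if "taxon" not in df.columns:
        raise ValueError(f"{path}: missing required 'taxon' column")
    taxon_raw = df.pop("taxon").astype(str)
    ko = df.pop("ko_pathway") if "ko_pathway" in df.columns else None
    from .metaproteome import bin_homologous_proteins

    assignments = {
        p: {g.strip() for g in t.split(";") if g.strip()} for p, t in taxon_raw.items()
    }
    taxon = pd.Series(bin_homologous_proteins(assignments))
    counts = df.astype(float)
    return SpectralCountTable(counts, taxon=taxon, ko_pathway=ko)


def write_spectral_counts(table: SpectralCountTable, path, sep: str = "\t") -> None:
    out = table.counts.copy()
    out.insert(0, "taxon", table.taxon)
    if table.ko_pathway is not None:
        out.insert(1, "ko_pathway", table.ko_pathway)
    out.index.name = "protein_id"
    out.to_csv(path, sep=sep)


def write_arc_strengths(strengths: ArcStrengthTable, path, sep: str = "\t") -> None:
    strengths.to_frame().to_csv(path, sep=sep, index=False)


def write_sif(network: ConsensusNetwork, path) -> None:
    """SIF edge list: 'nodeA<TAB>pp<TAB>nodeB', one line per consensus edge."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\tpp\t{b}\n")


def write_graphml(network: ConsensusNetwork, path) -> None:
    nx.write_graphml(network.graph, path)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
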