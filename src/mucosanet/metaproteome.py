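"""Metaproteome summarization: spectral counts to taxa, functions, dominance.

Bacterial proteins identified by mass spectrometry carry a taxon assignment
(a genus or species, or the sentinel "undistinguishable" when peptides match
several genera) and optionally a KEGG ko-level pathway. This module turns the
protein-by-participant normalized spectral-count matrix into per-participant
taxa proportions, functional (pathway) profiles, and the Lactobacillus-
dominance label used for stratified contrasts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import OmicLayerTable

log = logging.getLogger(__name__)

#: Sentinel taxon for proteins whose peptides match more than one genus.
UNDISTINGUISHABLE = "undistinguishable"


@dataclass
class SpectralCountTable:
    """Bacterial-protein spectral counts with taxon and pathway assignments.

    ``counts`` is protein x participant (normalized total spectral counts);
    ``taxon`` maps each protein to a genus/species name or the
    "undistinguishable" sentinel; ``ko_pathway`` is optional per protein.
    """

    counts: pd.DataFrame
    taxon: pd.Series
    ko_pathway: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate protein IDs")
        if (self.counts.to_numpy(dtype=float) < 0).any():
            raise ValueError("spectral counts must be >= 0")
        self.taxon = self.taxon.reindex(self.counts.index)
        if self.taxon.isna().any():
            missing = self.taxon[self.taxon.isna()].index.tolist()
            raise ValueError(f"proteins without taxon assignment: {missing}")
        if self.ko_pathway is not None:
            self.ko_pathway = self.ko_pathway.reindex(self.counts.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def participants(self) -> list[str]:
        return list(self.counts.columns)

    def normalized(self) -> "SpectralCountTable":
        """Counts divided by per-participant totals (normalization to total
        protein detected). Idempotent up to scale for already-normalized input."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals[totals == 0].index.tolist()
            raise ValueError(f"participants with zero total spectral counts: {bad}")
        return SpectralCountTable(self.counts / totals, self.taxon, self.ko_pathway)


def bin_homologous_proteins(raw_assignments: dict[str, set[str]]) -> dict[str, str]:
    """Resolve candidate-genus sets: singletons keep their genus, multi-genus
    proteins are binned into the "undistinguishable" category."""
    out: dict[str, str] = {}
    for protein, genera in raw_assignments.items():
        if not genera:
            raise ValueError(f"protein {protein!r} has an empty candidate-genus set")
        out[protein] = next(iter(genera)) if len(genera) == 1 else UNDISTINGUISHABLE
    return out


def compute_taxa_abundance(
    table: SpectralCountTable, include_undistinguishable: bool = True
) -> pd.DataFrame:
    """Per-participant taxa proportions (participant x taxon).

    Taxon abundance is the sum of normalized spectral counts over the taxon's
    proteins, renormalized to proportions per participant. The
    "undistinguishable" bin is included in the denominator by default.
    """
    counts = table.counts
    taxon = table.taxon
    if not include_undistinguishable:
        keep = taxon != UNDISTINGUISHABLE
        counts, taxon = counts[keep.to_numpy()], taxon[keep]
    sums = counts.groupby(taxon).sum()  # taxon x participant
    totals = sums.sum(axis=0)
    if (totals == 0).any():
        bad = totals[totals == 0].index.tolist()
        raise ValueError(f"participants with zero total counts: {bad}")
    return (sums / totals).T


_LACTO_SPECIES = re.compile(r"^l\.? ", re.IGNORECASE)


def is_lactobacillus(taxon: str) -> bool:
    """True for genus-level Lactobacillus bins and 'L. <species>' labels."""
    t = str(taxon).strip()
    return t.lower().startswith("lactobacillus") or bool(_LACTO_SPECIES.match(t))


def classify_lactobacillus_dominance(
    profile: pd.Series | pd.DataFrame, threshold: float = 0.5
) -> bool | pd.Series:
    """Lactobacillus dominance: summed Lactobacillus proportion strictly > 50%.

    Species-level bins (L. crispatus, L. iners, ...) are rolled up with any
    genus-level Lactobacillus bin before comparison. Accepts a single profile
    (Series, taxon -> proportion) or a participant x taxon frame.
    """
    if isinstance(profile, pd.DataFrame):
        cols = [c for c in profile.columns if is_lactobacillus(c)]
        total = profile[cols].sum(axis=1) if cols else pd.Series(0.0, index=profile.index)
        return total > threshold
    total = sum(v for t, v in profile.items() if is_lactobacillus(t))
    return bool(total > threshold)


def bin_ko_pathways(table: SpectralCountTable) -> OmicLayerTable:
    """Bin annotated proteins to ko-level pathways, as proportions per participant.

    Proteins without a ko annotation are excluded from the denominator, so
    pathway proportions are relative to annotated counts only.
    """
    if table.ko_pathway is None or table.ko_pathway.dropna().empty:
        raise ValueError("no ko-pathway annotations present")
    annotated = table.ko_pathway.notna()
    counts = table.counts[annotated.to_numpy()]
    pathways = table.ko_pathway[annotated]
    sums = counts.groupby(pathways).sum()  # pathway x participant
    totals = sums.sum(axis=0)
    if (totals == 0).any():
        bad = totals[totals == 0].index.tolist()
        log.warning("participants with zero annotated counts dropped from function "
                    "layer: %s", bad)
        sums = sums.drop(columns=bad)
        totals = totals.drop(index=bad)
    values = (sums / totals).T
    n_mapped = int(annotated.sum())
    log.info("ko-pathway binning: %d / %d proteins mapped to %d pathways",
             n_mapped, len(table.proteins), values.shape[1])
    return OmicLayerTable("bact_function", values)


def taxon_composition_of_feature(table: SpectralCountTable, feature: str) -> pd.Series:
    """Proportion of a protein's or pathway's summed counts contributed by each taxon.

    ``feature`` may be a protein ID (composition is then the single assigned
    taxon) or a ko pathway ID (counts of its member proteins are pooled across
    participants and split by taxon).
    """
    if feature in table.counts.index:
        rows = table.counts.loc[[feature]]
        taxa = table.taxon.loc[[feature]]
    elif table.ko_pathway is not None and (table.ko_pathway == feature).any():
        members = table.ko_pathway == feature
        rows = table.counts[members.to_numpy()]
        taxa = table.taxon[members]
    else:
        raise KeyError(f"feature {feature!r} is neither a protein nor a ko pathway")
    per_taxon = rows.sum(axis=1).groupby(taxa).sum()
    total = per_taxon.sum()
    if total == 0:
        raise ValueError(f"feature {feature!r} has zero total counts")
    return per_taxon / total
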