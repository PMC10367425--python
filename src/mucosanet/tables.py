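"""Core tabular containers shared by all pipeline stages.

Each omic layer (cytokines, immune cells, host proteins, metabolites, taxa,
bacterial functions, bacterial proteins) is carried as a participant-by-feature
abundance matrix with optional limit-of-detection (LOD) metadata and a boolean
mask marking below-LOD/absent entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LAYERS = (
    "cytokine",
    "immune_cell",
    "host_protein",
    "metabolite",
    "taxa",
    "bact_function",
    "bact_protein",
)

LAYER_UNITS = {
    "cytokine": "pg/mL",
    "immune_cell": "% live cells",
    "host_protein": "normalized relative abundance",
    "metabolite": "normalized relative abundance",
    "taxa": "proportion",
    "bact_function": "proportion",
    "bact_protein": "normalized spectral counts",
}


class EmptyLayerError(ValueError):
    """Raised when a filter removes every feature (or participant) of a layer."""


@dataclass
class OmicLayerTable:
    """One participant-by-feature abundance matrix for a single omic layer.

    Parameters
    ----------
    layer_id : str
        One of :data:`LAYERS`.
    values : pandas.DataFrame
        Participants as rows, features as columns; non-negative abundances.
        Entries flagged in ``missing_mask`` are placeholders (typically 0 or
        NaN) and carry no information until imputed.
    lod : pandas.Series, optional
        Per-feature minimum detectable concentration (> 0 where present).
    missing_mask : pandas.DataFrame, optional
        Boolean matrix aligned with ``values``; True marks below-LOD/absent.
    """

    layer_id: str
    values: pd.DataFrame
    lod: pd.Series | None = None
    missing_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.layer_id not in LAYERS:
            raise ValueError(
                f"unknown layer_id {self.layer_id!r}; expected one of {LAYERS}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate participant IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        if self.missing_mask is not None:
            if not self.missing_mask.index.equals(self.values.index) or not (
                self.missing_mask.columns.equals(self.values.columns)
            ):
                raise ValueError("missing_mask must be aligned with values")
            self.missing_mask = self.missing_mask.astype(bool)
        if self.lod is not None:
            self.lod = self.lod.reindex(self.values.columns)
            present = self.lod.dropna()
            if (present <= 0).any():
                bad = present[present <= 0].index.tolist()
                raise ValueError(f"LOD must be > 0; offending features: {bad}")
        arr = self.values.to_numpy(dtype=float)
        observed = ~self.mask().to_numpy()
        if not np.isfinite(arr[observed]).all():
            raise ValueError(f"layer {self.layer_id!r}: non-finite observed values")

    # -- convenience accessors -------------------------------------------------

    @property
    def participants(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    @property
    def units(self) -> str:
        return LAYER_UNITS[self.layer_id]

    def mask(self) -> pd.DataFrame:
        """Missing mask, materialized as all-False when absent."""
        if self.missing_mask is None:
            return pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        return self.missing_mask

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of participants with a masked entry."""
        return self.mask().mean(axis=0)

    def with_values(self, values: pd.DataFrame, **kwargs) -> "OmicLayerTable":
        """Copy with replaced values (and optionally lod / missing_mask)."""
        return replace(self, values=values, **kwargs)

    def select_features(self, features) -> "OmicLayerTable":
        """Restrict to the given features, preserving the given order."""
        features = list(features)
        if not features:
            raise EmptyLayerError(
                f"layer {self.layer_id!r}: feature selection left no features"
            )
        lod = self.lod.reindex(features) if self.lod is not None else None
        mask = (
            self.missing_mask.loc[:, features]
            if self.missing_mask is not None
            else None
        )
        return OmicLayerTable(
            layer_id=self.layer_id,
            values=self.values.loc[:, features],
            lod=lod,
            missing_mask=mask,
        )

    def select_participants(self, participants) -> "OmicLayerTable":
        participants = list(participants)
        if not participants:
            raise EmptyLayerError(
                f"layer {self.layer_id!r}: participant selection left no rows"
            )
        mask = (
            self.missing_mask.loc[participants]
            if self.missing_mask is not None
            else None
        )
        return OmicLayerTable(
            layer_id=self.layer_id,
            values=self.values.loc[participants],
            lod=self.lod,
            missing_mask=mask,
        )


@dataclass
class ReferenceReplicates:
    """Repeated measurements of one standard sample, feature x replicate.

    Used to estimate per-feature technical variability (coefficient of
    variation) for the host-proteome reproducibility filter.
    """

    replicate_values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.replicate_values.shape[1] < 2:
            raise ValueError("need at least 2 replicates")
        if self.replicate_values.index.has_duplicates:
            raise ValueError("duplicate feature IDs in reference replicates")
        if (self.replicate_values.to_numpy(dtype=float) < 0).any():
            raise ValueError("replicate values must be >= 0")

    @property
    def features(self) -> list[str]:
        return list(self.replicate_values.index)

    @property
    def n_replicates(self) -> int:
        return self.replicate_values.shape[1]

    def cv(self) -> pd.Series:
        """Per-feature coefficient of variation (sample SD / mean).

        Features with zero mean get NaN (downstream filters drop them with a
        warning rather than dividing by zero).
        """
        vals = self.replicate_values
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = sd / mean
        out[mean == 0] = np.nan
        return out
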