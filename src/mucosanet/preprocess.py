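"""Detection-limit filtering, imputation, and technical-variability filtering.

These are the panel-hygiene steps applied to every abundance layer before any
statistics: remove features censored in too many samples, impute what remains,
log-transform, and (for the host proteome) drop proteins whose technical
coefficient of variation across reference-replicate runs is too high.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import EmptyLayerError, OmicLayerTable, ReferenceReplicates

log = logging.getLogger(__name__)


class MissingLodError(ValueError):
    """A masked entry has no limit of detection to impute from."""


def filter_by_detection_rate(
    table: OmicLayerTable, max_missing_fraction: float = 0.40
) -> OmicLayerTable:
    """Drop features below the limit of detection in too many samples.

    A feature is retained only if its missing fraction is *strictly below*
    ``max_missing_fraction`` — a feature missing in exactly 40% of samples is
    removed under the default threshold.
    """
    if not 0 < max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in (0, 1]")
    frac = table.missing_fraction()
    keep = frac.index[frac < max_missing_fraction]
    if len(keep) == 0:
        raise EmptyLayerError(
            f"layer {table.layer_id!r}: every feature is missing in "
            f">= {max_missing_fraction:.0%} of samples"
        )
    dropped = len(table.features) - len(keep)
    log.info(
        "detection-rate filter (%s): kept %d / %d features (threshold %.0f%%)",
        table.layer_id, len(keep), len(table.features), 100 * max_missing_fraction,
    )
    if dropped:
        log.info("  removed: %s", sorted(set(table.features) - set(keep)))
    return table.select_features(keep)


def impute_half_min_lod(table: OmicLayerTable) -> OmicLayerTable:
    """Replace each below-LOD entry by half its feature's detection limit."""
    mask = table.mask()
    if not mask.to_numpy().any():
        return table
    need_lod = mask.any(axis=0)
    if table.lod is None:
        missing = need_lod[need_lod].index.tolist()
        raise MissingLodError(f"no LOD available for masked features {missing}")
    no_lod = need_lod & table.lod.isna()
    if no_lod.any():
        raise MissingLodError(
            f"no LOD available for masked features {no_lod[no_lod].index.tolist()}"
        )
    values = table.values.copy()
    fill = pd.DataFrame(
        np.broadcast_to((table.lod / 2.0).to_numpy(), values.shape),
        index=values.index, columns=values.columns,
    )
    values = values.mask(mask, fill)
    n = int(mask.to_numpy().sum())
    log.info("half-min LOD imputation (%s): imputed %d entries", table.layer_id, n)
    return table.with_values(values, missing_mask=None)


def impute_zero_replacement(
    table: OmicLayerTable, strategy: str = "half_min"
) -> OmicLayerTable:
    """Impute below-LOD metabolite entries.

    ``strategy`` selects the replacement value per masked cell:

    - ``"half_min"`` (default): half the feature's minimum observed positive
      value — mirrors the cytokine half-LOD rule and keeps values log-safe;
    - ``"zero"``: literal zero (what the name suggests, but breaks log2);
    - ``"global_half_min"``: half the layer-wide minimum observed positive value.
    """
    if table.layer_id != "metabolite":
        raise ValueError("zero-replacement imputation is defined for the metabolite layer")
    if strategy not in ("half_min", "zero", "global_half_min"):
        raise ValueError(f"unknown strategy {strategy!r}")
    mask = table.mask()
    if not mask.to_numpy().any():
        return table
    values = table.values.copy()
    observed = values.where(~mask)
    observed = observed.where(observed > 0)
    all_masked = mask.all(axis=0)
    if all_masked.any():
        raise EmptyLayerError(
            "metabolite features with every entry masked (should have been "
            f"removed by the detection-rate filter): {all_masked[all_masked].index.tolist()}"
        )
    if strategy == "zero":
        fill = pd.DataFrame(0.0, index=values.index, columns=values.columns)
    elif strategy == "global_half_min":
        g = float(np.nanmin(observed.to_numpy())) / 2.0
        fill = pd.DataFrame(g, index=values.index, columns=values.columns)
    else:
        per_feature = observed.min(axis=0) / 2.0
        if per_feature.isna().any():
            bad = per_feature[per_feature.isna()].index.tolist()
            raise EmptyLayerError(
                f"metabolite features with no positive observed value: {bad}"
            )
        fill = pd.DataFrame(
            np.broadcast_to(per_feature.to_numpy(), values.shape),
            index=values.index, columns=values.columns,
        )
    values = values.mask(mask, fill)
    log.info(
        "zero-replacement imputation (metabolite, %s): imputed %d entries",
        strategy, int(mask.to_numpy().sum()),
    )
    return table.with_values(values, missing_mask=None)


def log2_transform(table: OmicLayerTable) -> OmicLayerTable:
    """Elementwise log2; all values must be strictly positive (post-imputation)."""
    arr = table.values.to_numpy(dtype=float)
    bad = np.argwhere(~(arr > 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"log2 of non-positive value {arr[i, j]!r} at participant "
            f"{table.values.index[i]!r}, feature {table.values.columns[j]!r}"
        )
    return table.with_values(np.log2(table.values))


def inverse_log2_transform(table: OmicLayerTable) -> OmicLayerTable:
    """Inverse of :func:`log2_transform` (elementwise ``2**x``)."""
    return table.with_values(np.exp2(table.values))


def filter_by_technical_cv(
    table: OmicLayerTable, refs: ReferenceReplicates, max_cv: float = 0.25
) -> OmicLayerTable:
    """Keep features whose technical CV across reference runs is < ``max_cv``.

    Features absent from the reference replicates, or with zero replicate
    mean, are dropped with a warning (they cannot be certified reproducible).
    """
    if not 0 < max_cv <= 1:
        raise ValueError("max_cv must be in (0, 1]")
    cv = refs.cv()
    keep: list[str] = []
    absent: list[str] = []
    degenerate: list[str] = []
    for feat in table.features:
        if feat not in cv.index:
            absent.append(feat)
        elif np.isnan(cv[feat]):
            degenerate.append(feat)
        elif cv[feat] < max_cv:
            keep.append(feat)
    if absent:
        log.warning("technical-CV filter: %d features absent from reference replicates "
                    "dropped: %s", len(absent), absent[:10])
    if degenerate:
        log.warning("technical-CV filter: zero replicate mean, dropped: %s", degenerate)
    if not keep:
        raise EmptyLayerError(
            f"layer {table.layer_id!r}: no feature has technical CV < {max_cv}"
        )
    log.info(
        "technical-CV filter (%s): kept %d / %d features (CV < %.0f%%)",
        table.layer_id, len(keep), len(table.features), 100 * max_cv,
    )
    return table.select_features(keep)


def complete_case_filter(tables: list[OmicLayerTable]) -> list[OmicLayerTable]:
    """Restrict every layer to participants complete (no missing row) in all.

    A participant is kept only if it is present in every table and its row has
    no masked entry and no NaN in any table. Output tables share one
    participant order (the first table's order restricted to the kept set).
    """
    if not tables:
        raise ValueError("need at least one table")
    complete_sets = []
    for t in tables:
        row_ok = ~(t.mask().any(axis=1) | t.values.isna().any(axis=1))
        complete_sets.append(set(row_ok[row_ok].index))
    common = set.intersection(*complete_sets)
    if not common:
        counts = {t.layer_id: len(s) for t, s in zip(tables, complete_sets)}
        raise EmptyLayerError(
            f"no participant is complete across all layers; per-layer complete "
            f"counts: {counts}"
        )
    order = [p for p in tables[0].participants if p in common]
    dropped = len(set(tables[0].participants) - common)
    if dropped:
        log.info("complete-case filter: dropped %d participants, %d retained",
                 dropped, len(order))
    return [t.select_participants(order) for t in tables]
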