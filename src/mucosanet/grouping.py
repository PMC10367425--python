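"""Inflammation stratification from the curated 10-cytokine panel.

Participants are grouped into low/medium/high genital inflammation by
unsupervised hierarchical clustering of ten inflammatory cytokines measured
in cervicovaginal lavage, summarized per participant as the number of
cytokines in the cohort upper quartile, and optionally flagged for bacterial
vaginosis via the Amsel 3-of-4 rule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .tables import OmicLayerTable

log = logging.getLogger(__name__)

#: Canonical curated panel of ten inflammatory cytokines, in canonical order.
CURATED_PANEL = (
    "IFN-a2",
    "IL-1a",
    "IL-1b",
    "IL-6",
    "IL-8",
    "IP-10",
    "MCP-1",
    "MIP-1a",
    "MIP-1b",
    "RANTES",
)

# Chemokine-nomenclature and spelling aliases, mapped after normalization
# (case-fold, Greek letters to Latin, separators stripped).
_ALIASES = {
    "ccl5": "RANTES",
    "ccl2": "MCP-1",
    "ccl3": "MIP-1a",
    "ccl4": "MIP-1b",
    "cxcl8": "IL-8",
    "cxcl10": "IP-10",
}

_GREEK = {"α": "a", "β": "b", "γ": "g"}


def normalize_cytokine_name(name: str) -> str:
    """Collapse a cytokine name to a canonical lookup key."""
    s = str(name).strip().lower()
    for greek, latin in _GREEK.items():
        s = s.replace(greek, latin)
    s = re.sub(r"[\s_\-/()]+", "", s)
    return s


_CANONICAL_KEYS = {normalize_cytokine_name(c): c for c in CURATED_PANEL}


def canonical_cytokine(name: str) -> str | None:
    """Map a raw cytokine label to its canonical panel name, or None."""
    key = normalize_cytokine_name(name)
    if key in _CANONICAL_KEYS:
        return _CANONICAL_KEYS[key]
    return _ALIASES.get(key)


def select_curated_panel(table: OmicLayerTable) -> OmicLayerTable:
    """Restrict a cytokine layer to the curated 10-cytokine inflammation panel.

    Raw feature names are matched through a normalization + alias table (so
    e.g. "CCL5" maps to RANTES); the output columns are renamed to canonical
    names in canonical order.
    """
    mapping: dict[str, str] = {}
    for feat in table.features:
        canon = canonical_cytokine(feat)
        if canon is not None:
            if canon in mapping.values():
                raise ValueError(f"cytokine {canon!r} matched by multiple input columns")
            mapping[feat] = canon
    missing = [c for c in CURATED_PANEL if c not in mapping.values()]
    if missing:
        raise ValueError(
            f"curated panel cytokines absent after preprocessing: {missing}"
        )
    order = {v: k for k, v in mapping.items()}
    selected = table.select_features([order[c] for c in CURATED_PANEL])
    values = selected.values.rename(columns=mapping)
    lod = selected.lod.rename(index=mapping) if selected.lod is not None else None
    mask = (
        selected.missing_mask.rename(columns=mapping)
        if selected.missing_mask is not None
        else None
    )
    return OmicLayerTable(table.layer_id, values, lod=lod, missing_mask=mask)


@dataclass(frozen=True)
class InflammationAssignment:
    """Per-participant inflammation group plus upper-quartile cytokine count."""

    participant: str
    group: str
    uq_count: int


def count_upper_quartile(
    panel: OmicLayerTable, strict: bool = True, quantile_method: str = "linear"
) -> pd.Series:
    """Number of panel cytokines above the cohort 75th percentile, per participant.

    The 75th percentile is the linear-interpolation sample quantile by default;
    ``strict`` counts values strictly above it (the default convention), else
    at-or-above.
    """
    values = panel.values
    if values.shape[0] < 4:
        raise ValueError("upper quartile ill-defined with fewer than 4 participants")
    q75 = values.quantile(0.75, axis=0, interpolation=quantile_method)
    if strict:
        above = values.gt(q75, axis=1)
    else:
        above = values.ge(q75, axis=1)
    return above.sum(axis=1).astype(int)


_GROUP_NAMES = {
    1: ["low"],
    2: ["low", "high"],
    3: ["low", "medium", "high"],
}


def cluster_inflammation_groups(
    panel: OmicLayerTable,
    k: int = 3,
    *,
    log_transform: bool = True,
    standardize: bool = True,
    metric: str = "euclidean",
    linkage: str = "ward",
) -> list[InflammationAssignment]:
    """Agglomerative clustering of participants into k inflammation groups.

    The panel is log2-transformed and per-feature z-scored (both optional),
    participants are clustered (Euclidean/Ward by default) and the tree is cut
    into ``k`` clusters. Clusters are ranked by mean upper-quartile cytokine
    count (ties broken by mean standardized cytokine level) and labeled
    low ... high in ascending order, so labels do not depend on cluster index
    or participant order.
    """
    n = panel.values.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of participants ({n})")
    X = panel.values.to_numpy(dtype=float)
    if log_transform:
        if not (X > 0).all():
            raise ValueError("log transform requires strictly positive panel values")
        X = np.log2(X)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        if (sd == 0).any():
            const = [panel.features[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant cytokines cannot be standardized: {const}")
        X = (X - X.mean(axis=0)) / sd
    if k == 1:
        cluster_ids = np.ones(n, dtype=int)
    else:
        Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
        cluster_ids = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    uq = count_upper_quartile(panel)
    uq_arr = uq.to_numpy()
    # rank clusters low -> high by mean uq_count, tie-break mean z-scored level
    order_keys = []
    for cid in np.unique(cluster_ids):
        members = cluster_ids == cid
        order_keys.append((uq_arr[members].mean(), X[members].mean(), cid))
    ranked = [cid for _, _, cid in sorted(order_keys)]
    names = _GROUP_NAMES.get(k, [f"level_{i + 1}" for i in range(k)])
    label_of = {cid: names[rank] for rank, cid in enumerate(ranked)}
    out = [
        InflammationAssignment(p, label_of[cid], int(c))
        for p, cid, c in zip(panel.participants, cluster_ids, uq_arr)
    ]
    sizes = pd.Series([a.group for a in out]).value_counts().to_dict()
    log.info("inflammation clustering: k=%d, group sizes %s", k, sizes)
    return out


def assignments_to_frame(assignments: list[InflammationAssignment]) -> pd.DataFrame:
    """Tidy frame (participant index, columns group/uq_count) for export."""
    return pd.DataFrame(
        {"group": [a.group for a in assignments], "uq_count": [a.uq_count for a in assignments]},
        index=pd.Index([a.participant for a in assignments], name="participant"),
    )


def group_summary(assignments: list[InflammationAssignment]) -> pd.DataFrame:
    """Per-group size and uq_count median/range (Table-1-style summary)."""
    df = assignments_to_frame(assignments)
    rows = []
    for g, sub in df.groupby("group", sort=False):
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "uq_median": float(sub["uq_count"].median()),
                "uq_min": int(sub["uq_count"].min()),
                "uq_max": int(sub["uq_count"].max()),
            }
        )
    order = {"low": 0, "medium": 1, "high": 2}
    rows.sort(key=lambda r: order.get(r["group"], 99))
    return pd.DataFrame(rows).set_index("group")


@dataclass(frozen=True)
class AmselRecord:
    """Amsel bacterial-vaginosis call for one participant.

    ``bv_positive`` is True iff at least 3 of the 4 clinical criteria (clue
    cells, positive whiff test, pH > 4.5, abnormal discharge) are present;
    None marks an indeterminate record (a missing criterion).
    """

    participant: str
    clue_cells: bool | None
    whiff_positive: bool | None
    ph_above_4_5: bool | None
    abnormal_discharge: bool | None
    bv_positive: bool | None = None


def call_amsel_bv(record: AmselRecord) -> AmselRecord:
    """Apply the 3-of-4 Amsel rule; missing criteria yield an indeterminate call."""
    criteria = (
        record.clue_cells,
        record.whiff_positive,
        record.ph_above_4_5,
        record.abnormal_discharge,
    )
    if any(c is None for c in criteria):
        log.warning("Amsel call indeterminate for %s (missing criterion)", record.participant)
        return AmselRecord(
            record.participant, *criteria, bv_positive=None
        )
    return AmselRecord(record.participant, *criteria, bv_positive=sum(criteria) >= 3)
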