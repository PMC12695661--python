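"""Fold-change regulation classes, small-class merging and reproducibility.

The standard taxonomy on the linear fold change f (treatment/control):

    HU  f >= 2           IU  1.5 <= f < 2      SU  1.3 <= f < 1.5
    NC  1/1.2 < f < 1.2
    SD  1/1.5 <= f < 1/1.3    ID  1/2 <= f < 1/1.5    HD  f < 1/2
    Others  the deliberate 1.2..1.3-fold slivers on both sides

Down-class boundaries are stated in fold-down language (d = 1/f): SD is
1.3 < d <= 1.5, ID is 1.5 < d <= 2, HD is d > 2, so the inclusive edge sits
on the weaker side of each down class. The f = 1/1.2 boundary (d exactly
1.2) is assigned to Others, symmetric with f = 1.2 on the up side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

STANDARD_ORDER = ["HU", "IU", "SU", "NC", "SD", "ID", "HD"]
UP_CLASSES = ["HU", "IU", "SU"]
DOWN_CLASSES = ["SD", "ID", "HD"]

SCHEMES = ("standard", "a485", "npc_rad21")


@dataclass(frozen=True)
class ClassScheme:
    """A named fold-change class taxonomy."""

    name: str

    def __post_init__(self):
        if self.name not in SCHEMES:
            raise ValueError(f"unknown class scheme {self.name!r}")


def assign_class(fc_linear: float, scheme: str = "standard") -> str:
    """Class label for one linear fold change.

    For the ``a485`` scheme classes are defined on the fold-down d = 1/f:
    ND d <= 1.2, ID 1.5 < d <= 2, HD1 2 < d <= 4, HD2 d > 4; the deliberate
    1.2 < d <= 1.5 gap is reported as ``Others``.
    """
    if fc_linear is None or not math.isfinite(fc_linear) or fc_linear <= 0:
        raise ValueError(f"fold change must be finite and positive, got {fc_linear!r}")
    f = float(fc_linear)
    if scheme == "standard":
        if f >= 2.0:
            return "HU"
        if f >= 1.5:
            return "IU"
        if f >= 1.3:
            return "SU"
        if f >= 1.2:
            return "Others"
        if f > 1 / 1.2:
            return "NC"
        if f >= 1 / 1.3:
            return "Others"
        if f >= 1 / 1.5:
            return "SD"
        if f >= 0.5:
            return "ID"
        return "HD"
    if scheme == "a485":
        d = 1.0 / f
        if d <= 1.2:
            return "ND"
        if d <= 1.5:
            return "Others"
        if d <= 2.0:
            return "ID"
        if d <= 4.0:
            return "HD1"
        return "HD2"
    raise ValueError(f"assign_class does not handle scheme {scheme!r}")


def assign_classes(fc_linear: pd.Series, scheme: str = "standard") -> pd.Series:
    """Vectorized :func:`assign_class`; NaN fold changes raise."""
    if fc_linear.isna().any():
        bad = fc_linear.index[fc_linear.isna()].tolist()
        raise ValueError(f"NaN fold change for genes {bad[:5]}")
    return fc_linear.map(lambda f: assign_class(f, scheme)).rename("class")


def classify_table(
    adjusted_log2fc: pd.Series,
    expressed: pd.Series,
    scheme: str = "standard",
) -> pd.DataFrame:
    """RegulationTable: one label per expressed gene, ``none`` otherwise."""
    expressed = expressed.reindex(adjusted_log2fc.index).fillna(False).astype(bool)
    usable = expressed & np.isfinite(adjusted_log2fc)
    labels = pd.Series("none", index=adjusted_log2fc.index, dtype=object, name="class")
    fc = np.exp2(adjusted_log2fc[usable])
    labels[usable] = assign_classes(fc, scheme=scheme)
    grouping = pd.Series("none", index=labels.index, dtype=object)
    grouping[labels.isin(DOWN_CLASSES + ["HD1", "HD2"])] = "down"
    grouping[labels.isin(UP_CLASSES)] = "up"
    grouping[labels == "NC"] = "NC"
    grouping[labels == "ND"] = "NC"
    return pd.DataFrame({"class": labels, "grouping": grouping})


def average_npc_classes(
    fc_early: pd.Series,
    fc_late: pd.Series,
    gate_fold_down: float = 1.3,
) -> pd.DataFrame:
    """Two-time-point class call used for progenitor-cell contrasts.

    ``fc_early``/``fc_late`` are linear fold changes (treatment/control).
    A gene must be more than ``gate_fold_down``-fold down at BOTH time
    points; the label then follows the average fold-down: > 2 HD,
    (1.5, 2] ID, (1.3, 1.5] SD. Genes failing the gate (or with a missing
    time point) are unclassified with the reason recorded.
    """
    idx = fc_early.index.union(fc_late.index)
    e = fc_early.reindex(idx)
    l = fc_late.reindex(idx)
    label = pd.Series("unclassified", index=idx, dtype=object, name="class")
    reason = pd.Series("", index=idx, dtype=object, name="reason")
    missing = e.isna() | l.isna()
    reason[missing] = "missing_time_point"
    d_e = 1.0 / e
    d_l = 1.0 / l
    gated = ~missing & (d_e > gate_fold_down) & (d_l > gate_fold_down)
    reason[~missing & ~gated] = "gate_failed"
    avg_d = (d_e + d_l) / 2.0
    label[gated & (avg_d > 2.0)] = "HD"
    label[gated & (avg_d > 1.5) & (avg_d <= 2.0)] = "ID"
    label[gated & (avg_d > gate_fold_down) & (avg_d <= 1.5)] = "SD"
    return pd.DataFrame({"class": label, "reason": reason})


def merge_small_classes(labels: pd.Series, min_n: int = 10) -> pd.DataFrame:
    """Merge classes with fewer than ``min_n`` genes into adjacent classes.

    Merging happens within the up side (HU, IU, SU) and the down side
    (SD, ID, HD) independently, moving toward NC; the innermost group of a
    side merges outward when small. Iterates until every surviving group on
    a side has >= min_n genes or the side has collapsed to a single group.
    Joint names follow class order, e.g. ``HU + IU``. NC and Others never
    merge. Returns the original labels plus a ``merged_class`` column.
    """
    counts = labels.value_counts()

    def merge_side(side_outer_to_inner: list[str]) -> dict[str, str]:
        groups: list[list[str]] = [[c] for c in side_outer_to_inner if counts.get(c, 0) > 0]

        def n_of(grp):
            return sum(int(counts.get(c, 0)) for c in grp)

        changed = True
        while changed and len(groups) > 1:
            changed = False
            for i, grp in enumerate(groups):
                if n_of(grp) < min_n:
                    # merge toward NC (next inner group); innermost merges outward
                    j = i + 1 if i + 1 < len(groups) else i - 1
                    groups[min(i, j)] = groups[min(i, j)] + groups[max(i, j)]
                    del groups[max(i, j)]
                    changed = True
                    break
        mapping = {}
        for grp in groups:
            name = " + ".join(sorted(grp, key=STANDARD_ORDER.index))
            for c in grp:
                mapping[c] = name
        return mapping

    mapping: dict[str, str] = {}
    mapping.update(merge_side(["HU", "IU", "SU"]))
    mapping.update(merge_side(["HD", "ID", "SD"]))
    merged = labels.map(lambda c: mapping.get(c, c)).rename("merged_class")
    return pd.DataFrame({"class": labels, "merged_class": merged})


def reproducibility_filter(
    initial_log2fc: pd.Series,
    replicate_log2fc: pd.DataFrame,
    direction: str = "down",
    fc_threshold: float = 1.3,
    per_replicate_threshold: float | None = None,
    min_fraction: float = 0.5,
) -> pd.Series:
    """Replicate-reproducibility verdict per gene.

    A gene passes when its initial fold change is at least ``fc_threshold``
    in the stated direction AND at least ``ceil(min_fraction * n)`` of the
    replicate pairs show a fold change of at least the per-replicate
    threshold (default: same as the initial gate) in the same direction.
    """
    if replicate_log2fc.shape[1] == 0:
        raise ValueError("no replicate fold changes supplied")
    if direction not in {"down", "up"}:
        raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")
    thr = math.log2(fc_threshold)
    rep_thr = math.log2(per_replicate_threshold or fc_threshold)
    reps = replicate_log2fc.reindex(initial_log2fc.index)
    if direction == "down":
        initial_pass = initial_log2fc <= -thr
        rep_pass = reps <= -rep_thr
    else:
        initial_pass = initial_log2fc >= thr
        rep_pass = reps >= rep_thr
    need = math.ceil(min_fraction * replicate_log2fc.shape[1])
    return (initial_pass & (rep_pass.sum(axis=1) >= need)).rename("reproducible")


def consistency_fraction(
    replicate_log2fc: pd.DataFrame,
    gene_set,
    min_replicates: int,
    threshold: float = 1.3,
    direction: str = "down",
) -> float:
    """Fraction of the gene set regulated in >= min_replicates replicates."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    reps = replicate_log2fc.loc[gene_set]
    thr = math.log2(threshold)
    hits = (reps <= -thr) if direction == "down" else (reps >= thr)
    return float((hits.sum(axis=1) >= min_replicates).mean())


def call_uastrx_up(
    antisense_adjusted_log2fc: pd.Series,
    sense_expressed: pd.Series,
    antisense_retained: pd.Series,
    threshold_fc: float = 2.0,
) -> pd.DataFrame:
    """Upstream-antisense upregulation candidates (pending manual curation).

    Candidates need an antisense fold change of at least ``threshold_fc``
    up, an expressed sense transcript, and must have survived the antisense
    low-count filter. The output is explicitly marked as candidates; the
    manual genome-track curation step is not automated.
    """
    idx = antisense_adjusted_log2fc.index
    sense_expressed = sense_expressed.reindex(idx).fillna(False).astype(bool)
    antisense_retained = antisense_retained.reindex(idx).fillna(False).astype(bool)
    up = antisense_adjusted_log2fc >= math.log2(threshold_fc)
    candidate = up & sense_expressed & antisense_retained
    out = pd.DataFrame(
        {
            "antisense_adjusted_log2fc": antisense_adjusted_log2fc,
            "sense_expressed": sense_expressed,
            "antisense_retained": antisense_retained,
            "candidate": candidate,
            "status": np.where(candidate, "candidate_pending_curation", ""),
        }
    )
    return out[out["candidate"]].copy()
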