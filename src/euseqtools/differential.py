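"""Median-of-ratios normalization and asymmetry-corrected fold changes.

Size factors follow the median-of-ratios construction: a geometric-mean
pseudo-reference over genes with all-positive counts, then the per-sample
median ratio to that reference. Fold changes are ratios of condition means
of normalized counts; the median log2FC over expressed genes is subtracted
so that an asymmetric regulation profile does not bias unregulated genes
away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DifferentialResult:
    """Per-contrast differential table plus normalization metadata."""

    table: pd.DataFrame  # raw_log2fc, adjusted_log2fc, undefined_reason
    size_factors: pd.Series
    asymmetry_median: float
    per_replicate: pd.DataFrame | None = None
    per_replicate_medians: dict = field(default_factory=dict)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Single-sample input gets a unit factor. Raises when no gene has
    positive counts in every sample.
    """
    if counts.shape[1] == 1:
        return pd.Series(1.0, index=counts.columns)
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in all samples; median-of-ratios is "
            "undefined (consider a pseudo-count on the input)"
        )
    log_ref = np.log(mat[all_pos]).mean(axis=1)  # geometric mean per gene
    ratios = np.log(mat[all_pos]) - log_ref[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return pd.Series(s, index=counts.columns)


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts.div(size_factors, axis=1)


def compute_adjusted_log2fc(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    sample_sheet: pd.DataFrame,
    expressed: pd.Series,
) -> DifferentialResult:
    """Raw and asymmetry-adjusted log2 fold changes for one contrast.

    raw_log2fc = log2(mean normalized treatment / mean normalized control);
    the median raw log2FC over expressed genes (``asymmetry_median``) is
    subtracted from every gene. Genes with a zero condition mean get NaN
    with an ``undefined_reason`` instead of +-inf.
    """
    ctrl = sample_sheet.loc[sample_sheet["condition"] == "control", "sample"].tolist()
    treat = sample_sheet.loc[sample_sheet["condition"] == "treatment", "sample"].tolist()
    if not ctrl or not treat:
        raise ValueError("contrast needs at least one control and one treatment sample")
    norm = normalize_counts(counts, size_factors)
    c_mean = norm[ctrl].mean(axis=1)
    t_mean = norm[treat].mean(axis=1)

    raw = pd.Series(np.nan, index=counts.index, name="raw_log2fc")
    ok = (c_mean > 0) & (t_mean > 0)
    raw[ok] = np.log2(t_mean[ok] / c_mean[ok])
    reason = pd.Series("", index=counts.index, dtype=object)
    reason[c_mean == 0] = "zero_control_mean"
    reason[(c_mean > 0) & (t_mean == 0)] = "zero_treatment_mean"

    expressed = expressed.reindex(counts.index).fillna(False).astype(bool)
    exp_vals = raw[expressed & np.isfinite(raw)]
    if len(exp_vals) == 0:
        raise ValueError("expressed set empty or entirely undefined; cannot center")
    m = float(np.median(exp_vals))
    table = pd.DataFrame(
        {
            "raw_log2fc": raw,
            "adjusted_log2fc": raw - m,
            "mean_norm_control": c_mean,
            "mean_norm_treatment": t_mean,
            "expressed": expressed,
            "undefined_reason": reason,
        }
    )
    return DifferentialResult(table=table, size_factors=size_factors, asymmetry_median=m)


def per_replicate_log2fc(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    pairing: list[tuple[str, str]],
    expressed: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Asymmetry-adjusted log2FC per matched (control, treatment) pair.

    For each pair the per-gene log2 of the normalized ratio is computed and
    the per-pair median over expressed genes subtracted. Ratios with a zero
    count on either side are NaN (flagged undefined). Returns the gene ×
    pair matrix and the per-pair medians.
    """
    if not pairing:
        raise ValueError("no replicate pairs given")
    known = set(counts.columns)
    orphans = [s for pair in pairing for s in pair if s not in known]
    if orphans:
        raise ValueError(f"unpaired/unknown samples in pairing: {orphans}")
    norm = normalize_counts(counts, size_factors)
    expressed = expressed.reindex(counts.index).fillna(False).astype(bool)
    out = {}
    medians = {}
    for ctrl, treat in pairing:
        pair_name = f"{treat}_vs_{ctrl}"
        c = norm[ctrl]
        t = norm[treat]
        lfc = pd.Series(np.nan, index=counts.index)
        ok = (c > 0) & (t > 0)
        lfc[ok] = np.log2(t[ok] / c[ok])
        vals = lfc[expressed & np.isfinite(lfc)]
        if len(vals) == 0:
            raise ValueError(f"pair {pair_name}: no expressed gene with defined ratio")
        med = float(np.median(vals))
        medians[pair_name] = med
        out[pair_name] = lfc - med
    return pd.DataFrame(out), medians


def correlate(fc_a: pd.Series, fc_b: pd.Series, method: str = "pearson") -> tuple[float, int]:
    """Pearson correlation on the shared finite support; returns (r, n)."""
    if method != "pearson":
        raise ValueError(f"unsupported correlation method {method!r}")
    a, b = fc_a.align(fc_b, join="inner")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError(f"need at least 3 shared finite values, got {len(a)}")
    r = stats.pearsonr(a.to_numpy(), b.to_numpy()).statistic
    return float(r), int(len(a))
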