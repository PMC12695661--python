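"""Strand-aware fragment counting, TPM, and expression filters.

Counting rule: a fragment is counted for a window when it overlaps it by at
least one bp, matches the required strand for the counting mode, and does
not touch any exclusion region. A fragment overlapping several genes'
windows is counted once per window.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

LOW_COUNT_MAX_MEAN = 20.0  # sense low-count exclusion (mean reads per condition)
ANTISENSE_LOW_COUNT_MAX_MEAN = 10.0
EXPRESSED_MIN_MEAN_TPM = 15.0

VALID_STRANDS = {"+", "-"}


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    m_starts, m_ends = [], []
    for s, e in zip(starts, ends):
        if m_ends and s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.asarray(m_starts), np.asarray(m_ends)


def _overlaps_any(
    starts: np.ndarray, ends: np.ndarray, m_starts: np.ndarray, m_ends: np.ndarray
) -> np.ndarray:
    """Vectorized: does [start, end) intersect any merged interval?"""
    if len(m_starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    # candidate merged interval: the last one starting before the fragment end
    idx = np.searchsorted(m_starts, ends, side="left") - 1
    hit = idx >= 0
    hit[hit] = m_ends[idx[hit]] > starts[hit]
    return hit


def count_fragments(
    fragments_by_sample: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    exclusion: pd.DataFrame | None = None,
    mode: str = "sense",
) -> tuple[pd.DataFrame, dict]:
    """Count fragments per window per sample.

    ``fragments_by_sample`` maps sample name to a BED6-like frame (chrom,
    start, end, strand; 0-based half-open). ``windows`` has gene_id, chrom,
    start, end, strand. ``mode``: sense (fragment strand == window strand),
    antisense (opposite), or unstranded.

    Returns the gene-by-sample integer count matrix and a report with
    rejected/ignored record tallies.
    """
    if mode not in {"sense", "antisense", "unstranded"}:
        raise ValueError(f"unknown counting mode {mode!r}")

    excl_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if exclusion is not None and len(exclusion) > 0:
        for chrom, grp in exclusion.groupby("chrom"):
            excl_by_chrom[chrom] = _merge_intervals(
                grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)
            )

    window_chroms = set(windows["chrom"].unique())
    gene_ids = windows["gene_id"].to_numpy()
    counts = pd.DataFrame(
        0, index=pd.Index(gene_ids, name="gene_id"), columns=list(fragments_by_sample)
    )
    report = {"rejected_bad_strand": {}, "ignored_unknown_chrom": {}, "excluded_fragments": {}}

    for sample, frags in fragments_by_sample.items():
        n_bad_strand = n_unknown = n_excluded = 0
        col = np.zeros(len(windows), dtype=np.int64)
        if len(frags) > 0:
            if mode != "unstranded":
                ok = frags["strand"].isin(VALID_STRANDS)
                n_bad_strand = int((~ok).sum())
                frags = frags[ok]
            for chrom, grp in frags.groupby("chrom"):
                if chrom not in window_chroms:
                    n_unknown += len(grp)
                    continue
                fs = grp["start"].to_numpy(np.int64)
                fe = grp["end"].to_numpy(np.int64)
                fstrand = grp["strand"].to_numpy()
                if chrom in excl_by_chrom:
                    ms, me = excl_by_chrom[chrom]
                    excluded = _overlaps_any(fs, fe, ms, me)
                    n_excluded += int(excluded.sum())
                    fs, fe, fstrand = fs[~excluded], fe[~excluded], fstrand[~excluded]
                wmask = (windows["chrom"] == chrom).to_numpy()
                widx = np.flatnonzero(wmask)
                ws = windows["start"].to_numpy(np.int64)[wmask]
                we = windows["end"].to_numpy(np.int64)[wmask]
                wstrand = windows["strand"].to_numpy()[wmask]
                if mode == "unstranded":
                    strand_groups = {None: np.ones(len(fs), dtype=bool)}
                else:
                    strand_groups = {s: fstrand == s for s in VALID_STRANDS}
                for s, fmask in strand_groups.items():
                    starts_sorted = np.sort(fs[fmask])
                    ends_sorted = np.sort(fe[fmask])
                    if s is None:
                        sel = np.ones(len(widx), dtype=bool)
                    elif mode == "sense":
                        sel = wstrand == s
                    else:  # antisense: fragment strand opposite the window strand
                        sel = wstrand == ("-" if s == "+" else "+")
                    if not sel.any() or len(starts_sorted) == 0:
                        continue
                    # overlap iff frag.start < window.end and frag.end > window.start
                    n_over = np.searchsorted(starts_sorted, we[sel], side="left")
                    n_left = np.searchsorted(ends_sorted, ws[sel], side="right")
                    col[widx[sel]] += n_over - n_left
        counts[sample] = col
        report["rejected_bad_strand"][sample] = n_bad_strand
        report["ignored_unknown_chrom"][sample] = n_unknown
        report["excluded_fragments"][sample] = n_excluded
    return counts, report


def quantify_antisense(
    fragments_by_sample: Mapping[str, pd.DataFrame],
    genes: pd.DataFrame,
    exclusion: pd.DataFrame | None = None,
    strand_specific: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Count fragments in upstream antisense windows.

    Requires strand-specific libraries; the antisense windows already carry
    the strand opposite the gene, so counting is sense with respect to the
    window's own strand.
    """
    if not strand_specific:
        raise ValueError(
            "antisense quantification requires strand-specific libraries; "
            "non-strand-specific data cannot separate upstream antisense signal"
        )
    windows = genes[["gene_id", "chrom", "antisense_start", "antisense_end", "antisense_strand"]]
    windows = windows.rename(
        columns={
            "antisense_start": "start",
            "antisense_end": "end",
            "antisense_strand": "strand",
        }
    )
    return count_fragments(fragments_by_sample, windows, exclusion=exclusion, mode="sense")


def compute_tpm(counts: pd.DataFrame, window_lengths: pd.Series) -> pd.DataFrame:
    """TPM with the counting-window length as the per-gene length.

    ``TPM_ij = (c_ij / L_i[kb]) / sum_k (c_kj / L_k[kb]) * 1e6``; columns sum
    to 1e6. Raises on an all-zero sample.
    """
    lengths = window_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("window_lengths must be positive and cover every gene")
    rate = counts.div(lengths / 1_000.0, axis=0)
    denom = rate.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s), TPM undefined: {list(zero.index)}")
    return rate.div(denom, axis=1) * 1e6


def apply_expression_filters(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    low_count_max_mean: float = LOW_COUNT_MAX_MEAN,
    expressed_min_mean_tpm: float = EXPRESSED_MIN_MEAN_TPM,
) -> pd.DataFrame:
    """Per-gene low-count exclusion and expressed flags for one contrast.

    A gene is low-count excluded iff its mean raw count is <= the threshold
    in BOTH conditions; expressed iff retained and the average of the two
    condition-mean TPMs exceeds the TPM threshold.
    """
    for cond in ("control", "treatment"):
        if cond not in set(sample_sheet["condition"]):
            raise ValueError(f"sample sheet has no {cond!r} samples")
    ctrl = sample_sheet.loc[sample_sheet["condition"] == "control", "sample"].tolist()
    treat = sample_sheet.loc[sample_sheet["condition"] == "treatment", "sample"].tolist()
    mean_count_ctrl = counts[ctrl].mean(axis=1)
    mean_count_treat = counts[treat].mean(axis=1)
    mean_tpm_ctrl = tpm[ctrl].mean(axis=1)
    mean_tpm_treat = tpm[treat].mean(axis=1)
    low = (mean_count_ctrl <= low_count_max_mean) & (mean_count_treat <= low_count_max_mean)
    expressed = ~low & ((mean_tpm_ctrl + mean_tpm_treat) / 2.0 > expressed_min_mean_tpm)
    return pd.DataFrame(
        {
            "mean_count_control": mean_count_ctrl,
            "mean_count_treatment": mean_count_treat,
            "mean_tpm_control": mean_tpm_ctrl,
            "mean_tpm_treatment": mean_tpm_treat,
            "low_count_excluded": low,
            "expressed": expressed,
        }
    )
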