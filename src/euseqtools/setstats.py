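"""Overlap enrichment, class-wise distribution tests and proximity controls."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContingencyResult:
    a: int  # in set_a and set_b
    b: int  # in set_a only
    c: int  # in set_b only
    d: int  # in neither
    odds_ratio: float  # sample OR (a*d)/(b*c); inf/0 flagged, not corrected
    p: float
    fraction_a_in_b: float
    fraction_b_in_a: float
    fold_enrichment: float  # conditional freq of A among B vs among not-B
    zero_cell: bool


def overlap_enrichment(set_a, set_b, universe) -> ContingencyResult:
    """Two-sided Fisher exact test of gene-set overlap within a universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("set_a and set_b must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    zero_cell = 0 in (a, b, c, d)
    if b * c == 0:
        odds = math.inf if a * d > 0 else (0.0 if a * d == 0 and (b or c) else math.nan)
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    frac_ab = a / len(set_a) if set_a else math.nan
    frac_ba = a / len(set_b) if set_b else math.nan
    # conditional frequency of membership in A inside vs outside B
    in_b = a / (a + c) if (a + c) else math.nan
    out_b = b / (b + d) if (b + d) else math.nan
    fold = fold_enrichment(in_b, out_b).ratio if out_b and not math.isnan(out_b) else math.inf
    return ContingencyResult(a, b, c, d, odds, p, frac_ab, frac_ba, fold, zero_cell)


@dataclass
class FoldEnrichment:
    ratio: float
    presented: float  # integer "x-fold" presentation (floor for ratios >= 1)


def fold_enrichment(frac_1: float, frac_2: float) -> FoldEnrichment:
    """Ratio of two proportions with an integer-fold presentation value.

    The presentation value follows the usual "x-fold more frequent" style:
    the integer part of the ratio for ratios >= 1 (127.7 presents as
    127-fold), the full-precision ratio below 1.
    """
    if frac_2 == 0:
        warnings.warn("fold_enrichment with zero denominator -> inf", stacklevel=2)
        return FoldEnrichment(math.inf, math.inf)
    ratio = frac_1 / frac_2
    presented = float(math.floor(ratio)) if ratio >= 1 else ratio
    return FoldEnrichment(ratio, presented)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def class_distribution_test(
    values_by_class: dict[str, np.ndarray],
    reference_label: str,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U of every class against a reference, with BH.

    Small samples without ties use the exact distribution; larger or tied
    samples use the midrank normal approximation with continuity
    correction (scipy's auto method). Degenerate comparisons where every
    value in both groups is identical get p = 1 with a flag.
    """
    if reference_label not in values_by_class:
        raise ValueError(f"reference class {reference_label!r} missing")
    ref = np.asarray(values_by_class[reference_label], dtype=float)
    if len(ref) == 0:
        raise ValueError("reference class is empty")
    rows = []
    for label, vals in values_by_class.items():
        if label == reference_label:
            continue
        vals = np.asarray(vals, dtype=float)
        if len(vals) == 0:
            raise ValueError(f"class {label!r} is empty")
        combined = np.concatenate([vals, ref])
        if np.all(combined == combined[0]):
            rows.append(
                {"class": label, "n": len(vals), "U": len(vals) * len(ref) / 2.0,
                 "p": 1.0, "degenerate": True}
            )
            continue
        res = stats.mannwhitneyu(vals, ref, alternative="two-sided", method="auto")
        rows.append(
            {"class": label, "n": len(vals), "U": float(res.statistic),
             "p": float(res.pvalue), "degenerate": False}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def ks_two_sample(values_a, values_b) -> tuple[float, float]:
    """Two-sided KS statistic and asymptotic p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def proximity_enrichment(
    feature_positions: pd.DataFrame,
    genes: pd.DataFrame,
    gene_set,
    window_bp: int = 50_000,
    n_controls: int = 1_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Feature density near a gene set versus random same-size gene draws.

    ``feature_positions``: columns chrom, pos (e.g. peak summits).
    ``genes``: gene_id, chrom, tss (1-based). Counts features with a
    position within +-window_bp of each TSS; the empirical p-value is the
    add-one fraction of control draws whose mean count reaches the
    observed mean.
    """
    if n_controls < 100:
        warnings.warn(
            f"n_controls={n_controls} gives coarse empirical p resolution", stacklevel=2
        )
    gene_set = list(gene_set)
    all_ids = genes["gene_id"].tolist()
    if len(gene_set) > len(all_ids):
        raise ValueError("gene_set larger than the gene universe")
    by_chrom = {
        chrom: np.sort(grp["pos"].to_numpy(np.int64))
        for chrom, grp in feature_positions.groupby("chrom")
    }
    tss0 = genes["tss"].to_numpy(np.int64) - 1
    chroms = genes["chrom"].to_numpy()
    counts = np.zeros(len(genes), dtype=np.int64)
    for chrom, pos in by_chrom.items():
        mask = chroms == chrom
        lo = np.searchsorted(pos, tss0[mask] - window_bp, side="left")
        hi = np.searchsorted(pos, tss0[mask] + window_bp, side="right")
        counts[mask] = hi - lo
    per_gene = pd.Series(counts, index=genes["gene_id"].to_numpy())
    observed = per_gene.loc[gene_set].to_numpy()
    obs_mean = float(observed.mean())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    control_means = np.empty(n_controls)
    vals = per_gene.to_numpy()
    for i in range(n_controls):
        draw = rng.choice(len(vals), size=len(gene_set), replace=False)
        control_means[i] = vals[draw].mean()
    p = (1 + int((control_means >= obs_mean).sum())) / (n_controls + 1)
    return {
        "observed_counts": observed,
        "observed_mean": obs_mean,
        "control_means": control_means,
        "empirical_p": float(p),
    }
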