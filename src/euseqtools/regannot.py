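"""Promoter-centric peak geometry, motif orientation and signal analyses.

Distances are signed in gene-strand coordinates: negative means upstream of
the TSS with respect to the direction of transcription, regardless of which
genomic strand the gene lies on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import differential

PROMOTER_NESTED_WINDOWS = (2_000, 400, 200)
MOTIF_SCAN_HALF_WIDTH = 100
DEFAULT_PWM_SCORE_FRACTION = 0.8
RAD21_CTCF_PAIRING_BP = 100

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _signed_distance(summit: np.ndarray, tss0: int, strand: str) -> np.ndarray:
    d = summit - tss0
    return d if strand == "+" else -d


def annotate_promoter_peaks(
    ctcf_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    rad21_peaks: pd.DataFrame | None = None,
    pairing_distance_bp: int = RAD21_CTCF_PAIRING_BP,
) -> pd.DataFrame:
    """Per-gene nearest CTCF summit geometry around the TSS.

    ``ctcf_peaks`` / ``rad21_peaks`` need chrom, summit and signal_value
    columns (see :func:`euseqtools.io.read_narrowpeak`). Reports the signed
    distance of the nearest summit, nested promoter-window membership
    (any summit within each window), the peak height, and the RAD21/CTCF
    signal ratio for summit pairs within ``pairing_distance_bp``.
    """
    if "summit" not in ctcf_peaks.columns:
        raise ValueError("CTCF peaks need a 'summit' column (absolute 0-based position)")
    ctcf_by_chrom = {
        chrom: grp.sort_values("summit").reset_index(drop=True)
        for chrom, grp in ctcf_peaks.groupby("chrom")
    }
    rad21_by_chrom = {}
    if rad21_peaks is not None and len(rad21_peaks) > 0:
        rad21_by_chrom = {
            chrom: (grp["summit"].to_numpy(np.int64), grp["signal_value"].to_numpy(float))
            for chrom, grp in rad21_peaks.sort_values("summit").groupby("chrom")
        }
    rows = []
    for g in genes.itertuples(index=False):
        tss0 = int(g.tss) - 1
        rec = {
            "gene_id": g.gene_id,
            "nearest_summit_distance": np.nan,
            "peak_height": np.nan,
            "in_2kb": False,
            "in_400bp": False,
            "in_200bp": False,
            "rad21_ctcf_ratio": np.nan,
        }
        grp = ctcf_by_chrom.get(g.chrom)
        if grp is not None:
            summits = grp["summit"].to_numpy(np.int64)
            dist = _signed_distance(summits, tss0, g.strand)
            k = int(np.argmin(np.abs(dist)))
            rec["nearest_summit_distance"] = int(dist[k])
            rec["peak_height"] = float(grp["signal_value"].iloc[k])
            absd = np.abs(dist)
            rec["in_2kb"] = bool((absd <= 2_000).any())
            rec["in_400bp"] = bool((absd <= 400).any())
            rec["in_200bp"] = bool((absd <= 200).any())
            chrom_rad21 = rad21_by_chrom.get(g.chrom)
            if chrom_rad21 is not None:
                r_summits, r_signal = chrom_rad21
                nearest_summit = int(summits[k])
                j = np.searchsorted(r_summits, nearest_summit)
                best = None
                for jj in (j - 1, j):
                    if 0 <= jj < len(r_summits):
                        gap = abs(int(r_summits[jj]) - nearest_summit)
                        if gap <= pairing_distance_bp and (best is None or gap < best[0]):
                            best = (gap, jj)
                if best is not None:
                    rec["rad21_ctcf_ratio"] = float(r_signal[best[1]]) / float(
                        grp["signal_value"].iloc[k]
                    )
        rows.append(rec)
    return pd.DataFrame(rows)


def distal_rad21_ctcf_ratios(
    ctcf_peaks: pd.DataFrame,
    rad21_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    min_tss_distance_bp: int = 200,
    pairing_distance_bp: int = RAD21_CTCF_PAIRING_BP,
) -> pd.Series:
    """RAD21/CTCF signal ratios for CTCF peaks away from every TSS."""
    tss_by_chrom = {
        chrom: np.sort(grp["tss"].to_numpy(np.int64) - 1)
        for chrom, grp in genes.groupby("chrom")
    }
    rad21_by_chrom = {
        chrom: (grp["summit"].to_numpy(np.int64), grp["signal_value"].to_numpy(float))
        for chrom, grp in rad21_peaks.sort_values("summit").groupby("chrom")
    }
    ratios = []
    for p in ctcf_peaks.itertuples(index=False):
        tss = tss_by_chrom.get(p.chrom)
        summit = int(p.summit)
        if tss is not None and len(tss):
            i = np.searchsorted(tss, summit)
            near = min(
                abs(int(tss[j]) - summit) for j in (i - 1, i) if 0 <= j < len(tss)
            )
            if near <= min_tss_distance_bp:
                continue
        chrom_rad21 = rad21_by_chrom.get(p.chrom)
        if chrom_rad21 is None:
            continue
        r_summits, r_signal = chrom_rad21
        j = np.searchsorted(r_summits, summit)
        for jj in (j - 1, j):
            if 0 <= jj < len(r_summits) and abs(int(r_summits[jj]) - summit) <= pairing_distance_bp:
                ratios.append(float(r_signal[jj]) / float(p.signal_value))
                break
    return pd.Series(ratios, name="rad21_ctcf_ratio")


# ---------------------------------------------------------------------------
# Motif orientation
# ---------------------------------------------------------------------------

@dataclass
class MotifScan:
    orientation: str  # forward / reverse / both / none, relative to the gene
    plus_hits: list[int]  # genomic-strand hit start offsets within the window
    minus_hits: list[int]


def _pssm_scores(pssm, seq: str) -> np.ndarray:
    if len(seq) < pssm.length:
        return np.array([])
    return np.asarray(pssm.calculate(seq), dtype=float).reshape(-1)

def scan_motif_strands(
    sequence: str,
    pwm,
    score_fraction: float = DEFAULT_PWM_SCORE_FRACTION,
) -> tuple[list[int], list[int]]:
    """Positions of PWM hits on the + and - strands of ``sequence``.

    The threshold is ``score_fraction`` of the maximum achievable log-odds
    score of the matrix.
    """
    pssm = pwm.pssm
    threshold = score_fraction * pssm.max
    seq = sequence.upper()
    fwd = _pssm_scores(pssm, seq)
    rev = _pssm_scores(pssm.reverse_complement(), seq)
    plus = [int(i) for i in np.flatnonzero(fwd >= threshold)] if fwd.size else []
    minus = [int(i) for i in np.flatnonzero(rev >= threshold)] if rev.size else []
    return plus, minus


def classify_motif_orientation(
    summit: int,
    chrom_seq: str,
    pwm,
    gene_strand: str,
    half_width: int = MOTIF_SCAN_HALF_WIDTH,
    score_fraction: float = DEFAULT_PWM_SCORE_FRACTION,
) -> MotifScan:
    """Motif orientation in summit +- half_width, relative to the gene.

    A hit on the gene's genomic strand is ``forward``; on the opposite
    strand ``reverse``; hits on both strands give ``both``. Windows
    extending past the contig are truncated with a warning.
    """
    if gene_strand not in {"+", "-"}:
        raise ValueError(f"invalid gene strand {gene_strand!r}")
    lo = summit - half_width
    hi = summit + half_width + 1
    if lo < 0 or hi > len(chrom_seq):
        warnings.warn(
            f"motif window [{lo}, {hi}) truncated to contig bounds", stacklevel=2
        )
        lo, hi = max(lo, 0), min(hi, len(chrom_seq))
    plus, minus = scan_motif_strands(chrom_seq[lo:hi], pwm, score_fraction)
    same = plus if gene_strand == "+" else minus
    opposite = minus if gene_strand == "+" else plus
    if same and opposite:
        orientation = "both"
    elif same:
        orientation = "forward"
    elif opposite:
        orientation = "reverse"
    else:
        orientation = "none"
    return MotifScan(orientation, plus, minus)


def annotate_motif_orientations(
    annotations: pd.DataFrame,
    genes: pd.DataFrame,
    genome: dict[str, str],
    pwm,
    max_summit_distance_bp: int = 400,
    score_fraction: float = DEFAULT_PWM_SCORE_FRACTION,
) -> pd.DataFrame:
    """Add a motif_orientation column for genes with a promoter peak.

    Only genes whose nearest summit lies within ``max_summit_distance_bp``
    of the TSS are scanned; others get ``none`` with no peak flagged NaN.
    """
    gene_info = genes.set_index("gene_id")
    out = annotations.copy()
    orientations = []
    for rec in out.itertuples(index=False):
        d = rec.nearest_summit_distance
        if not np.isfinite(d) or abs(d) > max_summit_distance_bp:
            orientations.append(None)
            continue
        g = gene_info.loc[rec.gene_id]
        tss0 = int(g["tss"]) - 1
        summit = tss0 + (int(d) if g["strand"] == "+" else -int(d))
        scan = classify_motif_orientation(
            summit, genome[g["chrom"]], pwm, g["strand"], score_fraction=score_fraction
        )
        orientations.append(scan.orientation)
    out["motif_orientation"] = orientations
    return out


def summarize_binding_positions(
    annotations: pd.DataFrame,
    class_labels: pd.Series,
    max_distance_bp: int = 400,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, list[str]]:
    """Per-class signed summit-distance distributions and medians.

    Restricted to genes whose nearest summit is within ``max_distance_bp``
    of the TSS. Classes with no bound genes are omitted and listed in the
    returned notes.
    """
    merged = annotations.merge(
        class_labels.rename("class"), left_on="gene_id", right_index=True, how="inner"
    )
    merged = merged[
        np.isfinite(merged["nearest_summit_distance"])
        & (merged["nearest_summit_distance"].abs() <= max_distance_bp)
    ]
    distributions: dict[str, np.ndarray] = {}
    rows = []
    notes = []
    for label in class_labels.dropna().unique():
        vals = merged.loc[merged["class"] == label, "nearest_summit_distance"].to_numpy()
        if len(vals) == 0:
            notes.append(f"class {label}: no bound genes within +-{max_distance_bp} bp")
            continue
        distributions[label] = vals
        rows.append({"class": label, "n": len(vals), "median_distance": float(np.median(vals))})
    return distributions, pd.DataFrame(rows), notes


# ---------------------------------------------------------------------------
# Pol II anchored normalization
# ---------------------------------------------------------------------------

def polii_normalize_quantify(
    promoter_counts: pd.DataFrame,
    body_counts: pd.DataFrame,
    nc_gene_set,
) -> tuple[pd.DataFrame, float]:
    """Pol II promoter/body log2FC anchored to unchanged genes.

    Count frames have ``control`` and ``treatment`` columns. The anchoring
    factor is the (geometric) median over the anchor set of the treatment/
    control gene-body ratio; computed in log space so the anchor set's
    median body log2FC is exactly zero for any set size. All treatment
    counts are divided by the factor before fold changes.
    """
    nc = [g for g in nc_gene_set]
    if not nc:
        raise ValueError("anchor gene set is empty")
    body_nc = body_counts.loc[nc]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(body_nc["treatment"] / body_nc["control"])
    log_ratio = log_ratio[np.isfinite(log_ratio)]
    if len(log_ratio) == 0:
        raise ValueError("anchoring factor undefined: no anchor gene with positive counts")
    factor = float(2 ** np.median(log_ratio))
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError(f"invalid anchoring factor {factor}")

    def lfc(frame: pd.DataFrame) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2((frame["treatment"] / factor) / frame["control"])
        return pd.Series(np.where(np.isfinite(vals), vals, np.nan), index=frame.index)

    out = pd.DataFrame(
        {
            "promoter_log2fc": lfc(promoter_counts),
            "body_log2fc": lfc(body_counts),
        }
    )
    out["body_too_short"] = body_counts.get(
        "too_short", pd.Series(False, index=body_counts.index)
    )
    return out, factor


def polii_region_windows(genes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter (+-400 bp of TSS) and body (+500 bp..TES) count windows.

    Genes shorter than 500 bp get an empty, flagged body interval.
    """
    prom_rows, body_rows = [], []
    for g in genes.itertuples(index=False):
        tss0 = int(g.tss) - 1
        prom_rows.append(
            {"gene_id": g.gene_id, "chrom": g.chrom,
             "start": tss0 - 400, "end": tss0 + 401, "strand": g.strand}
        )
        span = abs(int(g.tes) - int(g.tss)) + 1
        too_short = span <= 500
        if g.strand == "+":
            start, end = tss0 + 500, int(g.tes)
        else:
            start, end = int(g.tes) - 1, tss0 + 1 - 500
        if too_short:
            start, end = tss0, tss0  # empty
        body_rows.append(
            {"gene_id": g.gene_id, "chrom": g.chrom, "start": start, "end": end,
             "strand": g.strand, "too_short": too_short}
        )
    return pd.DataFrame(prom_rows), pd.DataFrame(body_rows)


# ---------------------------------------------------------------------------
# ATAC differential accessibility
# ---------------------------------------------------------------------------

def quartile_stratify(heights: pd.Series) -> pd.Series:
    """Deterministic height quartiles: Q1 = highest, Q4 = lowest.

    Rank-based cut (ties broken by index label) so stratum sizes differ by
    at most one.
    """
    order = pd.DataFrame(
        {"h": heights.to_numpy(), "tiebreak": heights.index.astype(str)},
        index=heights.index,
    )
    order = order.sort_values(["h", "tiebreak"], ascending=[False, True], kind="mergesort")
    n = len(order)
    labels = np.array([f"Q{i * 4 // n + 1}" for i in range(n)])
    return pd.Series(labels, index=order.index).reindex(heights.index)


def atac_differential(
    atac_counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    peak_positions: pd.DataFrame,
    genes: pd.DataFrame,
    ctcf_peaks: pd.DataFrame | None = None,
    fc_threshold: float = 2.0,
    promoter_bp: int = 200,
) -> tuple[pd.DataFrame, dict]:
    """Per-peak accessibility log2FC, loss/gain fractions and CTCF quartiles.

    ``atac_counts``: peaks x samples; ``peak_positions``: peak_id, chrom,
    start, end, summit. Median-of-ratios scaling is estimated across peaks;
    peaks with zero counts in both conditions are excluded (tallied).
    CTCF-overlapping peaks get height quartiles within each promoter/distal
    stratum (Q1 = strongest CTCF peak); non-overlapping peaks form the
    no-CTCF reference stratum.
    """
    ctrl = sample_sheet.loc[sample_sheet["condition"] == "control", "sample"].tolist()
    treat = sample_sheet.loc[sample_sheet["condition"] == "treatment", "sample"].tolist()
    if not ctrl or not treat:
        raise ValueError("need control and treatment ATAC samples")
    sf = differential.estimate_size_factors(atac_counts)
    norm = atac_counts.div(sf, axis=1)
    c_mean = norm[ctrl].mean(axis=1)
    t_mean = norm[treat].mean(axis=1)
    both_zero = (c_mean == 0) & (t_mean == 0)
    report = {"excluded_zero_both": int(both_zero.sum())}
    keep = ~both_zero
    with np.errstate(divide="ignore"):
        lfc = pd.Series(np.log2(t_mean[keep] / c_mean[keep]), index=atac_counts.index[keep])

    pos = peak_positions.set_index("peak_id").loc[lfc.index]
    tss_by_chrom = {
        chrom: np.sort(grp["tss"].to_numpy(np.int64) - 1)
        for chrom, grp in genes.groupby("chrom")
    }
    promoter = []
    for p in pos.itertuples():
        tss = tss_by_chrom.get(p.chrom)
        summit = int(p.summit)
        if tss is None or len(tss) == 0:
            promoter.append(False)
            continue
        i = np.searchsorted(tss, summit)
        near = min(abs(int(tss[j]) - summit) for j in (i - 1, i) if 0 <= j < len(tss))
        promoter.append(near <= promoter_bp)
    result = pd.DataFrame(
        {
            "log2fc": lfc,
            "promoter": promoter,
        },
        index=lfc.index,
    )

    result["ctcf_height"] = np.nan
    if ctcf_peaks is not None and len(ctcf_peaks) > 0:
        by_chrom = {
            chrom: (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
                grp["signal_value"].to_numpy(float),
            )
            for chrom, grp in ctcf_peaks.sort_values("start").groupby("chrom")
        }
        heights = []
        for p in pos.itertuples():
            entry = by_chrom.get(p.chrom)
            h = np.nan
            if entry is not None:
                cs, ce, sig = entry
                hit = (cs < int(p.end)) & (ce > int(p.start))
                if hit.any():
                    h = float(sig[hit].max())
            heights.append(h)
        result["ctcf_height"] = heights

    result["ctcf_quartile"] = "no_CTCF"
    for stratum, mask in (("promoter", result["promoter"]), ("distal", ~result["promoter"])):
        has = mask & result["ctcf_height"].notna()
        if has.any():
            result.loc[has, "ctcf_quartile"] = quartile_stratify(result.loc[has, "ctcf_height"])

    log_thr = math.log2(fc_threshold)
    summary = {
        "fraction_lost": float((result["log2fc"] <= -log_thr).mean()),
        "fraction_gained": float((result["log2fc"] >= log_thr).mean()),
        "n_peaks": int(len(result)),
        **report,
    }
    return result, summary
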