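"""Representative-transcript selection and per-gene window geometry.

One representative transcript is chosen per gene by a two-step rule:
promoter-mark-supported expressed isoforms first (longest wins), longest
isoform as fallback. From the representative model we derive the
strand-aware counting window (capped by treatment duration), promoter
windows around the TSS, and the upstream antisense window.

All windows are 0-based half-open genomic intervals; TSS/TES are kept
1-based to match GTF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: gene-body cap (bp from TSS) per treatment duration in minutes
WINDOW_CAP_BP = {30: 30_000, 60: 90_000, 120: 240_000}

#: antisense window relative to TSS in gene-strand coordinates, half-open
ANTISENSE_UPSTREAM_START = -1_700
ANTISENSE_UPSTREAM_END = -200

PROMOTER_HALF_WIDTHS = {"2kb": 2_000, "400bp": 400, "200bp": 200}

KEPT_BIOTYPES = {"protein_coding", "lincRNA"}


@dataclass(frozen=True)
class GeneModel:
    """A representative transcript with derived windows (scalar view)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int  # 1-based
    tes: int  # 1-based
    transcript_id: str
    transcript_length: int
    biotype: str
    window_start: int  # 0-based half-open counting window
    window_end: int
    antisense_start: int
    antisense_end: int
    antisense_strand: str


def compute_counting_window(
    tss: int,
    tes: int,
    strand: str,
    treatment_minutes: int | None = None,
    full_gene: bool = False,
) -> tuple[int, int]:
    """Counting window from the TSS toward the TES, capped by duration.

    ``tss``/``tes`` are 1-based inclusive; the returned interval is 0-based
    half-open. For minus-strand genes the window extends leftward from the
    TSS. Unknown durations require an explicit ``full_gene=True``.
    """
    if strand not in {"+", "-"}:
        raise ValueError(f"invalid strand {strand!r}")
    span = abs(tes - tss) + 1
    if full_gene:
        cap = span
    elif treatment_minutes in WINDOW_CAP_BP:
        cap = WINDOW_CAP_BP[treatment_minutes]
    else:
        raise ValueError(
            f"no counting-window cap defined for treatment_minutes="
            f"{treatment_minutes!r}; pass full_gene=True to count the whole gene"
        )
    length = min(span, cap)
    if strand == "+":
        if tes < tss:
            raise ValueError("plus-strand gene with TES < TSS")
        start = tss - 1
        return start, start + length
    if tes > tss:
        raise ValueError("minus-strand gene with TES > TSS")
    end = tss  # half-open end; 0-based TSS is tss-1
    return end - length, end


def antisense_window(tss: int, strand: str) -> tuple[int, int, str]:
    """Upstream antisense window (0-based half-open) and its strand.

    Spans gene-strand offsets [-1700, -200) relative to the TSS, on the
    strand opposite the gene.
    """
    tss0 = tss - 1
    if strand == "+":
        return (
            tss0 + ANTISENSE_UPSTREAM_START,
            tss0 + ANTISENSE_UPSTREAM_END,
            "-",
        )
    if strand == "-":
        return (
            tss0 - ANTISENSE_UPSTREAM_END + 1,
            tss0 - ANTISENSE_UPSTREAM_START + 1,
            "+",
        )
    raise ValueError(f"invalid strand {strand!r}")


def promoter_window(tss: int, half_width: int) -> tuple[int, int]:
    """Symmetric window of ``±half_width`` bp around the TSS (0-based)."""
    tss0 = tss - 1
    return tss0 - half_width, tss0 + half_width + 1


def tss_of(start0: int, end0: int, strand: str) -> int:
    """1-based TSS from a 0-based half-open transcript interval."""
    return start0 + 1 if strand == "+" else end0


def tes_of(start0: int, end0: int, strand: str) -> int:
    return end0 if strand == "+" else start0 + 1


def select_reference_transcripts(
    transcripts: pd.DataFrame,
    tpm: pd.Series | dict,
    peak_summits: pd.DataFrame | None,
    tpm_threshold: float = 2.0,
    peak_distance_bp: int = 1_000,
    kept_biotypes: set[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Pick one representative transcript per gene.

    ``transcripts``: columns chrom, start, end (0-based half-open), strand,
    gene_id, transcript_id, biotype. ``tpm`` maps transcript_id to TPM.
    ``peak_summits``: DataFrame with chrom and summit columns (or None).

    Step 1 keeps isoforms with TPM > threshold and a promoter-mark summit
    within ``peak_distance_bp`` of the TSS; the longest such isoform wins.
    Step 2 falls back to the longest isoform for genes with no
    peak-supported isoform. Ties break on lexicographic transcript_id.
    """
    kept_biotypes = kept_biotypes if kept_biotypes is not None else KEPT_BIOTYPES
    report: dict = {"n_input": len(transcripts), "rejected_no_gene_id": 0}
    if len(transcripts) == 0:
        return transcripts.copy(), report

    tx = transcripts.copy()
    bad = tx["gene_id"].isna() | (tx["gene_id"].astype(str) == "")
    report["rejected_no_gene_id"] = int(bad.sum())
    tx = tx[~bad]
    tx = tx[tx["biotype"].isin(kept_biotypes)].copy()
    report["n_after_biotype_filter"] = len(tx)
    if len(tx) == 0:
        return tx, report

    tpm = pd.Series(tpm, dtype=float) if not isinstance(tpm, pd.Series) else tpm
    tx["tpm"] = tx["transcript_id"].map(tpm).fillna(0.0)
    tx["length"] = tx["end"] - tx["start"]
    tx["tss"] = np.where(tx["strand"] == "+", tx["start"] + 1, tx["end"])

    if peak_summits is not None and len(peak_summits) > 0:
        summits_by_chrom = {
            chrom: np.sort(grp["summit"].to_numpy())
            for chrom, grp in peak_summits.groupby("chrom")
        }
        def has_peak(row) -> bool:
            s = summits_by_chrom.get(row.chrom)
            if s is None:
                return False
            tss0 = row.tss - 1
            i = np.searchsorted(s, tss0)
            for j in (i - 1, i):
                if 0 <= j < len(s) and abs(int(s[j]) - tss0) <= peak_distance_bp:
                    return True
            return False

        tx["peak_supported"] = [has_peak(r) for r in tx.itertuples(index=False)]
    else:
        tx["peak_supported"] = False

    tx["expressed_supported"] = (tx["tpm"] > tpm_threshold) & tx["peak_supported"]

    chosen = []
    for _gene, grp in tx.groupby("gene_id", sort=True):
        cands = grp[grp["expressed_supported"]]
        pool = cands if len(cands) else grp
        pool = pool.sort_values(
            ["length", "transcript_id"], ascending=[False, True], kind="mergesort"
        )
        chosen.append(pool.iloc[0])
    selected = pd.DataFrame(chosen).reset_index(drop=True)
    report["n_genes"] = len(selected)
    return selected, report


def build_gene_models(
    selected: pd.DataFrame,
    treatment_minutes: int | None = None,
    full_gene: bool = False,
) -> pd.DataFrame:
    """Derive counting/antisense window columns for selected transcripts.

    Returns one row per gene with 1-based tss/tes and 0-based half-open
    window columns. Raises on duplicated gene_ids.
    """
    if selected["gene_id"].duplicated().any():
        dups = selected.loc[selected["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicated gene_ids: {dups[:5]}")
    rows = []
    for t in selected.itertuples(index=False):
        tss = tss_of(int(t.start), int(t.end), t.strand)
        tes = tes_of(int(t.start), int(t.end), t.strand)
        ws, we = compute_counting_window(tss, tes, t.strand, treatment_minutes, full_gene)
        as_s, as_e, as_strand = antisense_window(tss, t.strand)
        rows.append(
            {
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "tss": tss,
                "tes": tes,
                "transcript_id": t.transcript_id,
                "transcript_length": int(t.end) - int(t.start),
                "biotype": t.biotype,
                "window_start": ws,
                "window_end": we,
                "antisense_start": as_s,
                "antisense_end": as_e,
                "antisense_strand": as_strand,
            }
        )
    return pd.DataFrame(rows)


def gene_models_to_windows(genes: pd.DataFrame, which: str = "sense") -> pd.DataFrame:
    """Extract a windows table (gene_id, chrom, start, end, strand)."""
    if which == "sense":
        df = genes[["gene_id", "chrom", "window_start", "window_end", "strand"]]
        return df.rename(columns={"window_start": "start", "window_end": "end"})
    if which == "antisense":
        df = genes[["gene_id", "chrom", "antisense_start", "antisense_end", "antisense_strand"]]
        return df.rename(
            columns={
                "antisense_start": "start",
                "antisense_end": "end",
                "antisense_strand": "strand",
            }
        )
    raise ValueError(f"unknown window kind {which!r}")
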