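"""Readers and writers for the plain-text formats used across the toolkit.

Coordinate conventions are centralized here: GTF is 1-based inclusive on
disk, BED/narrowPeak are 0-based half-open. All in-memory interval columns
(``start``/``end``) are 0-based half-open; GTF conversion happens only at
the read/write boundary.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

NARROWPEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signal_value",
    "p_value",
    "q_value",
    "summit_offset",
]

# JASPAR CTCF matrix MA0139.1 (public database matrix, bundled so the
# simulator and scanner work without any download).
DEFAULT_CTCF_JASPAR = """>MA0139.1 CTCF
A [     87    167    281     56      8    744     40    107    851      5    333     54     12     56    104    372     82    117    402 ]
C [    291    145     49    800    903     13    528    433     11      0      3     12      0      8    733     13    482    322    181 ]
G [     76    414    449     21      0     65    334    48     32    903    566    504    890    775      5    507    307     73    266 ]
T [    459    187    134     36      2     91    11    324     18      3    131    458     22      8    169     40    263    507    116 ]
"""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a ``{name: sequence}`` dict (uppercased)."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED6 / narrowPeak
# ---------------------------------------------------------------------------

def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=BED6_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        comment="#",
    )
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """Read an ENCODE narrowPeak file.

    Adds an absolute ``summit`` column (0-based position). Peaks without a
    summit (offset -1) raise, since downstream geometry requires summits.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS, comment="#")
    if (df["summit_offset"] < 0).any():
        bad = int(np.flatnonzero(df["summit_offset"].to_numpy() < 0)[0]) + 1
        raise ValueError(f"peak without summit at {path} line {bad}")
    df["summit"] = df["start"] + df["summit_offset"]
    return df


def write_narrowpeak(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "summit_offset" not in out.columns and "summit" in out.columns:
        out["summit_offset"] = out["summit"] - out["start"]
    out.loc[:, NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_transcripts(path: str | Path) -> pd.DataFrame:
    """Read transcript records from a GENCODE-dialect GTF.

    Returns 0-based half-open ``start``/``end`` plus gene_id, transcript_id,
    biotype (transcript_type or gene_type attribute) and strand.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            attrs = dict(_ATTR_RE.findall(f[8]))
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                    "gene_id": attrs.get("gene_id", ""),
                    "transcript_id": attrs.get("transcript_id", ""),
                    "biotype": attrs.get("transcript_type", attrs.get("gene_type", "other")),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id", "biotype"],
    )


def write_gtf(transcripts: pd.DataFrame, path: str | Path, source: str = "euseqtools") -> None:
    """Write transcript rows (0-based half-open in memory) as GTF."""
    with open(path, "w") as fh:
        for t in transcripts.itertuples(index=False):
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_type "{t.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        str(t.chrom),
                        source,
                        "transcript",
                        str(int(t.start) + 1),
                        str(int(t.end)),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample count matrix: TSV, gene_id first column, header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# JASPAR motifs
# ---------------------------------------------------------------------------

def read_jaspar_motif(source: str | Path | None = None):
    """Load a JASPAR-format PFM; defaults to the bundled CTCF matrix."""
    if source is None:
        return motifs.read(_io.StringIO(DEFAULT_CTCF_JASPAR), "jaspar")
    with open(source) as fh:
        return motifs.read(fh, "jaspar")


def motif_consensus(motif) -> str:
    return str(motif.consensus)
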