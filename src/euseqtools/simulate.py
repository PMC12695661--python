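"""Miniature-genome simulator with planted ground truth for every stage.

Generates gene models on a small multi-chromosome genome, negative-binomial
replicate counts with planted per-gene fold changes spanning the class
taxonomy, strand-specific fragment files that tabulate exactly to the count
matrix, CTCF/RAD21 peaks with oriented motif instances planted in the
genome sequence, and Pol II / ATAC signal tracks with a global confounder
and planted accessibility losses.

Determinism contract: everything derives from ``SimulationConfig.seed``;
stages draw from independent child generators so that, for a fixed config,
outputs are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, classify, io

DOWN_LABELS = {"SD", "ID", "HD", "HD1", "HD2"}
UP_LABELS = {"SU", "IU", "HU"}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PeakPlacement:
    """Per-gene rule for CTCF/RAD21 presence and motif planting."""

    presence_fraction: float = 0.5
    summit_offsets: tuple[int, ...] = (-79, -150, -300, 150)
    height_range: tuple[float, float] = (5.0, 50.0)
    orientation_probs: dict[str, float] = field(
        default_factory=lambda: {"forward": 0.5, "reverse": 0.2, "both": 0.1, "none": 0.2}
    )
    rad21_fraction: float = 0.7
    rad21_summit_jitter: int = 30


@dataclass
class SimulationConfig:
    n_genes: int = 200
    n_chromosomes: int = 2
    chrom_length: int = 6_000_000
    gene_length_range: tuple[int, int] = (2_000, 120_000)
    class_spectrum: dict[str, tuple[float, tuple[float, float]]] = field(
        default_factory=lambda: {
            "NC": (0.90, (1.0, 1.0)),
            "SD": (0.030, (1.32, 1.48)),
            "ID": (0.025, (1.55, 1.95)),
            "HD": (0.020, (2.10, 4.00)),
            "SU": (0.013, (1.32, 1.48)),
            "IU": (0.007, (1.55, 1.95)),
            "HU": (0.005, (2.10, 4.00)),
        }
    )
    global_asymmetry_fc: float = 1.0
    nb_mean_range: tuple[float, float] = (100.0, 2_000.0)
    nb_dispersion: float = 50.0  # NB size/shape: var = mu + mu^2/size
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    n_replicates_initial: int = 4
    n_replicates_extra: int = 0
    labeling_minutes: int = 60
    fragment_length: int = 100
    uastrx_fraction: float = 0.05
    uastrx_fc: float = 3.0
    antisense_mean_range: tuple[float, float] = (30.0, 200.0)
    polii_confounder: float = 1.6
    uastrx_polii_promoter_gain: float = 2.0
    n_atac_background_peaks: int = 300
    atac_loss_fraction: float = 0.064
    atac_gain_fraction: float = 0.0003
    atac_mean_range: tuple[float, float] = (200.0, 1_000.0)
    peak_placement: PeakPlacement = field(default_factory=PeakPlacement)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        total = sum(frac for frac, _rng in self.class_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_spectrum fractions sum to {total}, expected 1")
        for label, (_frac, (lo, hi)) in self.class_spectrum.items():
            if lo < 1.0 or hi < lo:
                raise ValueError(
                    f"class {label}: FC range must satisfy 1 <= lo <= hi, got ({lo}, {hi})"
                )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.labeling_minutes not in {30, 60, 120, 240}:
            raise ValueError("labeling_minutes must be one of {30, 60, 120, 240}")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


class PlacementError(RuntimeError):
    """Raised when genes cannot be placed; chrom_length is too small."""


# ---------------------------------------------------------------------------
# Gene models and genome
# ---------------------------------------------------------------------------

MIN_UPSTREAM_CLEARANCE = 5_000
_EDGE_MARGIN = 10_000


def generate_gene_models(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Place non-overlapping genes and build the genome with planted motifs.

    Returns the gene-model table (windows per :mod:`annotation`, plus
    ground-truth peak/motif columns) and the genome as ``{chrom: sequence}``.
    """
    config.validate()
    rng = config.rng(stage=1)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seq_arrays = {
        c: _BASES[rng.integers(0, 4, size=config.chrom_length)] for c in chrom_names
    }
    if config.n_genes == 0:
        genome = {c: arr.tobytes().decode("ascii") for c, arr in seq_arrays.items()}
        return pd.DataFrame(
            columns=["gene_id", "chrom", "strand", "tss", "tes"]
        ), genome

    lo, hi = config.gene_length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes)).astype(int)
    strands = rng.choice(["+", "-"], size=config.n_genes)

    cursors = {c: _EDGE_MARGIN for c in chrom_names}
    rows = []
    chrom_cycle = 0
    for i in range(config.n_genes):
        length = int(lengths[i])
        placed = False
        for _attempt in range(config.n_chromosomes):
            chrom = chrom_names[chrom_cycle % config.n_chromosomes]
            chrom_cycle += 1
            start = cursors[chrom]
            if start + length + _EDGE_MARGIN <= config.chrom_length:
                gap = MIN_UPSTREAM_CLEARANCE + int(rng.integers(0, 2_000))
                cursors[chrom] = start + length + gap
                rows.append(
                    {
                        "gene_id": f"g{i + 1:05d}",
                        "transcript_id": f"t{i + 1:05d}",
                        "chrom": chrom,
                        "start": start,
                        "end": start + length,
                        "strand": strands[i],
                        "biotype": "protein_coding",
                    }
                )
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place gene {i + 1}/{config.n_genes}: chrom_length "
                f"{config.chrom_length} too small for the requested gene set"
            )
    transcripts = pd.DataFrame(rows)
    genes = annotation.build_gene_models(
        transcripts,
        treatment_minutes=config.labeling_minutes if config.labeling_minutes != 240 else None,
        full_gene=config.labeling_minutes == 240,
    )

    # plant CTCF/RAD21 peak geometry and motif instances
    pp = config.peak_placement
    n = len(genes)
    has_ctcf = rng.random(n) < pp.presence_fraction
    summit_offsets = rng.choice(np.asarray(pp.summit_offsets), size=n)
    heights = rng.uniform(*pp.height_range, size=n)
    orient_labels = list(pp.orientation_probs)
    orient_p = np.asarray([pp.orientation_probs[k] for k in orient_labels], dtype=float)
    orient_p = orient_p / orient_p.sum()
    orientations = rng.choice(orient_labels, size=n, p=orient_p)
    has_rad21 = has_ctcf & (rng.random(n) < pp.rad21_fraction)
    rad21_heights = heights * rng.uniform(0.3, 1.5, size=n)
    rad21_jitter = rng.integers(-pp.rad21_summit_jitter, pp.rad21_summit_jitter + 1, size=n)

    genes["has_ctcf"] = has_ctcf
    genes["summit_offset"] = np.where(has_ctcf, summit_offsets, 0)
    genes["ctcf_height"] = np.where(has_ctcf, heights, np.nan)
    genes["motif_orientation"] = np.where(has_ctcf, orientations, "none")
    genes["has_rad21"] = has_rad21
    genes["rad21_height"] = np.where(has_rad21, rad21_heights, np.nan)
    genes["rad21_summit_jitter"] = np.where(has_rad21, rad21_jitter, 0)

    pwm = io.read_jaspar_motif()
    consensus = io.motif_consensus(pwm)
    fwd = np.frombuffer(consensus.encode(), dtype=np.uint8)
    rev = np.frombuffer(_revcomp(consensus).encode(), dtype=np.uint8)
    for g in genes.itertuples(index=False):
        if not g.has_ctcf:
            continue
        summit = _summit_genomic(int(g.tss), g.strand, int(g.summit_offset))
        arr = seq_arrays[g.chrom]
        gene_strand_motif = fwd if g.strand == "+" else rev
        opposite_motif = rev if g.strand == "+" else fwd
        if g.motif_orientation == "forward":
            _plant(arr, summit - len(fwd) // 2, gene_strand_motif)
        elif g.motif_orientation == "reverse":
            _plant(arr, summit - len(fwd) // 2, opposite_motif)
        elif g.motif_orientation == "both":
            _plant(arr, summit - len(fwd) - 3, gene_strand_motif)
            _plant(arr, summit + 3, opposite_motif)

    genome = {c: arr.tobytes().decode("ascii") for c, arr in seq_arrays.items()}
    return genes, genome


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _summit_genomic(tss: int, strand: str, offset: int) -> int:
    tss0 = tss - 1
    return tss0 + offset if strand == "+" else tss0 - offset


def _plant(arr: np.ndarray, start: int, motif: np.ndarray) -> None:
    if start < 0 or start + len(motif) > len(arr):
        raise PlacementError("motif instance outside contig; enlarge chrom_length")
    arr[start : start + len(motif)] = motif


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def generate_counts(
    config: SimulationConfig, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrices with planted fold changes.

    Returns (sense counts, sample sheet, ground truth, antisense counts).
    Control mean is ``m_i * s_j``; treatment mean ``m_i * FC_i * A * s_j``
    where A is the global asymmetry/library confounder. Ground-truth class
    labels are computed from the planted FCs by the classification module
    (single source of truth for boundaries).
    """
    config.validate()
    rng = config.rng(stage=2)
    n = len(genes)
    gene_ids = genes["gene_id"].to_numpy()
    n_reps = config.n_replicates_initial + config.n_replicates_extra
    ctrl_samples = [f"ctrl_{j + 1:02d}" for j in range(n_reps)]
    treat_samples = [f"treat_{j + 1:02d}" for j in range(n_reps)]
    phases = ["initial"] * config.n_replicates_initial + ["extra"] * config.n_replicates_extra
    sheet = pd.DataFrame(
        {
            "sample": ctrl_samples + treat_samples,
            "condition": ["control"] * n_reps + ["treatment"] * n_reps,
            "replicate": list(range(1, n_reps + 1)) * 2,
            "pair_id": [f"pair_{j + 1:02d}" for j in range(n_reps)] * 2,
            "phase": phases * 2,
        }
    )

    labels = list(config.class_spectrum)
    fracs = np.asarray([config.class_spectrum[k][0] for k in labels], dtype=float)
    fracs = fracs / fracs.sum()
    gene_labels = rng.choice(labels, size=n, p=fracs)
    magnitudes = np.ones(n)
    for k in labels:
        mask = gene_labels == k
        lo, hi = config.class_spectrum[k][1]
        magnitudes[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
    true_fc = np.where(np.isin(gene_labels, list(DOWN_LABELS)), 1.0 / magnitudes, magnitudes)

    base_mean = np.exp(
        rng.uniform(np.log(config.nb_mean_range[0]), np.log(config.nb_mean_range[1]), size=n)
    )
    size_factors = rng.uniform(*config.size_factor_range, size=2 * n_reps)

    mu_ctrl = base_mean[:, None] * size_factors[None, :n_reps]
    mu_treat = (
        base_mean[:, None]
        * true_fc[:, None]
        * config.global_asymmetry_fc
        * size_factors[None, n_reps:]
    )
    counts = pd.DataFrame(
        np.concatenate(
            [
                _nb_draw(rng, mu_ctrl, config.nb_dispersion),
                _nb_draw(rng, mu_treat, config.nb_dispersion),
            ],
            axis=1,
        ),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=ctrl_samples + treat_samples,
    )

    uastrx = rng.random(n) < config.uastrx_fraction
    as_base = rng.uniform(*config.antisense_mean_range, size=n)
    as_fc = np.where(uastrx, config.uastrx_fc, 1.0)
    as_mu_ctrl = as_base[:, None] * size_factors[None, :n_reps]
    as_mu_treat = as_base[:, None] * as_fc[:, None] * size_factors[None, n_reps:]
    antisense_counts = pd.DataFrame(
        np.concatenate(
            [
                _nb_draw(rng, as_mu_ctrl, config.nb_dispersion),
                _nb_draw(rng, as_mu_treat, config.nb_dispersion),
            ],
            axis=1,
        ),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=ctrl_samples + treat_samples,
    )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_fc": true_fc,
            "true_class": [classify.assign_class(f) for f in true_fc],
            "base_mean": base_mean,
            "uastrx_up": uastrx,
            "true_antisense_fc": as_fc,
        }
    ).set_index("gene_id")
    for col in ("has_ctcf", "summit_offset", "ctcf_height", "motif_orientation"):
        if col in genes.columns:
            truth[col] = genes.set_index("gene_id")[col]
    truth.attrs["size_factors"] = size_factors
    return counts, sheet, truth, antisense_counts


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def generate_fragments(
    counts: pd.DataFrame,
    genes: pd.DataFrame,
    fragment_length: int = 100,
    antisense_counts: pd.DataFrame | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Uniformly-placed BED6 fragments reproducing the count matrix exactly.

    Sense fragments lie fully inside each gene's counting window on the
    gene's strand; antisense fragments (when an antisense matrix is given)
    lie inside the upstream antisense window on the opposite strand.
    """
    rng = np.random.default_rng([int(seed), 3])
    gene_info = genes.set_index("gene_id")
    too_short = gene_info["window_end"] - gene_info["window_start"] < fragment_length
    if too_short.any():
        bad = gene_info.index[too_short].tolist()
        raise ValueError(
            f"counting window shorter than fragment length {fragment_length} "
            f"for genes {bad[:5]}"
        )
    out: dict[str, pd.DataFrame] = {}
    for sample in counts.columns:
        chroms, starts, strands = [], [], []
        for gene_id, c in counts[sample].items():
            c = int(c)
            if c == 0:
                continue
            g = gene_info.loc[gene_id]
            s = rng.integers(
                int(g["window_start"]), int(g["window_end"]) - fragment_length + 1, size=c
            )
            starts.append(s)
            chroms.extend([g["chrom"]] * c)
            strands.extend([g["strand"]] * c)
        if antisense_counts is not None:
            for gene_id, c in antisense_counts[sample].items():
                c = int(c)
                if c == 0:
                    continue
                g = gene_info.loc[gene_id]
                lo, hi = int(g["antisense_start"]), int(g["antisense_end"])
                if hi - lo < fragment_length:
                    raise ValueError(
                        f"antisense window of {gene_id} shorter than fragment length"
                    )
                s = rng.integers(lo, hi - fragment_length + 1, size=c)
                starts.append(s)
                chroms.extend([g["chrom"]] * c)
                strands.extend([g["antisense_strand"]] * c)
        all_starts = (
            np.concatenate(starts) if starts else np.array([], dtype=np.int64)
        )
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "start": all_starts,
                "end": all_starts + fragment_length,
                "name": [f"{sample}_f{i}" for i in range(len(all_starts))],
                "score": 0,
                "strand": strands,
            }
        )
        out[sample] = df
    return out


# ---------------------------------------------------------------------------
# Signal tracks (Pol II, ATAC, peak files)
# ---------------------------------------------------------------------------

def build_peak_tables(genes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """narrowPeak-style CTCF and RAD21 tables from planted gene columns."""
    ctcf_rows, rad21_rows = [], []
    for g in genes.itertuples(index=False):
        if not g.has_ctcf:
            continue
        summit = _summit_genomic(int(g.tss), g.strand, int(g.summit_offset))
        ctcf_rows.append(
            {
                "chrom": g.chrom,
                "start": summit - 250,
                "end": summit + 250,
                "name": f"ctcf_{g.gene_id}",
                "score": 0,
                "strand": ".",
                "signal_value": float(g.ctcf_height),
                "p_value": -1,
                "q_value": -1,
                "summit_offset": 250,
                "summit": summit,
            }
        )
        if g.has_rad21:
            r_summit = summit + int(g.rad21_summit_jitter)
            rad21_rows.append(
                {
                    "chrom": g.chrom,
                    "start": r_summit - 250,
                    "end": r_summit + 250,
                    "name": f"rad21_{g.gene_id}",
                    "score": 0,
                    "strand": ".",
                    "signal_value": float(g.rad21_height),
                    "p_value": -1,
                    "q_value": -1,
                    "summit_offset": 250,
                    "summit": r_summit,
                }
            )
    cols = io.NARROWPEAK_COLUMNS + ["summit"]
    return (
        pd.DataFrame(ctcf_rows, columns=cols),
        pd.DataFrame(rad21_rows, columns=cols),
    )


def generate_signal_tracks(
    config: SimulationConfig,
    genes: pd.DataFrame,
    ground_truth: pd.DataFrame | None = None,
) -> dict:
    """Pol II promoter/body and ATAC per-region counts for two conditions.

    Pol II treatment counts carry a global library confounder
    (``config.polii_confounder``) that the anchored normalization must
    remove. A configured fraction of CTCF-bound ATAC peaks gets a planted
    >=2-fold accessibility loss.
    """
    config.validate()
    rng = config.rng(stage=4)
    n = len(genes)
    gene_ids = genes["gene_id"].to_numpy()

    true_fc = (
        ground_truth["true_fc"].reindex(gene_ids).to_numpy()
        if ground_truth is not None
        else np.ones(n)
    )
    uastrx = (
        ground_truth["uastrx_up"].reindex(gene_ids).to_numpy()
        if ground_truth is not None
        else np.zeros(n, dtype=bool)
    )

    prom_change = np.where(true_fc < 1.0, true_fc, 1.0)
    prom_change = np.where(uastrx, config.uastrx_polii_promoter_gain, prom_change)
    body_change = np.where(true_fc < 1.0, true_fc, 1.0)

    prom_base = rng.uniform(200, 1_000, size=n)
    body_base = rng.uniform(500, 2_000, size=n)
    polii_promoter = pd.DataFrame(
        {
            "control": rng.poisson(prom_base),
            "treatment": rng.poisson(prom_base * prom_change * config.polii_confounder),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    polii_body = pd.DataFrame(
        {
            "control": rng.poisson(body_base),
            "treatment": rng.poisson(body_base * body_change * config.polii_confounder),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    ctcf_peaks, rad21_peaks = build_peak_tables(genes)

    # ATAC peaks: one at every CTCF peak, plus CTCF-free background peaks
    atac_rows = []
    ctcf_bound = []
    for p in ctcf_peaks.itertuples(index=False):
        atac_rows.append((p.chrom, int(p.summit)))
        ctcf_bound.append(True)
    chrom_names = sorted(genes["chrom"].unique()) or ["chr1"]
    for _i in range(config.n_atac_background_peaks):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        pos = int(rng.integers(_EDGE_MARGIN, config.chrom_length - _EDGE_MARGIN))
        atac_rows.append((chrom, pos))
        ctcf_bound.append(False)
    n_peaks = len(atac_rows)
    peak_ids = [f"atac_{i + 1:05d}" for i in range(n_peaks)]
    positions = pd.DataFrame(
        {
            "peak_id": peak_ids,
            "chrom": [r[0] for r in atac_rows],
            "start": [r[1] - 250 for r in atac_rows],
            "end": [r[1] + 250 for r in atac_rows],
            "summit": [r[1] for r in atac_rows],
        }
    )
    ctcf_bound = np.asarray(ctcf_bound)
    change = np.ones(n_peaks)
    bound_idx = np.flatnonzero(ctcf_bound)
    n_loss = int(round(config.atac_loss_fraction * len(bound_idx)))
    loss_idx = rng.choice(bound_idx, size=min(n_loss, len(bound_idx)), replace=False)
    change[loss_idx] = 1.0 / rng.uniform(2.5, 6.0, size=len(loss_idx))
    free_idx = np.flatnonzero(change == 1.0)
    n_gain = int(round(config.atac_gain_fraction * n_peaks))
    gain_idx = rng.choice(free_idx, size=min(n_gain, len(free_idx)), replace=False)
    change[gain_idx] = rng.uniform(2.5, 6.0, size=len(gain_idx))

    atac_base = rng.uniform(*config.atac_mean_range, size=n_peaks)
    atac_counts = pd.DataFrame(
        {
            "control": rng.poisson(atac_base),
            "treatment": rng.poisson(atac_base * change),
        },
        index=pd.Index(peak_ids, name="peak_id"),
    )
    atac_sheet = pd.DataFrame(
        {"sample": ["control", "treatment"], "condition": ["control", "treatment"]}
    )
    signal_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_polii_promoter_change": prom_change,
            "true_polii_body_change": body_change,
        }
    ).set_index("gene_id")
    atac_truth = pd.DataFrame(
        {"peak_id": peak_ids, "true_change": change, "ctcf_bound": ctcf_bound}
    ).set_index("peak_id")
    return {
        "polii_promoter": polii_promoter,
        "polii_body": polii_body,
        "polii_confounder": config.polii_confounder,
        "ctcf_peaks": ctcf_peaks,
        "rad21_peaks": rad21_peaks,
        "atac_counts": atac_counts,
        "atac_positions": positions,
        "atac_sample_sheet": atac_sheet,
        "signal_truth": signal_truth,
        "atac_truth": atac_truth,
    }


# ---------------------------------------------------------------------------
# Full dataset writer
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    write_fragments: bool = True,
    write_genome: bool = True,
    force: bool = False,
) -> dict:
    """Run the full simulator and write a plain-text dataset directory."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    genes, genome = generate_gene_models(config)
    counts, sheet, truth, antisense_counts = generate_counts(config, genes)
    tracks = generate_signal_tracks(config, genes, truth)

    files: dict[str, Path] = {}
    if write_genome:
        io.write_fasta(genome, outdir / "genome.fa")
        files["genome"] = outdir / "genome.fa"
    tx_df = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.where(genes["strand"] == "+", genes["tss"] - 1, genes["tes"] - 1),
            "end": np.where(genes["strand"] == "+", genes["tes"], genes["tss"]),
            "strand": genes["strand"],
            "gene_id": genes["gene_id"],
            "transcript_id": genes["transcript_id"],
            "biotype": genes["biotype"],
        }
    ) if len(genes) else pd.DataFrame(
        columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id", "biotype"]
    )
    io.write_gtf(tx_df, outdir / "genes.gtf")
    files["gtf"] = outdir / "genes.gtf"
    io.write_table(genes, outdir / "gene_models.tsv")
    files["gene_models"] = outdir / "gene_models.tsv"
    io.write_counts(counts, outdir / "counts.tsv")
    files["counts"] = outdir / "counts.tsv"
    io.write_counts(antisense_counts, outdir / "antisense_counts.tsv")
    files["antisense_counts"] = outdir / "antisense_counts.tsv"
    io.write_table(sheet, outdir / "samples.tsv")
    files["samples"] = outdir / "samples.tsv"
    io.write_table(truth.reset_index(), outdir / "ground_truth.tsv")
    files["ground_truth"] = outdir / "ground_truth.tsv"
    io.write_narrowpeak(tracks["ctcf_peaks"], outdir / "ctcf_peaks.narrowPeak")
    files["ctcf_peaks"] = outdir / "ctcf_peaks.narrowPeak"
    io.write_narrowpeak(tracks["rad21_peaks"], outdir / "rad21_peaks.narrowPeak")
    files["rad21_peaks"] = outdir / "rad21_peaks.narrowPeak"
    io.write_counts(tracks["polii_promoter"], outdir / "polii_promoter.tsv")
    io.write_counts(tracks["polii_body"], outdir / "polii_body.tsv")
    io.write_counts(tracks["atac_counts"], outdir / "atac_counts.tsv")
    io.write_table(tracks["atac_positions"], outdir / "atac_positions.tsv")
    io.write_table(tracks["atac_truth"].reset_index(), outdir / "atac_truth.tsv")
    io.write_table(tracks["signal_truth"].reset_index(), outdir / "signal_truth.tsv")
    for key in (
        "polii_promoter", "polii_body", "atac_counts", "atac_positions",
        "atac_truth", "signal_truth",
    ):
        files[key] = outdir / f"{key}.tsv"

    if write_fragments and len(genes):
        frag_dir = outdir / "fragments"
        frag_dir.mkdir(exist_ok=True)
        frags = generate_fragments(
            counts, genes, config.fragment_length, antisense_counts, seed=config.seed
        )
        for sample, df in frags.items():
            path = frag_dir / f"{sample}.bed"
            io.write_bed6(df, path)
            files[f"fragments/{sample}"] = path

    manifest = {
        "config": _config_to_jsonable(config),
        "files": {
            key: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for key, p in files.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=list))
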