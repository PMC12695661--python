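"""Shared fixtures: small simulated datasets and independent oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from euseqtools import simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        n_genes=40,
        n_chromosomes=2,
        chrom_length=2_000_000,
        gene_length_range=(2_000, 40_000),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    genes, genome = simulate.generate_gene_models(small_config)
    counts, sheet, truth, antisense = simulate.generate_counts(small_config, genes)
    return {
        "config": small_config,
        "genes": genes,
        "genome": genome,
        "counts": counts,
        "sheet": sheet,
        "truth": truth,
        "antisense": antisense,
    }


# ---------------------------------------------------------------------------
# Independent oracles (deliberately brute force)
# ---------------------------------------------------------------------------

def brute_force_counts(
    fragments: pd.DataFrame,
    windows: pd.DataFrame,
    exclusion: pd.DataFrame | None = None,
    mode: str = "sense",
) -> pd.Series:
    """Per-window fragment counts by per-fragment scanning."""
    excl = [] if exclusion is None else list(exclusion.itertuples(index=False))
    out = {}
    for w in windows.itertuples(index=False):
        n = 0
        for f in fragments.itertuples(index=False):
            if f.chrom != w.chrom:
                continue
            if not (f.start < w.end and f.end > w.start):
                continue
            if mode == "sense" and f.strand != w.strand:
                continue
            if mode == "antisense" and f.strand == w.strand:
                continue
            if any(
                e.chrom == f.chrom and f.start < e.end and f.end > e.start for e in excl
            ):
                continue
            n += 1
        out[w.gene_id] = n
    return pd.Series(out)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    k_lo = max(0, col1 - (c + d))
    k_hi = min(row1, col1)
    ks = np.arange(k_lo, k_hi + 1)
    probs = hypergeom.pmf(ks, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def mwu_two_sided_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Assumes no ties. Two-sided p is twice the smaller tail, capped at 1.
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x)

    def u_stat(first, second):
        return sum(1 for a in first for b in second if a > b)

    u_obs = u_stat(x, y)
    us = [
        u_stat([pooled[i] for i in comb], [pooled[i] for i in range(len(pooled)) if i not in set(comb)])
        for comb in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.asarray(us)
    p_le = float((us <= u_obs).mean())
    p_ge = float((us >= u_obs).mean())
    return float(u_obs), min(1.0, 2 * min(p_le, p_ge))


def ks_statistic_sweep(a, b) -> float:
    """KS D by evaluating both ECDFs at every observed point."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    pts = np.concatenate([a, b])
    d = 0.0
    for x in pts:
        fa = np.searchsorted(a, x, side="right") / len(a)
        fb = np.searchsorted(b, x, side="right") / len(b)
        d = max(d, abs(fa - fb))
    return d


def bh_step_up(ps):
    """Hand BH step-up for cross-checks."""
    ps = list(ps)
    n = len(ps)
    order = sorted(range(n), key=lambda i: ps[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, ps[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def random_contingency_table(rng: np.random.Generator, max_n: int = 200):
    while True:
        cells = rng.integers(0, max_n // 2, size=4)
        if cells.sum() <= max_n and cells.sum() > 0:
            return tuple(int(v) for v in cells)
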