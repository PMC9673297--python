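"""Pairwise LD (r2 on genotype counts), sliding-window pruning, LD decay.

r2 is the squared Pearson correlation of genotype-count vectors (composite
LD); no phase information is assumed. Pruning mirrors the classic
``--indep-pairwise <window> <step> <r2>`` behaviour with deterministic
tie-breaking, and the retained count serves as the effective number of
independent tests for Bonferroni correction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .types import GenotypeMatrix
from .genotype_io import minor_allele_frequency

__all__ = [
    "ld_r2",
    "ld_prune",
    "bonferroni_threshold",
    "ld_decay_curve",
    "LDDecayCurve",
]


def ld_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of two genotype columns.

    Computed over samples non-missing at both sites. Raises if either site
    has zero variance among those samples.
    """
    mat = g.numeric()
    x, y = mat[:, i], mat[:, j]
    obs = ~(np.isnan(x) | np.isnan(y))
    x, y = x[obs], y[obs]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        raise ValueError(f"no variation at variant pair ({i}, {j})")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_matrix(cols: np.ndarray) -> np.ndarray:
    """Pairwise r2 of columns; missing cells mean-imputed per column."""
    x = cols.copy()
    mu = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    x[nan_mask] = np.take(mu, np.nonzero(nan_mask)[1])
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / x.shape[0]
    r = c / np.outer(sd, sd)
    return r * r


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy sliding-window LD pruning per chromosome.

    Within each window of ``window_snps`` successive SNPs, while any retained
    pair has r2 > ``r2_max``, the member with the smaller MAF is removed
    (tie -> the larger position); the window then advances by ``step_snps``.
    Returns the sorted indices (into ``g.variants``) of retained SNPs.
    """
    if not window_snps > step_snps >= 1:
        raise ValueError("require window_snps > step_snps >= 1")
    mat = g.numeric()
    maf = np.array([minor_allele_frequency(g, j) for j in range(g.n_variants)])
    pos = np.array([v.pos for v in g.variants])
    chroms = np.array([v.chrom for v in g.variants])

    removed = np.zeros(g.n_variants, dtype=bool)
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while True:
            win = idx[start : start + window_snps]
            active = win[~removed[win]]
            if active.size > 1:
                r2 = _r2_matrix(mat[:, active])
                alive = np.ones(active.size, dtype=bool)
                while True:
                    hit = None
                    for a in range(active.size):
                        if not alive[a]:
                            continue
                        for b in range(a + 1, active.size):
                            if alive[b] and r2[a, b] > r2_max:
                                hit = (a, b)
                                break
                        if hit:
                            break
                    if hit is None:
                        break
                    a, b = hit
                    ia, ib = active[a], active[b]
                    if maf[ia] < maf[ib]:
                        drop = a
                    elif maf[ib] < maf[ia]:
                        drop = b
                    else:  # tie -> larger position
                        drop = a if pos[ia] > pos[ib] else b
                    alive[drop] = False
                    removed[active[drop]] = True
            if start + window_snps >= idx.size:
                break
            start += step_snps
    return np.flatnonzero(~removed)


def bonferroni_threshold(alpha: float = 0.05, n_effective: int = 1) -> float:
    """Genome-wide significance threshold alpha / N_effective."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_effective < 1:
        raise ValueError("n_effective must be >= 1")
    return alpha / n_effective


@dataclasses.dataclass
class LDDecayCurve:
    """Mean r2 of SNP pairs binned by physical distance."""

    bin_edges: np.ndarray  # (B+1,) bp
    mean_r2: np.ndarray  # (B,) nan for empty bins
    n_pairs: np.ndarray  # (B,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "n_pairs": self.n_pairs,
                "mean_r2": self.mean_r2,
            }
        )


def ld_decay_curve(
    g: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    bin_bp: int = 1000,
    max_pairs_per_chrom: int | None = 100_000,
    seed: int | None = None,
) -> LDDecayCurve:
    """r2 against distance for intra-chromosome SNP pairs, averaged per bin.

    Pairs farther apart than ``max_dist_bp`` are ignored; when a chromosome
    has more eligible pairs than ``max_pairs_per_chrom`` a reproducible
    random subset is used.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(0, max_dist_bp + bin_bp, bin_bp)
    nbins = edges.size - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)

    mat = g.numeric()
    chroms = np.array([v.chrom for v in g.variants])
    pos = np.array([v.pos for v in g.variants])
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if idx.size < 2:
            continue
        ii, jj = np.triu_indices(idx.size, k=1)
        dist = pos[idx[jj]] - pos[idx[ii]]
        ok = dist <= max_dist_bp
        ii, jj, dist = ii[ok], jj[ok], dist[ok]
        if max_pairs_per_chrom is not None and ii.size > max_pairs_per_chrom:
            sel = rng.choice(ii.size, size=max_pairs_per_chrom, replace=False)
            ii, jj, dist = ii[sel], jj[sel], dist[sel]
        if ii.size == 0:
            continue
        r2_full = _r2_matrix(mat[:, idx])
        r2 = r2_full[ii, jj]
        good = ~np.isnan(r2)
        b = np.minimum(np.searchsorted(edges, dist[good], side="right") - 1, nbins - 1)
        np.add.at(sums, b, r2[good])
        np.add.at(counts, b, 1)

    if counts.sum() == 0:
        warnings.warn("no eligible SNP pair for LD decay curve")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(edges, mean, counts)
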