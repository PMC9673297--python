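"""Sliding-window nucleotide diversity and Weir-Cockerham F_ST.

Windows are anchored at position 1 on each chromosome and advance by the
step size; trailing partial windows are kept and flagged. Per-site pi is
2ab / (N(N-1)) for a alternate and b reference alleles among N non-missing
alleles; a window's value is the site sum divided by the window size in bp.
F_ST uses the Weir & Cockerham (1984) per-site variance components with
ratio-of-sums (weighted) windowing; negative window values are permitted.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix

__all__ = [
    "WindowStat",
    "windowed_pi",
    "windowed_fst",
    "site_pi",
    "site_fst_components",
    "zscore_windows",
    "select_outlier_windows",
    "windows_to_frame",
]


@dataclasses.dataclass
class WindowStat:
    """One sliding-window statistic over [start, end], 1-based inclusive."""

    chrom: str
    start: int
    end: int
    value: float  # nan when undefined
    n_variants: int
    partial: bool = False


def _window_spans(max_pos: int, window_bp: int, step_bp: int):
    start = 1
    while start <= max_pos:
        end = start + window_bp - 1
        yield start, min(end, max_pos), end > max_pos
        start += step_bp


def site_pi(alt_count: int, n_alleles: int) -> float:
    """Per-site nucleotide diversity 2ab / (N(N-1))."""
    if n_alleles < 2:
        return 0.0
    a = alt_count
    b = n_alleles - alt_count
    return 2.0 * a * b / (n_alleles * (n_alleles - 1))


def windowed_pi(
    g: GenotypeMatrix, window_bp: int = 50_000, step_bp: int = 10_000
) -> list[WindowStat]:
    """Per-bp nucleotide diversity in sliding windows."""
    calls = g.calls
    obs = calls != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(
            n_alleles >= 2,
            2.0 * alt * (n_alleles - alt) / (n_alleles * np.maximum(n_alleles - 1, 1)),
            0.0,
        )

    chroms = np.array([v.chrom for v in g.variants])
    pos = np.array([v.pos for v in g.variants])
    out: list[WindowStat] = []
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        cpos, cpi = pos[sel], pi[sel]
        for start, end, partial in _window_spans(int(cpos.max()), window_bp, step_bp):
            inwin = (cpos >= start) & (cpos <= end)
            out.append(
                WindowStat(
                    chrom=chrom,
                    start=start,
                    end=end,
                    value=float(cpi[inwin].sum() / window_bp),
                    n_variants=int(inwin.sum()),
                    partial=partial,
                )
            )
    return out


def site_fst_components(
    n1: int, p1: float, h1: float, n2: int, p2: float, h2: float
) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) per-site variance components (a, b, c).

    ``n_i`` are diploid sample sizes, ``p_i`` alternate-allele frequencies and
    ``h_i`` observed heterozygote proportions in the two populations.
    F_ST at the site is a / (a + b + c).
    """
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if nbar <= 1:
        return (np.nan, np.nan, np.nan)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return (float(a), float(b), float(c))


def windowed_fst(
    g1: GenotypeMatrix,
    g2: GenotypeMatrix,
    window_bp: int = 50_000,
    step_bp: int = 10_000,
) -> list[WindowStat]:
    """Weir-Cockerham F_ST in sliding windows (ratio of summed components).

    Both matrices must carry the same variant list. Sites where either
    population has fewer than 2 non-missing genotypes are excluded. Windows
    with a zero denominator get nan.
    """
    if [v.key for v in g1.variants] != [v.key for v in g2.variants]:
        raise ValueError("the two populations must share an identical variant list")

    def _counts(g: GenotypeMatrix):
        obs = g.calls != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, g.calls, 0).sum(axis=0)
        het = np.where(obs, g.calls == 1, False).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
            h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
        return n, p, h

    n1, p1, h1 = _counts(g1)
    n2, p2, h2 = _counts(g2)

    m = g1.n_variants
    num = np.full(m, np.nan)
    den = np.full(m, np.nan)
    for j in range(m):
        if n1[j] < 2 or n2[j] < 2:
            continue
        a, b, c = site_fst_components(
            int(n1[j]), float(p1[j]), float(h1[j]), int(n2[j]), float(p2[j]), float(h2[j])
        )
        num[j], den[j] = a, a + b + c

    chroms = np.array([v.chrom for v in g1.variants])
    pos = np.array([v.pos for v in g1.variants])
    out: list[WindowStat] = []
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        cpos = pos[sel]
        cnum, cden = num[sel], den[sel]
        for start, end, partial in _window_spans(int(cpos.max()), window_bp, step_bp):
            inwin = (cpos >= start) & (cpos <= end) & ~np.isnan(cden)
            d = cden[inwin].sum()
            value = float(cnum[inwin].sum() / d) if inwin.any() and d != 0 else np.nan
            out.append(
                WindowStat(
                    chrom=chrom,
                    start=start,
                    end=end,
                    value=value,
                    n_variants=int(inwin.sum()),
                    partial=partial,
                )
            )
    return out


def zscore_windows(stats_list: list[WindowStat]) -> list[WindowStat]:
    """Z-transform window values ((x - mean)/sd across defined windows)."""
    vals = np.array([w.value for w in stats_list])
    ok = np.isfinite(vals)
    mu = vals[ok].mean()
    sd = vals[ok].std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance across windows; z-transform undefined")
    out = []
    for w, v in zip(stats_list, vals):
        out.append(dataclasses.replace(w, value=(v - mu) / sd if np.isfinite(v) else np.nan))
    return out


def select_outlier_windows(
    stats_list: list[WindowStat],
    quantile: float = 0.95,
    zscore: bool = False,
) -> tuple[list[WindowStat], list[tuple[str, int, int]]]:
    """Top-quantile outlier windows, merged into regions.

    Returns ``(selected_windows, merged_regions)`` where regions are
    (chrom, start, end) spans of overlapping or adjacent selected windows.
    """
    if zscore:
        stats_list = zscore_windows(stats_list)
    vals = np.array([w.value for w in stats_list])
    ok = np.isfinite(vals)
    if not ok.any():
        warnings.warn("no window with a defined value")
        return [], []
    cutoff = np.quantile(vals[ok], quantile)
    selected = [w for w, v in zip(stats_list, vals) if np.isfinite(v) and v >= cutoff]

    selected_sorted = sorted(selected, key=lambda w: (w.chrom, w.start))
    regions: list[tuple[str, int, int]] = []
    for w in selected_sorted:
        if regions and regions[-1][0] == w.chrom and w.start <= regions[-1][2] + 1:
            regions[-1] = (w.chrom, regions[-1][1], max(regions[-1][2], w.end))
        else:
            regions.append((w.chrom, w.start, w.end))
    return selected, regions


def windows_to_frame(stats_list: list[WindowStat], bed_style: bool = False) -> pd.DataFrame:
    """Window table; ``bed_style`` emits 0-based half-open starts."""
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in stats_list],
            "start": [w.start - 1 if bed_style else w.start for w in stats_list],
            "end": [w.end for w in stats_list],
            "value": [w.value for w in stats_list],
            "n_variants": [w.n_variants for w in stats_list],
            "partial": [w.partial for w in stats_list],
        }
    )
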