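"""Imputation-quality metrics against a high-coverage truth set.

Sites are matched on exact (chrom, pos, ref, alt) identity. Genotype
concordance (GC) is the per-site fraction of hard-called imputed genotypes
identical to the truth; genotype accuracy (GA) is the per-site Pearson
correlation between imputed dosages and truth genotype codes. Aggregates are
unweighted means over evaluable sites, optionally binned by truth-set MAF.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .genotype_io import minor_allele_frequency
from .types import MISSING, DosageMatrix, GenotypeMatrix, VariantMeta

__all__ = [
    "SiteMatch",
    "ImputationEvalResult",
    "match_sites",
    "genotype_concordance",
    "genotype_accuracy",
    "evaluate_imputation",
    "binned_metrics",
    "evaluate_design_grid",
]


@dataclasses.dataclass
class SiteMatch:
    """Exact-key join of two variant lists on (chrom, pos, ref, alt)."""

    pairs: list[tuple[int, int]]  # (truth index, test index)
    n_truth_only: int
    n_test_only: int
    n_duplicate_keys: int = 0


@dataclasses.dataclass
class ImputationEvalResult:
    """Per-site and aggregate GC/GA with MAF-bin support."""

    site_gc: np.ndarray  # (n_matched,) nan where not evaluable
    site_ga: np.ndarray  # (n_matched,) nan where skipped
    truth_maf: np.ndarray  # (n_matched,)
    mean_gc: float
    mean_ga: float
    n_sites_skipped_gc: int
    n_sites_skipped_ga: int
    match: SiteMatch


def match_sites(
    truth_variants: list[VariantMeta], test_variants: list[VariantMeta]
) -> SiteMatch:
    """Match sites shared between two variant lists by exact identity.

    Duplicated keys within a list keep the first occurrence; later
    duplicates are flagged in ``n_duplicate_keys``.
    """
    n_dup = 0
    truth_by_key: dict[tuple, int] = {}
    for i, v in enumerate(truth_variants):
        if v.key in truth_by_key:
            n_dup += 1
            continue
        truth_by_key[v.key] = i
    seen_test: set[tuple] = set()
    pairs: list[tuple[int, int]] = []
    matched_truth: set[int] = set()
    n_test_only = 0
    for j, v in enumerate(test_variants):
        if v.key in seen_test:
            n_dup += 1
            continue
        seen_test.add(v.key)
        i = truth_by_key.get(v.key)
        if i is None:
            n_test_only += 1
        else:
            pairs.append((i, j))
            matched_truth.add(i)
    n_truth_only = len(truth_by_key) - len(matched_truth)
    return SiteMatch(pairs, n_truth_only, n_test_only, n_dup)


def _as_hard_calls(test: GenotypeMatrix | DosageMatrix) -> GenotypeMatrix:
    return test if isinstance(test, GenotypeMatrix) else test.hard_calls()


def _shared_sample_index(
    truth_ids: list[str], test_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    pos = {s: i for i, s in enumerate(test_ids)}
    ti, si = [], []
    for i, s in enumerate(truth_ids):
        if s in pos:
            ti.append(i)
            si.append(pos[s])
    if not ti:
        raise ValueError("no shared samples between truth and test sets")
    return np.array(ti), np.array(si)


def genotype_concordance(
    truth: GenotypeMatrix,
    test: GenotypeMatrix | DosageMatrix,
    match: SiteMatch,
) -> tuple[np.ndarray, float, int]:
    """Per-site GC and its unweighted mean over evaluable sites.

    Cells missing in either set are excluded from the site's denominator;
    sites with no evaluable cell are skipped (nan) and counted.
    """
    hard = _as_hard_calls(test)
    ti, si = _shared_sample_index(truth.sample_ids, hard.sample_ids)
    gc = np.full(len(match.pairs), np.nan)
    n_skipped = 0
    for k, (i, j) in enumerate(match.pairs):
        a = truth.calls[ti, i]
        b = hard.calls[si, j]
        ok = (a != MISSING) & (b != MISSING)
        if not ok.any():
            n_skipped += 1
            continue
        gc[k] = float((a[ok] == b[ok]).mean())
    mean = float(np.nanmean(gc)) if np.isfinite(gc).any() else np.nan
    return gc, mean, n_skipped


def genotype_accuracy(
    truth: GenotypeMatrix,
    test: DosageMatrix,
    match: SiteMatch,
) -> tuple[np.ndarray, float, int]:
    """Per-site GA (dosage-truth Pearson r) and its mean over evaluable sites.

    Sites with fewer than 3 paired observations or zero variance in either
    vector are skipped (nan) and counted.
    """
    ti, si = _shared_sample_index(truth.sample_ids, test.sample_ids)
    ga = np.full(len(match.pairs), np.nan)
    n_skipped = 0
    for k, (i, j) in enumerate(match.pairs):
        a = truth.calls[ti, i].astype(float)
        a[truth.calls[ti, i] == MISSING] = np.nan
        b = test.dosages[si, j]
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3:
            n_skipped += 1
            continue
        x, y = a[ok], b[ok]
        if x.std() == 0 or y.std() == 0:
            n_skipped += 1
            continue
        ga[k] = float(np.corrcoef(x, y)[0, 1])
    mean = float(np.nanmean(ga)) if np.isfinite(ga).any() else np.nan
    return ga, mean, n_skipped


def evaluate_imputation(
    truth: GenotypeMatrix,
    test: GenotypeMatrix | DosageMatrix,
) -> ImputationEvalResult:
    """Match sites and compute per-site + mean GC and (for dosages) GA."""
    match = match_sites(truth.variants, test.variants)
    gc, mean_gc, skip_gc = genotype_concordance(truth, test, match)
    if isinstance(test, DosageMatrix):
        ga, mean_ga, skip_ga = genotype_accuracy(truth, test, match)
    else:
        ga = np.full(len(match.pairs), np.nan)
        mean_ga, skip_ga = np.nan, len(match.pairs)
    maf = np.array(
        [minor_allele_frequency(truth, i) for i, _ in match.pairs]
        if match.pairs
        else []
    )
    return ImputationEvalResult(
        site_gc=gc,
        site_ga=ga,
        truth_maf=maf,
        mean_gc=mean_gc,
        mean_ga=mean_ga,
        n_sites_skipped_gc=skip_gc,
        n_sites_skipped_ga=skip_ga,
        match=match,
    )


def binned_metrics(
    result: ImputationEvalResult,
    bin_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean GC/GA per truth-MAF bin.

    Bins are half-open [lo, hi) except the last, which is closed at 0.5.
    Empty bins are reported with count 0 and nan means.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 0.501, 0.05)
    bin_edges = np.asarray(bin_edges, dtype=float)
    nb = bin_edges.size - 1
    rows = []
    for b in range(nb):
        lo, hi = bin_edges[b], bin_edges[b + 1]
        if b == nb - 1:
            sel = (result.truth_maf >= lo) & (result.truth_maf <= hi)
        else:
            sel = (result.truth_maf >= lo) & (result.truth_maf < hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows.append(
                {
                    "maf_lo": lo,
                    "maf_hi": hi,
                    "n_sites": int(sel.sum()),
                    "mean_gc": float(np.nanmean(result.site_gc[sel])) if sel.any() else np.nan,
                    "mean_ga": float(np.nanmean(result.site_ga[sel])) if sel.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)


def evaluate_design_grid(
    truth: GenotypeMatrix,
    cells: list[tuple[int, float, DosageMatrix]],
) -> pd.DataFrame:
    """Mean GC/GA per (sample_size, depth) design cell, long format."""
    rows = []
    for sample_size, depth, test in cells:
        res = evaluate_imputation(truth, test)
        rows.append(
            {
                "sample_size": sample_size,
                "depth": depth,
                "mean_gc": res.mean_gc,
                "mean_ga": res.mean_ga,
                "n_sites": len(res.match.pairs),
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_size", "depth", "mean_gc", "mean_ga", "n_sites"]
    )
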