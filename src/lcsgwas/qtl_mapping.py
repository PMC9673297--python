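"""Simulation-based 95% confidence intervals for QTL and QTL heritability.

The drop-log(P) method: remove the lead SNP's estimated effect from the
phenotypes, then repeatedly (i) pick a SNP in the candidate region, (ii) add
the lead effect to that SNP, (iii) rescan the region with the multivariate
GLS test, and (iv) record the drop in -log10(P) between the scan's best SNP
and the planted causal SNP. The 95th percentile of the drops, D, defines the
CI: the span of region SNPs whose observed -log10(P) is within D of the
observed lead.

QTL heritability is the reduction in SNP-based heritability when the lead
SNP is fitted as a fixed effect (h2_QTL = h2 - h2_adjusted, clamped at 0).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .association import GLSScanner, QTLRecord, _align_genotypes, _impute_and_freqs
from .mixed_model import (
    ModelFrame,
    VarianceComponents,
    fit_multitrait_reml,
)
from .types import DosageMatrix, GenotypeMatrix

__all__ = [
    "DropLogPResult",
    "drop_logp_ci",
    "qtl_heritability",
    "ci_width",
    "summarize_ci_widths",
]


@dataclasses.dataclass
class DropLogPResult:
    """Drop-log(P) simulation output and the derived confidence interval."""

    drops: np.ndarray  # (S,) per-simulation drops, >= 0
    d95: float  # 95th percentile of the drops
    ci_start: int  # 1-based inclusive
    ci_end: int
    ci_width: int  # end - start + 1
    n_simulations: int
    seed: int | None
    lead_pos: int
    percentile: float = 95.0


def ci_width(start: int, end: int) -> int:
    """Inclusive width of a 1-based interval: end - start + 1."""
    if end < start:
        raise ValueError("end must be >= start")
    return end - start + 1


def summarize_ci_widths(
    intervals: list[tuple[int, int]], below_bp: int = 1_000_000
) -> dict:
    """Mean CI width and the fraction of intervals narrower than a cutoff."""
    widths = np.array([ci_width(s, e) for s, e in intervals], dtype=float)
    return {
        "widths": widths,
        "mean_width": float(widths.mean()),
        "fraction_below": float((widths < below_bp).mean()),
    }


def drop_logp_ci(
    frame: ModelFrame,
    vc: VarianceComponents,
    genotypes: GenotypeMatrix | DosageMatrix,
    qtl: QTLRecord,
    region_pad_bp: int = 1_000_000,
    n_sims: int = 1000,
    percentile: float = 95.0,
    seed: int | None = None,
) -> DropLogPResult:
    """Drop-log(P) confidence interval for one QTL.

    The candidate region is the QTL cluster bounds padded by
    ``region_pad_bp``. Causal SNPs are sampled without replacement while the
    region holds at least ``n_sims`` SNPs, with replacement otherwise.
    Variance components stay fixed at the null fit throughout.
    """
    rng = np.random.default_rng(seed)
    lo = qtl.start - region_pad_bp
    hi = qtl.end + region_pad_bp
    region_idx = np.array(
        [
            j
            for j, v in enumerate(genotypes.variants)
            if v.chrom == qtl.chrom and lo <= v.pos <= hi
        ],
        dtype=int,
    )
    positions = np.array([genotypes.variants[j].pos for j in region_idx])

    if region_idx.size < 2:
        warnings.warn("QTL region has < 2 SNPs; degenerate CI at the lead position")
        return DropLogPResult(
            drops=np.zeros(0),
            d95=0.0,
            ci_start=qtl.lead.pos,
            ci_end=qtl.lead.pos,
            ci_width=1,
            n_simulations=0,
            seed=seed,
            lead_pos=qtl.lead.pos,
            percentile=percentile,
        )

    mat = _align_genotypes(genotypes, frame.sample_ids)[:, region_idx]
    mat, _ = _impute_and_freqs(mat)

    scanner = GLSScanner(frame, vc)
    state = scanner.prepare(mat)
    alpha_obs, _, obs_nlp = scanner.scan_phenotype(state, scanner.Ytil)

    lead_local = int(np.nanargmax(obs_nlp))
    lead_pos = int(positions[lead_local])
    alpha_lead = alpha_obs[lead_local]

    # residual phenotype with the lead effect removed (rotated space)
    Wtil = state["Wtil"]
    Y_res = scanner.Ytil - np.outer(Wtil[:, lead_local], alpha_lead)

    # candidate causal SNPs: testable sites only (polymorphic, non-singular)
    testable = np.flatnonzero(state["ok"])
    if testable.size == 0:
        raise ValueError("no testable SNP in the QTL region")
    if testable.size >= n_sims:
        causal = rng.choice(testable, size=n_sims, replace=False)
    else:
        causal = rng.choice(testable, size=n_sims, replace=True)

    drops = np.empty(n_sims)
    for s, c in enumerate(causal):
        Ys = Y_res + np.outer(Wtil[:, c], alpha_lead)
        _, _, nlp = scanner.scan_phenotype(state, Ys)
        best = np.nanmax(nlp)
        drops[s] = max(best - nlp[c], 0.0)

    d = float(np.percentile(drops, percentile))
    qualify = obs_nlp >= obs_nlp[lead_local] - d - 1e-12
    qual_pos = positions[qualify]
    start, end = int(qual_pos.min()), int(qual_pos.max())
    return DropLogPResult(
        drops=drops,
        d95=d,
        ci_start=start,
        ci_end=end,
        ci_width=ci_width(start, end),
        n_simulations=n_sims,
        seed=seed,
        lead_pos=lead_pos,
        percentile=percentile,
    )


def qtl_heritability(
    vc_null: VarianceComponents,
    frame: ModelFrame,
    genotypes: GenotypeMatrix | DosageMatrix,
    lead_snp: int,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> dict:
    """Per-trait QTL heritability via lead-SNP-adjusted REML.

    Refits the variance components with the lead SNP's genotype appended to
    the fixed-effect design (one coefficient per trait) and returns
    ``h2`` (unadjusted), ``h2_adjusted`` and ``h2_qtl = h2 - h2_adjusted``
    (clamped at zero with a warning when negative), plus the adjusted fit.
    """
    mat = _align_genotypes(genotypes, frame.sample_ids)
    w = mat[:, lead_snp]
    mu = np.nanmean(w)
    w = np.where(np.isnan(w), mu, w)
    if np.std(w) == 0:
        raise ValueError("lead SNP is monomorphic; cannot adjust for it")

    adj_frame = ModelFrame(
        sample_ids=frame.sample_ids,
        trait_names=frame.trait_names,
        Y=frame.Y,
        X=np.column_stack([frame.X, w]),
        X_names=[*frame.X_names, "lead_snp"],
        K=frame.K,
        n_dropped=frame.n_dropped,
    )
    vc_adj = fit_multitrait_reml(adj_frame, max_iter=max_iter, tol=tol)
    if not vc_adj.converged:
        raise RuntimeError(
            "lead-adjusted REML did not converge "
            f"(null logL={vc_null.restricted_log_likelihood:.4f}, "
            f"adjusted logL={vc_adj.restricted_log_likelihood:.4f})"
        )
    h2 = vc_null.heritabilities()
    h2_adj = vc_adj.heritabilities()
    h2_qtl = h2 - h2_adj
    if (h2_qtl < 0).any():
        warnings.warn("negative QTL heritability clamped to 0")
        h2_qtl = np.clip(h2_qtl, 0.0, None)
    return {"h2": h2, "h2_adjusted": h2_adj, "h2_qtl": h2_qtl, "vc_adjusted": vc_adj}
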