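"""Synthetic cohort generator mirroring a low-coverage-sequencing study.

The generator emulates the statistical structure the downstream analyses
assume: ~600 diploid individuals from a haplotype-copying model (founder
haplotypes with per-site allele frequencies in the common range, Markov
switching between founders produces distance-decaying LD), traits at 3-4
time points with genetic covariance Sigma_u propagated through the realized
GRM, residual covariance Sigma_e, sex and house fixed effects, optional
injected QTL scaled to a requested fraction of phenotypic variance, and a
read-sampling model that turns true genotypes into low-coverage posterior
dosages at a given mean depth and base-error rate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .kinship import vanraden_grm
from .types import DosageMatrix, GenotypeMatrix, PhenotypeTable, VariantMeta

__all__ = [
    "QTLSpec",
    "SimConfig",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_lcs_dosages",
    "write_simulation",
]

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class QTLSpec:
    """One injected causal SNP: flat variant index + per-trait variance fractions."""

    snp_index: int
    variance_fractions: tuple[float, ...]  # length t, each in [0, 1)


def _default_sigma(t: int, h2: tuple[float, ...], re_corr: float, rg_corr: float):
    """Unit-phenotypic-variance Sigma_u / Sigma_e from target heritabilities."""
    h2 = np.asarray(h2[:t])
    su_d = h2
    se_d = 1.0 - h2
    rg = np.full((t, t), rg_corr) + (1 - rg_corr) * np.eye(t)
    re = np.full((t, t), re_corr) + (1 - re_corr) * np.eye(t)
    su = rg * np.sqrt(np.outer(su_d, su_d))
    se = re * np.sqrt(np.outer(se_d, se_d))
    return su, se


@dataclasses.dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults follow the emulated design: ~600 individuals, common variants
    (MAF in [0.05, 0.5]) on several chromosomes with LD, three time points
    with heritabilities (0.10, 0.25, 0.40) and genetic correlation 0.5, sex
    plus five houses as fixed effects, and a low-coverage read model.
    """

    seed: int = 0
    n_individuals: int = 600
    n_snps: int = 5000
    n_chromosomes: int = 5
    n_founder_haplotypes: int = 10
    switch_rate: float = 0.02  # per adjacent-SNP founder-switch probability
    ancestral_ld_bp: float = 150_000.0  # founder-haplotype allele-retention scale; 0 = none
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_spacing_bp: int = 1000
    t_traits: int = 3
    sigma_u: np.ndarray | None = None  # (t, t); default from h2/rg below
    sigma_e: np.ndarray | None = None
    h2: tuple[float, ...] = (0.10, 0.25, 0.40, 0.30)
    genetic_corr: float = 0.5
    residual_corr: float = 0.3
    sex_effects: np.ndarray | None = None  # (t,); default 0.5 per trait
    n_houses: int = 5
    house_effects: np.ndarray | None = None  # (H, t)
    qtls: list[QTLSpec] = dataclasses.field(default_factory=list)
    depth: float = 1.0
    base_error: float = 0.01

    def __post_init__(self) -> None:
        t = self.t_traits
        if self.sigma_u is None or self.sigma_e is None:
            su, se = _default_sigma(t, self.h2, self.residual_corr, self.genetic_corr)
            if self.sigma_u is None:
                self.sigma_u = su
            if self.sigma_e is None:
                self.sigma_e = se
        self.sigma_u = np.atleast_2d(np.asarray(self.sigma_u, dtype=float))
        self.sigma_e = np.atleast_2d(np.asarray(self.sigma_e, dtype=float))
        for name, m in (("sigma_u", self.sigma_u), ("sigma_e", self.sigma_e)):
            if m.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            if np.linalg.eigvalsh((m + m.T) / 2).min() < -1e-8:
                raise ValueError(f"{name} must be positive semidefinite")
        if self.sex_effects is None:
            self.sex_effects = np.full(t, 0.5)
        self.sex_effects = np.asarray(self.sex_effects, dtype=float)
        if self.house_effects is None:
            self.house_effects = np.outer(
                np.linspace(-0.5, 0.5, self.n_houses), np.ones(t)
            )
        self.house_effects = np.asarray(self.house_effects, dtype=float)
        for q in self.qtls:
            frac = np.asarray(q.variance_fractions, dtype=float)
            if (frac < 0).any() or frac.sum() >= 1:
                raise ValueError("QTL variance fractions must be >= 0 and sum < 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("sigma_u", "sigma_e", "sex_effects", "house_effects"):
            d[k] = np.asarray(d[k]).tolist()
        d["qtls"] = [
            {"snp_index": q.snp_index, "variance_fractions": list(q.variance_fractions)}
            for q in self.qtls
        ]
        return d


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw diploid genotypes from a founder haplotype-copying model.

    Founder haplotypes carry per-site alternate alleles at frequencies drawn
    uniformly from ``maf_range``; within a founder, an allele is retained from
    the previous site with probability exp(-spacing / ancestral_ld_bp), so the
    founder pool itself carries distance-decaying ancestral LD. Each sample
    haplotype then copies a founder and switches to a random founder with
    probability ``switch_rate`` at each SNP step, which creates the mosaic
    relatedness structure. Returns the genotype matrix and the (2n, m)
    haplotype array.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m, C, F = cfg.n_individuals, cfg.n_snps, cfg.n_chromosomes, cfg.n_founder_haplotypes

    per_chrom = np.array_split(np.arange(m), C)
    # positions first: the founder allele-retention probability is distance based
    positions = np.empty(m, dtype=int)
    for c, idx in enumerate(per_chrom):
        spacing = rng.integers(1, 2 * cfg.mean_spacing_bp, size=idx.size)
        positions[idx] = np.cumsum(spacing)

    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    fresh = (rng.random((F, m)) < freqs).astype(np.int8)
    founders = np.empty((F, m), dtype=np.int8)
    for c, idx in enumerate(per_chrom):
        founders[:, idx[0]] = fresh[:, idx[0]]
        if cfg.ancestral_ld_bp > 0:
            gaps = np.diff(positions[idx]).astype(float)
            retain_p = np.exp(-gaps / cfg.ancestral_ld_bp)
        else:
            retain_p = np.zeros(idx.size - 1)
        retained = rng.random((F, idx.size - 1)) < retain_p[None, :]
        for k in range(1, idx.size):
            j, jprev = idx[k], idx[k - 1]
            founders[:, j] = np.where(retained[:, k - 1], founders[:, jprev], fresh[:, j])

    # copying paths for all 2n haplotypes at once
    switch = rng.random((2 * n, m)) < cfg.switch_rate
    # chromosome starts always resample the founder
    for idx in per_chrom:
        switch[:, idx[0]] = True
    anchor = np.where(switch, np.arange(m)[None, :], 0)
    anchor = np.maximum.accumulate(anchor, axis=1)
    founder_draw = rng.integers(0, F, size=(2 * n, m))
    path = np.take_along_axis(founder_draw, anchor, axis=1)
    haps = founders[path, np.arange(m)[None, :]]
    calls = (haps[0::2] + haps[1::2]).astype(np.int8)

    variants: list[VariantMeta] = []
    for c, idx in enumerate(per_chrom):
        for j in idx:
            ref, alt = rng.choice(4, size=2, replace=False)
            variants.append(
                VariantMeta(str(c + 1), int(positions[j]), _BASES[ref], _BASES[alt])
            )

    sample_ids = [f"ind{i:04d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, variants, calls), haps


def _matrix_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    return (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


def simulate_phenotypes(
    g: GenotypeMatrix, cfg: SimConfig
) -> tuple[PhenotypeTable, dict]:
    """Draw phenotypes y = Xb + QTL + u + e on simulated genotypes.

    u ~ N(0, Sigma_u (x) K) with K the VanRaden GRM of ``g``; e ~ N(0,
    Sigma_e (x) I). Each QTL's per-trait effect beta solves
    2p(1-p) beta^2 = fraction * total phenotypic variance, where the total
    is (Sigma_u,kk + Sigma_e,kk)/(1 - fraction). Returns the phenotype table
    and a truth dict (breeding values, QTL betas, covariates).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n, t = g.n_samples, cfg.t_traits
    su, se = cfg.sigma_u, cfg.sigma_e

    sex = rng.integers(0, 2, size=n)
    house = rng.integers(1, cfg.n_houses + 1, size=n)
    Xb = sex[:, None] * cfg.sex_effects[None, :] + cfg.house_effects[house - 1, :]

    if np.allclose(su, 0):
        u = np.zeros((n, t))
    else:
        K = vanraden_grm(g).K
        Ksqrt = _matrix_sqrt(K)
        u = Ksqrt @ rng.standard_normal((n, t)) @ _matrix_sqrt(su)
    e = rng.standard_normal((n, t)) @ _matrix_sqrt(se)

    qtl_term = np.zeros((n, t))
    betas = []
    for q in cfg.qtls:
        w = g.calls[:, q.snp_index].astype(float)
        p = w.mean() / 2.0
        var_w = 2.0 * p * (1.0 - p)
        if var_w <= 0:
            raise ValueError(f"QTL SNP {q.snp_index} is monomorphic")
        frac = np.asarray(q.variance_fractions, dtype=float)
        total = (np.diag(su) + np.diag(se)) / np.clip(1.0 - frac, 1e-12, None)
        beta = np.sqrt(frac * total / var_w)
        qtl_term += np.outer(w - 2.0 * p, beta)
        betas.append(beta)

    y = Xb + qtl_term + u + e
    ph = PhenotypeTable(
        sample_ids=list(g.sample_ids),
        trait_names=[f"trait_t{i + 1}" for i in range(t)],
        trait_values=y,
        sex=sex,
        house=house,
    )
    truth = {
        "breeding_values": u,
        "qtl_betas": betas,
        "sex": sex,
        "house": house,
        "fixed_part": Xb,
        "qtl_part": qtl_term,
    }
    return ph, truth


def simulate_lcs_dosages(
    g: GenotypeMatrix,
    depth: float,
    base_error: float = 0.01,
    seed: int | None = None,
) -> DosageMatrix:
    """Posterior dosages from a low-coverage read-sampling model.

    Per cell: read count ~ Poisson(depth); alternate-supporting reads ~
    Binomial(reads, f) with f = (g/2)(1 - eps) + (1 - g/2) eps for true
    genotype g; genotype posterior under a Hardy-Weinberg prior at the
    site's true allele frequency; dosage = posterior mean. Cells with zero
    reads fall back to the prior mean and are flagged in the
    ``zero_read_mask`` attribute of the result.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0 <= base_error < 0.5:
        raise ValueError("base_error must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n, m = g.calls.shape
    truth = g.calls.astype(float)
    p_site = truth.mean(axis=0) / 2.0  # true alternate frequency

    reads = rng.poisson(depth, size=(n, m))
    f = (truth / 2.0) * (1.0 - base_error) + (1.0 - truth / 2.0) * base_error
    alt_reads = rng.binomial(reads, f)

    eps = base_error
    f_geno = np.array([eps, 0.5, 1.0 - eps])  # alt-read prob per genotype
    prior = np.stack(
        [(1 - p_site) ** 2, 2 * p_site * (1 - p_site), p_site**2], axis=-1
    )  # (m, 3)
    from scipy.special import xlogy

    k = alt_reads[..., None].astype(float)
    r = reads[..., None].astype(float)
    # xlogy handles 0*log(0) = 0, so base_error = 0 stays exact
    loglik = xlogy(k, f_geno) + xlogy(r - k, 1.0 - f_geno)
    logpost = np.log(np.clip(prior[None, :, :], 1e-300, None)) + loglik
    logpost -= logpost.max(axis=-1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=-1, keepdims=True)

    dosage = post[..., 1] + 2.0 * post[..., 2]
    out = DosageMatrix(
        sample_ids=list(g.sample_ids),
        variants=list(g.variants),
        dosages=np.clip(dosage, 0.0, 2.0),
        probs=post,
    )
    out.zero_read_mask = reads == 0  # type: ignore[attr-defined]
    return out


def write_simulation(outdir: str | Path, cfg: SimConfig) -> dict:
    """Run the full generator and write truth VCF, dosage VCF, phenotypes, config."""
    from .genotype_io import write_genotypes, write_phenotypes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, _ = simulate_genotypes(cfg)
    ph, truth = simulate_phenotypes(g, cfg)
    ds = simulate_lcs_dosages(g, cfg.depth, cfg.base_error, seed=cfg.seed + 2)
    write_genotypes(g, outdir / "truth.vcf")
    write_genotypes(ds, outdir / "dosages.vcf")
    write_phenotypes(ph, outdir / "phenotypes.tsv")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    return {"genotypes": g, "phenotypes": ph, "dosages": ds, "truth": truth}
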