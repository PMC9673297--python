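import dataclasses

import numpy as np
import pytest

from lcsgwas.kinship import vanraden_grm
from lcsgwas.mixed_model import build_model_frame, fit_multitrait_reml
from lcsgwas.simdata import QTLSpec, SimConfig, simulate_genotypes, simulate_phenotypes
from lcsgwas.types import MISSING, GenotypeMatrix, VariantMeta


def make_genotypes(calls, chrom="1", start=100, spacing=100, sample_prefix="s"):
    """Small handcrafted GenotypeMatrix from an (n, m) array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    variants = [
        VariantMeta(chrom, start + j * spacing, "A", "G") for j in range(m)
    ]
    return GenotypeMatrix([f"{sample_prefix}{i}" for i in range(n)], variants, calls)


def pick_snp_near_maf(g, chrom, target=0.25):
    """Index of the SNP on `chrom` whose MAF is closest to `target`."""
    freqs = g.calls.mean(axis=0) / 2.0
    maf = np.minimum(freqs, 1 - freqs)
    idx = [j for j, v in enumerate(g.variants) if v.chrom == chrom]
    return idx[int(np.argmin(np.abs(maf[idx] - target)))]


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-individual, 1000-SNP cohort with a fitted null model (t=3)."""
    cfg = SimConfig(seed=42, n_individuals=300, n_snps=1000, n_chromosomes=2, t_traits=3)
    g, _ = simulate_genotypes(cfg)
    ph, truth = simulate_phenotypes(g, cfg)
    grm = vanraden_grm(g)
    frame = build_model_frame(ph, grm)
    vc = fit_multitrait_reml(frame)
    return {"cfg": cfg, "g": g, "ph": ph, "grm": grm, "frame": frame, "vc": vc, "truth": truth}


@pytest.fixture(scope="session")
def qtl_cohort():
    """Single-trait cohort with one injected QTL (8% of phenotypic variance)."""
    cfg = SimConfig(
        seed=7, n_individuals=400, n_snps=1500, n_chromosomes=3, t_traits=1, h2=(0.3,)
    )
    g, _ = simulate_genotypes(cfg)
    causal = pick_snp_near_maf(g, "1", 0.25)
    cfg = dataclasses.replace(cfg, qtls=[QTLSpec(causal, (0.08,))])
    ph, _ = simulate_phenotypes(g, cfg)
    frame = build_model_frame(ph, vanraden_grm(g))
    vc = fit_multitrait_reml(frame)
    return {"cfg": cfg, "g": g, "frame": frame, "vc": vc, "causal": causal}
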