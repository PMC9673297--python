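"""Core in-memory containers for genotype, dosage and phenotype data.

Genotypes are stored sample-major: an ``n x m`` integer matrix of
alternate-allele counts with ``MISSING`` (= -1) as the sentinel for no-calls.
Dosages use ``numpy.nan`` as the missing sentinel because they are continuous.
All genomic coordinates are 1-based and inclusive, as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Sentinel for a missing hard call; distinct from the valid codes {0, 1, 2}.
MISSING = -1


@dataclass(frozen=True)
class VariantMeta:
    """A biallelic SNP: chromosome, 1-based position, ref/alt alleles.

    ``info_score`` carries the imputation-quality score (in [0, 1]) when the
    variant came from an imputed VCF; ``None`` means not available.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    info_score: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Shared-site identity: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


def _check_variants_sorted(variants: Sequence[VariantMeta]) -> None:
    last: dict[str, int] = {}
    for v in variants:
        if v.chrom in last and v.pos <= last[v.chrom]:
            raise ValueError(
                f"positions must be strictly increasing within a chromosome; "
                f"{v.chrom}:{v.pos} follows {v.chrom}:{last[v.chrom]}"
            )
        last[v.chrom] = v.pos


@dataclass
class GenotypeMatrix:
    """Hard-called genotypes: alternate-allele counts in {0, 1, 2, MISSING}."""

    sample_ids: list[str]
    variants: list[VariantMeta]
    calls: np.ndarray  # (n, m) int8/int16, MISSING = -1

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        n, m = self.calls.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad}; expected 0/1/2/{MISSING}")
        _check_variants_sorted(self.variants)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in idx],
            calls=self.calls[:, idx],
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=list(self.variants),
            calls=self.calls[idx, :],
        )

    def numeric(self) -> np.ndarray:
        """Float copy with MISSING as nan (for correlation/covariance work)."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out


@dataclass
class DosageMatrix:
    """Continuous alternate-allele dosages in [0, 2]; nan marks missing cells.

    ``probs`` optionally stores the genotype-probability triples
    (P(hom-ref), P(het), P(hom-alt)) as an (n, m, 3) array. When present,
    each triple sums to 1 and dosage = P(het) + 2 P(hom-alt), both to 1e-6.
    """

    sample_ids: list[str]
    variants: list[VariantMeta]
    dosages: np.ndarray  # (n, m) float, nan = missing
    probs: np.ndarray | None = None  # (n, m, 3)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValueError("dosage shape does not match sample/variant counts")
        obs = ~np.isnan(self.dosages)
        if ((self.dosages[obs] < 0) | (self.dosages[obs] > 2)).any():
            raise ValueError("dosages must lie in [0, 2]")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)
            if self.probs.shape != (n, m, 3):
                raise ValueError("probs must have shape (n, m, 3)")
            psum = self.probs.sum(axis=2)
            if np.nanmax(np.abs(psum[obs] - 1.0)) > 1e-6:
                raise ValueError("genotype probability triples must sum to 1")
            implied = self.probs[..., 1] + 2.0 * self.probs[..., 2]
            if np.nanmax(np.abs(implied[obs] - self.dosages[obs])) > 1e-6:
                raise ValueError("dosage must equal P(het) + 2 P(hom-alt)")
        _check_variants_sorted(self.variants)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "DosageMatrix":
        idx = np.asarray(idx, dtype=int)
        return DosageMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx],
            probs=None if self.probs is None else self.probs[:, idx, :],
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "DosageMatrix":
        idx = np.asarray(idx, dtype=int)
        return DosageMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=list(self.variants),
            dosages=self.dosages[idx, :],
            probs=None if self.probs is None else self.probs[idx, :, :],
        )

    def hard_calls(self) -> GenotypeMatrix:
        """Collapse to hard calls.

        With probability triples: argmax of the triple (tie -> heterozygote).
        Otherwise: dosage rounded to the nearest integer (exact .5 -> 1).
        Missing cells stay MISSING.
        """
        n, m = self.dosages.shape
        if self.probs is not None:
            p = self.probs
            # tie -> het: bias the het column by a hair before argmax
            tiebreak = np.array([0.0, 1e-12, 0.0])
            calls = np.argmax(p + tiebreak, axis=2).astype(np.int8)
        else:
            d = self.dosages
            calls = np.floor(d + 0.5).astype(np.int8)  # exact .5 rounds up
            calls = np.clip(calls, 0, 2)
        calls = np.where(np.isnan(self.dosages), np.int8(MISSING), calls)
        return GenotypeMatrix(list(self.sample_ids), list(self.variants), calls)

    def numeric(self) -> np.ndarray:
        return self.dosages.copy()


@dataclass
class PhenotypeTable:
    """Traits (one trait measured at t time points) plus fixed covariates.

    ``trait_values`` is (n, t) with nan for missing records. ``sex`` is binary
    (0/1) and ``house`` holds integer levels 1..H; both may contain -1 for a
    missing covariate (such individuals are dropped at model-frame build).
    """

    sample_ids: list[str]
    trait_names: list[str]
    trait_values: np.ndarray  # (n, t) float, nan = missing
    sex: np.ndarray  # (n,) int in {0, 1, -1}
    house: np.ndarray  # (n,) int levels, -1 = missing

    def __post_init__(self) -> None:
        self.trait_values = np.atleast_2d(np.asarray(self.trait_values, dtype=float))
        self.sex = np.asarray(self.sex, dtype=int)
        self.house = np.asarray(self.house, dtype=int)
        n, t = self.trait_values.shape
        if t < 1:
            raise ValueError("need at least one trait")
        if len(self.trait_names) != t:
            raise ValueError("trait_names length does not match trait_values")
        if len(self.sample_ids) != n or self.sex.shape != (n,) or self.house.shape != (n,):
            raise ValueError("sample/covariate lengths do not match trait_values")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.trait_values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.trait_values.shape[1]


@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its scaling denominator."""

    K: np.ndarray  # (n, n) symmetric
    sample_ids: list[str]
    denominator: float  # sum over SNPs of 2 p_j (1 - p_j)
    n_snps_used: int
    freq_convention: str = "alt"

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n) or n != len(self.sample_ids):
            raise ValueError("K must be square and match sample_ids")
        if np.abs(self.K - self.K.T).max() > 1e-10:
            raise ValueError("K must be symmetric")
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        # trace can be exactly 0 in the degenerate all-identical-samples case
        if np.trace(self.K) < 0:
            raise ValueError("K must have non-negative trace")

    @property
    def n_samples(self) -> int:
        return self.K.shape[0]

    def subset(self, idx: Sequence[int] | np.ndarray) -> "GRM":
        idx = np.asarray(idx, dtype=int)
        return GRM(
            K=self.K[np.ix_(idx, idx)],
            sample_ids=[self.sample_ids[i] for i in idx],
            denominator=self.denominator,
            n_snps_used=self.n_snps_used,
            freq_convention=self.freq_convention,
        )
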