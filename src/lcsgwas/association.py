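"""Multivariate GWAS with Wald chi-square tests, conditional GWAS, QTL calls.

Each SNP is added to the null multi-trait LMM as a fixed effect with one
allele-substitution coefficient per trait ((I_t (x) w) alpha); alpha is
estimated by GLS with the variance components held at their null-model REML
estimates, and significance comes from the Wald statistic
W = alpha' var(alpha)^{-1} alpha ~ chi2(t). Conditional GWAS additionally
fixes the lead SNP's genotype as t covariates.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_model import ModelFrame, VarianceComponents, _RotatedModel
from .types import DosageMatrix, GenotypeMatrix, VariantMeta

__all__ = [
    "AssocRecord",
    "QTLRecord",
    "GLSScanner",
    "multivariate_gwas",
    "conditional_gwas",
    "wald_test",
    "cluster_qtl",
    "records_to_frame",
]

_LOG10 = math.log(10.0)


@dataclasses.dataclass
class AssocRecord:
    """Per-SNP multivariate association result."""

    variant: VariantMeta
    alpha: np.ndarray  # (t,) per-trait allele-substitution effects
    cov_alpha: np.ndarray  # (t, t)
    wald: float
    df: int
    p_value: float
    neglog10_p: float


@dataclasses.dataclass
class QTLRecord:
    """A cluster of significant SNPs with its lead (minimum-p) member."""

    chrom: str
    member_variants: list[VariantMeta]
    member_pvalues: list[float]
    lead: VariantMeta
    lead_p: float
    lead_alpha: np.ndarray
    start: int
    end: int
    ci_start: int | None = None
    ci_end: int | None = None
    ci_width: int | None = None
    qtl_h2: np.ndarray | None = None


def wald_test(alpha_hat: np.ndarray, cov_alpha: np.ndarray) -> tuple[float, int, float]:
    """Wald chi-square test of a multivariate SNP effect.

    Returns (statistic, df, p) with df = len(alpha_hat); requires a symmetric
    positive-definite covariance.
    """
    alpha_hat = np.atleast_1d(np.asarray(alpha_hat, dtype=float))
    cov_alpha = np.atleast_2d(np.asarray(cov_alpha, dtype=float))
    t = alpha_hat.size
    if np.abs(cov_alpha - cov_alpha.T).max() > 1e-8 * (1 + np.abs(cov_alpha).max()):
        raise ValueError("covariance must be symmetric")
    try:
        L = np.linalg.cholesky(cov_alpha)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    z = np.linalg.solve(L, alpha_hat)
    w = float(z @ z)
    return w, t, float(stats.chi2.sf(w, t))


def _align_genotypes(
    genotypes: GenotypeMatrix | DosageMatrix, sample_ids: list[str]
) -> np.ndarray:
    pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
    missing = [s for s in sample_ids if s not in pos]
    if missing:
        raise ValueError(f"samples absent from genotypes: {missing[:5]}...")
    mat = genotypes.numeric()[[pos[s] for s in sample_ids], :]
    return mat


class GLSScanner:
    """Vectorized GLS machinery for scanning SNPs under fixed (Su, Se).

    Precomputes the rotated design and per-individual inverse covariance
    blocks; ``scan`` tests a matrix of SNP columns and ``scan_phenotype``
    rescans a prepared SNP set against a new rotated phenotype (used by the
    drop-log(P) simulations, where only the phenotype changes).
    """

    def __init__(
        self,
        frame: ModelFrame,
        vc: VarianceComponents,
        extra_covariates: np.ndarray | None = None,
    ):
        self.frame = frame
        rot = _RotatedModel(frame)
        self.U = rot.U
        self.lam = rot.lam
        self.Ytil = rot.Y
        X = frame.X
        if extra_covariates is not None:
            extra = np.atleast_2d(np.asarray(extra_covariates, dtype=float))
            if extra.shape[0] != frame.n_samples:
                extra = extra.T
            X = np.column_stack([X, extra])
        self.Xtil = self.U.T @ X
        self.t = rot.t
        self.p = self.Xtil.shape[1]
        V = self.lam[:, None, None] * vc.sigma_u[None] + vc.sigma_e[None]
        self.Vinv = np.linalg.inv(V)
        tp = self.t * self.p
        self.C = np.einsum(
            "iab,ip,iq->apbq", self.Vinv, self.Xtil, self.Xtil
        ).reshape(tp, tp)
        self.Cinv = np.linalg.inv(self.C)

    # -- SNP preparation ---------------------------------------------------

    def prepare(self, W: np.ndarray) -> dict:
        """Precompute SNP-side tensors for a (n, m) genotype/dosage matrix.

        Missing cells must already be mean-imputed. Returns the opaque state
        consumed by :meth:`scan` and :meth:`scan_phenotype`.
        """
        Wtil = self.U.T @ W
        t, p = self.t, self.p
        Txw = np.einsum("iab,ip,ij->japb", self.Vinv, self.Xtil, Wtil).reshape(
            W.shape[1], t * p, t
        )
        Tww = np.einsum("iab,ij->jab", self.Vinv, Wtil**2)
        CinvTxw = np.einsum("kl,jlb->jkb", self.Cinv, Txw)
        S = Tww - np.einsum("jka,jkb->jab", Txw, CinvTxw)  # precision of alpha
        # batched inverse with a singularity guard
        ok = np.ones(W.shape[1], dtype=bool)
        Sinv = np.zeros_like(S)
        for j in range(S.shape[0]):
            try:
                Sinv[j] = np.linalg.inv(S[j])
                if not np.isfinite(Sinv[j]).all():
                    ok[j] = False
            except np.linalg.LinAlgError:
                ok[j] = False
        return {"Wtil": Wtil, "Txw": Txw, "S": S, "Sinv": Sinv, "ok": ok}

    def scan_phenotype(self, state: dict, Ytil: np.ndarray):
        """Test every prepared SNP against a rotated phenotype matrix (n, t).

        Returns (alpha (m,t), wald (m,), neglog10p (m,)).
        """
        VY = np.einsum("iab,ib->ia", self.Vinv, Ytil)
        rw = np.einsum("ia,ij->ja", VY, state["Wtil"])
        rx = np.einsum("ia,ip->ap", VY, self.Xtil).reshape(self.t * self.p)
        rhs = rw - np.einsum("jka,k->ja", state["Txw"], self.Cinv @ rx)
        alpha = np.einsum("jab,jb->ja", state["Sinv"], rhs)
        wald = np.einsum("ja,ja->j", rhs, alpha)
        wald = np.where(state["ok"], np.clip(wald, 0.0, None), np.nan)
        neglog10p = -stats.chi2.logsf(wald, self.t) / _LOG10
        return alpha, wald, neglog10p

    def scan(self, W: np.ndarray):
        """Full scan of (n, m) SNP columns against the frame's phenotype."""
        state = self.prepare(W)
        alpha, wald, nlp = self.scan_phenotype(state, self.Ytil)
        cov = state["Sinv"]
        return alpha, cov, wald, nlp, state["ok"]


def _impute_and_freqs(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(mat, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    out = np.where(np.isnan(mat), mu[None, :], mat)
    p = mu / 2.0
    return out, p


def multivariate_gwas(
    frame: ModelFrame,
    vc: VarianceComponents,
    genotypes: GenotypeMatrix | DosageMatrix,
    chunk_size: int = 2000,
) -> tuple[list[AssocRecord], int]:
    """Multivariate Wald-test GWAS over all SNPs.

    Variance components stay fixed at the null-model REML estimates.
    Monomorphic SNPs (MAF < 1e-6 among tested samples) and SNPs with a
    singular effect covariance are skipped. Returns (records, n_skipped).
    """
    mat = _align_genotypes(genotypes, frame.sample_ids)
    mat, p = _impute_and_freqs(mat)
    maf = np.minimum(p, 1.0 - p)
    testable = maf >= 1e-6
    n_skipped = int((~testable).sum())

    scanner = GLSScanner(frame, vc)
    records: list[AssocRecord] = []
    idx_all = np.flatnonzero(testable)
    for lo in range(0, idx_all.size, chunk_size):
        idx = idx_all[lo : lo + chunk_size]
        alpha, cov, wald, nlp, ok = scanner.scan(mat[:, idx])
        for jj, j in enumerate(idx):
            if not ok[jj]:
                n_skipped += 1
                continue
            records.append(
                AssocRecord(
                    variant=genotypes.variants[j],
                    alpha=alpha[jj],
                    cov_alpha=cov[jj],
                    wald=float(wald[jj]),
                    df=frame.n_traits,
                    p_value=float(stats.chi2.sf(wald[jj], frame.n_traits)),
                    neglog10_p=float(nlp[jj]),
                )
            )
    return records, n_skipped


def conditional_gwas(
    frame: ModelFrame,
    vc: VarianceComponents,
    genotypes: GenotypeMatrix | DosageMatrix,
    lead_snp: int | VariantMeta,
    chunk_size: int = 2000,
) -> tuple[list[AssocRecord], int]:
    """GWAS conditioning on a lead SNP fixed as t per-trait covariates.

    The lead SNP itself is excluded; test SNPs nearly collinear with the lead
    (|r| > 0.9999) are skipped. Returns (records, n_skipped).
    """
    if isinstance(lead_snp, VariantMeta):
        lead_idx = next(
            i for i, v in enumerate(genotypes.variants) if v.key == lead_snp.key
        )
    else:
        lead_idx = int(lead_snp)
    mat = _align_genotypes(genotypes, frame.sample_ids)
    mat, p = _impute_and_freqs(mat)
    w_lead = mat[:, lead_idx]
    if np.std(w_lead) == 0:
        raise ValueError("lead SNP is monomorphic in the tested samples")

    maf = np.minimum(p, 1.0 - p)
    wc = w_lead - w_lead.mean()
    denom = np.sqrt((wc**2).sum()) * np.sqrt(((mat - mat.mean(0)) ** 2).sum(0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs((mat - mat.mean(0)).T @ wc) / np.where(denom == 0, np.nan, denom)
    testable = (maf >= 1e-6) & ~(corr > 0.9999)
    testable[lead_idx] = False
    n_skipped = int((~testable).sum()) - 1  # lead exclusion not counted as a skip

    scanner = GLSScanner(frame, vc, extra_covariates=w_lead)
    records: list[AssocRecord] = []
    idx_all = np.flatnonzero(testable)
    for lo in range(0, idx_all.size, chunk_size):
        idx = idx_all[lo : lo + chunk_size]
        alpha, cov, wald, nlp, ok = scanner.scan(mat[:, idx])
        for jj, j in enumerate(idx):
            if not ok[jj]:
                n_skipped += 1
                continue
            records.append(
                AssocRecord(
                    variant=genotypes.variants[j],
                    alpha=alpha[jj],
                    cov_alpha=cov[jj],
                    wald=float(wald[jj]),
                    df=frame.n_traits,
                    p_value=float(stats.chi2.sf(wald[jj], frame.n_traits)),
                    neglog10_p=float(nlp[jj]),
                )
            )
    return records, n_skipped


def cluster_qtl(
    records: list[AssocRecord],
    threshold: float,
    merge_dist_bp: int = 1_000_000,
) -> list[QTLRecord]:
    """Merge significant SNPs (p < threshold) into QTL clusters.

    SNPs on the same chromosome within ``merge_dist_bp`` of the running
    cluster are merged; the lead is the minimum-p member.
    """
    sig = [r for r in records if r.p_value < threshold]
    sig.sort(key=lambda r: (r.variant.chrom, r.variant.pos))
    out: list[QTLRecord] = []
    cur: list[AssocRecord] = []

    def _flush():
        if not cur:
            return
        lead = min(cur, key=lambda r: (r.p_value, -r.neglog10_p))
        out.append(
            QTLRecord(
                chrom=cur[0].variant.chrom,
                member_variants=[r.variant for r in cur],
                member_pvalues=[r.p_value for r in cur],
                lead=lead.variant,
                lead_p=lead.p_value,
                lead_alpha=lead.alpha,
                start=min(r.variant.pos for r in cur),
                end=max(r.variant.pos for r in cur),
            )
        )

    for r in sig:
        if cur and (
            r.variant.chrom != cur[-1].variant.chrom
            or r.variant.pos - cur[-1].variant.pos > merge_dist_bp
        ):
            _flush()
            cur = []
        cur.append(r)
    _flush()
    return out


def records_to_frame(records: list[AssocRecord]) -> pd.DataFrame:
    """GWAS summary table: chrom, pos, ref, alt, per-trait betas, Wald, df, p."""
    if not records:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "wald", "df", "p", "neglog10_p"]
        )
    t = records[0].df
    data = {
        "chrom": [r.variant.chrom for r in records],
        "pos": [r.variant.pos for r in records],
        "ref": [r.variant.ref for r in records],
        "alt": [r.variant.alt for r in records],
    }
    for k in range(t):
        data[f"beta_{k + 1}"] = [r.alpha[k] for r in records]
    data["wald"] = [r.wald for r in records]
    data["df"] = [r.df for r in records]
    data["p"] = [r.p_value for r in records]
    data["neglog10_p"] = [r.neglog10_p for r in records]
    return pd.DataFrame(data)
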