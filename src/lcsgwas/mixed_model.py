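"""Multi-trait restricted maximum likelihood for the Kronecker-structured LMM.

The model for t traits (one trait at t time points) on n individuals is

    y = (I_t (x) X) b + u + e,    u ~ N(0, Sigma_u (x) K),  e ~ N(0, Sigma_e (x) I_n),

with X the fixed-effect design (intercept, sex, house dummies) and K a
genomic relationship matrix. Sigma_u and Sigma_e are t x t covariance
matrices; the narrow-sense heritability of trait i is
Sigma_u[i,i] / (Sigma_u[i,i] + Sigma_e[i,i]).

Fitting eigendecomposes K = U L U' once and rotates phenotypes and design by
U', after which the (tn x tn) covariance block-diagonalizes into n blocks
V_i = lambda_i Sigma_u + Sigma_e. Optimization is average-information (AI)
REML with an EM-REML fallback whenever an AI step would decrease the
restricted likelihood or leave the PSD cone.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.linalg import eigh

from .types import GRM, PhenotypeTable

__all__ = [
    "ModelFrame",
    "VarianceComponents",
    "build_model_frame",
    "MultiTraitREML",
    "fit_multitrait_reml",
    "heritability_from_vc",
    "genetic_correlations",
    "reml_loglik",
]


@dataclasses.dataclass
class ModelFrame:
    """Complete-case data aligned with a GRM, ready for REML / GWAS."""

    sample_ids: list[str]
    trait_names: list[str]
    Y: np.ndarray  # (n, t) traits, no missing
    X: np.ndarray  # (n, p) fixed-effect design, full column rank
    X_names: list[str]
    K: np.ndarray  # (n, n) relationship matrix aligned with sample_ids
    n_dropped: int = 0

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.Y.shape[1]


def build_model_frame(
    ph: PhenotypeTable,
    grm: GRM,
    trait_columns: list[str] | None = None,
) -> ModelFrame:
    """Assemble phenotypes, covariates and the GRM into a model frame.

    Individuals with any missing trait or covariate, or absent from the GRM,
    are dropped (count reported on the frame). House is dummy-coded with the
    first observed level as reference; constant covariate columns are dropped
    with a warning. Raises if the resulting design is rank deficient.
    """
    trait_columns = trait_columns or list(ph.trait_names)
    tidx = [ph.trait_names.index(c) for c in trait_columns]
    Y = ph.trait_values[:, tidx]

    grm_pos = {s: i for i, s in enumerate(grm.sample_ids)}
    complete = (
        ~np.isnan(Y).any(axis=1)
        & (ph.sex >= 0)
        & (ph.house >= 0)
        & np.array([s in grm_pos for s in ph.sample_ids])
    )
    keep = np.flatnonzero(complete)
    n_dropped = ph.n_samples - keep.size
    if keep.size == 0:
        raise ValueError("no complete-case individuals")
    ids = [ph.sample_ids[i] for i in keep]
    Y = Y[keep]
    sex = ph.sex[keep]
    house = ph.house[keep]

    cols = [np.ones(keep.size)]
    names = ["intercept"]
    if np.unique(sex).size > 1:
        cols.append(sex.astype(float))
        names.append("sex")
    else:
        warnings.warn("sex is constant; column dropped from the design")
    levels = np.unique(house)
    if levels.size > 1:
        for lev in levels[1:]:
            cols.append((house == lev).astype(float))
            names.append(f"house_{lev}")
    else:
        warnings.warn("single house level; house columns dropped from the design")
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns that do not add rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"fixed-effect design is rank deficient; offending columns: {bad}")

    Ksub = grm.K[np.ix_([grm_pos[s] for s in ids], [grm_pos[s] for s in ids])]
    p = X.shape[1]
    t = Y.shape[1]
    if keep.size < t + p + 1:
        raise ValueError("too few complete cases for the model")
    return ModelFrame(ids, list(trait_columns), Y, X, names, Ksub, n_dropped)


@dataclasses.dataclass
class VarianceComponents:
    """REML estimates of the trait-level covariance matrices."""

    sigma_u: np.ndarray  # (t, t)
    sigma_e: np.ndarray  # (t, t)
    restricted_log_likelihood: float
    converged: bool
    n_iterations: int
    trait_names: list[str] = dataclasses.field(default_factory=list)
    identifiable: bool = True

    @property
    def n_traits(self) -> int:
        return self.sigma_u.shape[0]

    def heritability(self, i: int) -> float:
        return heritability_from_vc(self, i)

    def heritabilities(self) -> np.ndarray:
        return np.array([heritability_from_vc(self, i) for i in range(self.n_traits)])


def heritability_from_vc(vc: VarianceComponents, time_point: int) -> float:
    """Narrow-sense h2 for one time point: Su_ii / (Su_ii + Se_ii)."""
    su = vc.sigma_u[time_point, time_point]
    se = vc.sigma_e[time_point, time_point]
    total = su + se
    if total <= 0:
        raise ValueError("zero total variance; heritability undefined")
    return float(su / total)


def genetic_correlations(vc: VarianceComponents) -> np.ndarray:
    """Genetic correlation matrix from the off-diagonals of Sigma_u."""
    d = np.sqrt(np.clip(np.diag(vc.sigma_u), 1e-12, None))
    return vc.sigma_u / np.outer(d, d)


# ---------------------------------------------------------------------------
# internals shared with the association scan


def _sym_params(t: int) -> list[tuple[int, int]]:
    return [(k, l) for k in range(t) for l in range(k, t)]


def _mat_from_params(theta: np.ndarray, t: int) -> tuple[np.ndarray, np.ndarray]:
    pairs = _sym_params(t)
    q = len(pairs)
    su = np.zeros((t, t))
    se = np.zeros((t, t))
    for a, (k, l) in enumerate(pairs):
        su[k, l] = su[l, k] = theta[a]
        se[k, l] = se[l, k] = theta[q + a]
    return su, se


def _params_from_mats(su: np.ndarray, se: np.ndarray) -> np.ndarray:
    pairs = _sym_params(su.shape[0])
    return np.array([su[k, l] for k, l in pairs] + [se[k, l] for k, l in pairs])


def _psd_clip(mat: np.ndarray, floor_frac: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone with a small eigen floor."""
    mat = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(mat)
    t = mat.shape[0]
    floor = max(floor_frac * max(np.trace(mat), 0.0) / t, 1e-10)
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


class _RotatedModel:
    """K-eigenrotated data: carries everything REML and GWAS scans need."""

    def __init__(self, frame: ModelFrame):
        lam, U = eigh((frame.K + frame.K.T) / 2.0)
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        self.Y = U.T @ frame.Y  # (n, t)
        self.X = U.T @ frame.X  # (n, p)
        self.n, self.t = self.Y.shape
        self.p = self.X.shape[1]

    def loglik_parts(self, su: np.ndarray, se: np.ndarray):
        """Restricted log-likelihood and the per-individual GLS quantities.

        Returns (logL, Vinv (n,t,t), Py (n,t), C (tp,tp), bhat (t,p)).
        """
        n, t, p = self.n, self.t, self.p
        V = self.lam[:, None, None] * su[None] + se[None]  # (n, t, t)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.sum(np.log(np.einsum("ikk->ik", L)))
        Vinv = np.linalg.inv(V)
        C = np.einsum("iab,ip,iq->apbq", Vinv, self.X, self.X).reshape(t * p, t * p)
        VY = np.einsum("iab,ib->ia", Vinv, self.Y)
        rx = np.einsum("ia,ip->ap", VY, self.X).reshape(t * p)
        try:
            Lc = np.linalg.cholesky((C + C.T) / 2.0)
        except np.linalg.LinAlgError:
            return None
        logdetC = 2.0 * np.sum(np.log(np.diag(Lc)))
        bhat = np.linalg.solve(C, rx).reshape(t, p)
        resid = self.Y - self.X @ bhat.T  # (n, t)
        Py = np.einsum("iab,ib->ia", Vinv, resid)
        yPy = float(np.sum(resid * Py))
        logL = -0.5 * (logdetV + logdetC + yPy + (n * t - p * t) * np.log(2.0 * np.pi))
        return logL, Vinv, Py, C, bhat


def reml_loglik(frame: ModelFrame, sigma_u: np.ndarray, sigma_e: np.ndarray) -> float:
    """Restricted log-likelihood at fixed (Sigma_u, Sigma_e).

    Exposed so the objective can be checked against a dense-matrix evaluation.
    """
    rot = _RotatedModel(frame)
    parts = rot.loglik_parts(np.atleast_2d(sigma_u), np.atleast_2d(sigma_e))
    if parts is None:
        raise ValueError("covariance not positive definite at the given components")
    return parts[0]


class MultiTraitREML:
    """AI-REML fitter for (Sigma_u, Sigma_e) with EM fallback.

    Parameters
    ----------
    max_iter:
        Iteration cap; ``converged_`` is False when reached.
    tol:
        Convergence on |delta restricted logL|; additionally the maximum
        relative parameter change must fall below 1e-6.

    After ``fit``, estimates live in ``sigma_u_``, ``sigma_e_``,
    ``loglik_``, ``converged_``, ``n_iter_``.
    """

    def __init__(self, max_iter: int = 1000, tol: float = 1e-8, verbose: bool = False):
        self.max_iter = max_iter
        self.tol = tol
        self.verbose = verbose

    # -- gradient / AI helpers ---------------------------------------------

    @staticmethod
    def _grad_mats(rot: _RotatedModel, Vinv, Py, C):
        """Sufficient statistics for gradient and EM updates."""
        t, p = rot.t, rot.p
        M = np.linalg.inv(C).reshape(t, p, t, p)
        G = np.einsum("iq,cqdr,ir->icd", rot.X, M, rot.X)  # (n, t, t)
        Pii = Vinv - Vinv @ G @ Vinv  # diagonal blocks of the projection P
        PyPy = np.einsum("ia,ib->iab", Py, Py)
        diff = PyPy - Pii  # (n, t, t)
        Su_stat = np.einsum("i,iab->ab", rot.lam, diff)  # for Sigma_u
        Se_stat = diff.sum(axis=0)  # for Sigma_e
        return Su_stat, Se_stat, Pii

    @staticmethod
    def _gradient(rot: _RotatedModel, Su_stat, Se_stat) -> np.ndarray:
        pairs = _sym_params(rot.t)
        g = []
        for k, l in pairs:
            g.append(0.5 * Su_stat[k, l] * (1 if k == l else 2))
        for k, l in pairs:
            g.append(0.5 * Se_stat[k, l] * (1 if k == l else 2))
        return np.array(g)

    @staticmethod
    def _ai_matrix(rot: _RotatedModel, Vinv, Py, C) -> np.ndarray:
        t, p, n = rot.t, rot.p, rot.n
        pairs = _sym_params(t)
        npar = 2 * len(pairs)
        # q_a = (dV/dtheta_a) Py, per individual
        q = np.zeros((npar, n, t))
        for a, (k, l) in enumerate(pairs):
            qa = np.zeros((n, t))
            qa[:, k] += rot.lam * Py[:, l]
            if k != l:
                qa[:, l] += rot.lam * Py[:, k]
            q[a] = qa
            qe = np.zeros((n, t))
            qe[:, k] += Py[:, l]
            if k != l:
                qe[:, l] += Py[:, k]
            q[len(pairs) + a] = qe
        Vq = np.einsum("iab,sib->sia", Vinv, q)  # (npar, n, t)
        s = np.einsum("sia,ip->sap", Vq, rot.X).reshape(npar, t * p)
        Cinv = np.linalg.inv(C)
        ai = 0.5 * (np.einsum("sia,ria->sr", q, Vq) - s @ Cinv @ s.T)
        return ai

    # -- main loop ---------------------------------------------------------

    def fit(self, frame: ModelFrame) -> "MultiTraitREML":
        rot = _RotatedModel(frame)
        t = rot.t
        if np.ptp(rot.lam) < 1e-8:
            warnings.warn(
                "relationship matrix has (near-)equal eigenvalues; "
                "Sigma_u and Sigma_e are not separately identifiable"
            )
            self.identifiable_ = False
        else:
            self.identifiable_ = True

        phen_cov = np.cov(frame.Y, rowvar=False).reshape(t, t)
        su = _psd_clip(0.5 * phen_cov)
        se = _psd_clip(0.5 * phen_cov)
        parts = rot.loglik_parts(su, se)
        if parts is None:
            raise RuntimeError("starting covariance not positive definite")
        logL = parts[0]
        self._trace = [logL]

        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            _, Vinv, Py, C, _ = parts
            Su_stat, Se_stat, _ = self._grad_mats(rot, Vinv, Py, C)
            grad = self._gradient(rot, Su_stat, Se_stat)
            ai = self._ai_matrix(rot, Vinv, Py, C)

            theta = _params_from_mats(su, se)
            new = None
            # AI (quasi-Newton) step with halving; accepted only if logL
            # does not decrease
            try:
                delta = np.linalg.solve(ai + 1e-10 * np.eye(ai.shape[0]), grad)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(6):
                    su_c, se_c = _mat_from_params(theta + step * delta, t)
                    su_c, se_c = _psd_clip(su_c), _psd_clip(se_c)
                    cand = rot.loglik_parts(su_c, se_c)
                    if cand is not None and cand[0] >= logL - 1e-12:
                        new = (su_c, se_c, cand)
                        break
                    step *= 0.5
            if new is None:
                # EM-REML fallback: monotone, stays in the PSD cone
                su_c = _psd_clip(su + (su @ Su_stat @ su) / rot.n)
                se_c = _psd_clip(se + (se @ Se_stat @ se) / rot.n)
                cand = rot.loglik_parts(su_c, se_c)
                if cand is None:
                    raise RuntimeError("EM update left the feasible region")
                new = (su_c, se_c, cand)

            su_new, se_new, parts = new
            new_logL = parts[0]
            if new_logL < logL - 1e-6 * (1 + abs(logL)):
                raise RuntimeError(
                    f"restricted likelihood diverged at iteration {it}: "
                    f"{logL:.6f} -> {new_logL:.6f}; trace: {self._trace}"
                )
            theta_old = _params_from_mats(su, se)
            theta_new = _params_from_mats(su_new, se_new)
            rel = np.max(np.abs(theta_new - theta_old) / np.maximum(np.abs(theta_old), 1e-8))
            dlog = new_logL - logL
            su, se, logL = su_new, se_new, new_logL
            self._trace.append(logL)
            if self.verbose:
                print(f"iter {it}: logL={logL:.6f} dlogL={dlog:.3e} rel={rel:.3e}")
            if abs(dlog) < self.tol and rel < 1e-6:
                converged = True
                break

        self.sigma_u_ = su
        self.sigma_e_ = se
        self.loglik_ = logL
        self.converged_ = converged
        self.n_iter_ = it
        self._rot = rot
        return self

    def variance_components_(self, trait_names: list[str] | None = None) -> VarianceComponents:
        return VarianceComponents(
            sigma_u=self.sigma_u_,
            sigma_e=self.sigma_e_,
            restricted_log_likelihood=self.loglik_,
            converged=self.converged_,
            n_iterations=self.n_iter_,
            trait_names=trait_names or [],
            identifiable=self.identifiable_,
        )


def fit_multitrait_reml(
    frame: ModelFrame, max_iter: int = 1000, tol: float = 1e-8
) -> VarianceComponents:
    """Fit the multi-trait REML model and return the variance components."""
    fitter = MultiTraitREML(max_iter=max_iter, tol=tol).fit(frame)
    return fitter.variance_components_(frame.trait_names)
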