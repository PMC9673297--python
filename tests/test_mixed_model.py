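"""Model-frame assembly and multi-trait REML (dense oracle, recovery, invariants)."""

import numpy as np
import pytest

from lcsgwas.kinship import vanraden_grm
from lcsgwas.mixed_model import (
    MultiTraitREML,
    ModelFrame,
    build_model_frame,
    fit_multitrait_reml,
    genetic_correlations,
    heritability_from_vc,
    reml_loglik,
    VarianceComponents,
)
from lcsgwas.simdata import SimConfig, simulate_genotypes, simulate_phenotypes
from lcsgwas.types import GRM, PhenotypeTable


def _phenotypes(n=8, t=2, seed=0, missing=()):
    rng = np.random.default_rng(seed)
    y = rng.standard_normal((n, t))
    for i, j in missing:
        y[i, j] = np.nan
    return PhenotypeTable(
        sample_ids=[f"s{i}" for i in range(n)],
        trait_names=[f"y{j}" for j in range(t)],
        trait_values=y,
        sex=rng.integers(0, 2, n),
        house=rng.integers(1, 3, n),
    )


def _grm(n, seed=1):
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n, 3 * n))
    K = w @ w.T / (3 * n)
    return GRM(K, [f"s{i}" for i in range(n)], denominator=1.0, n_snps_used=3 * n)


def test_frame_drops_incomplete_cases_and_subsets_grm():
    ph = _phenotypes(n=9, missing=[(2, 0)])
    grm = _grm(9)
    frame = build_model_frame(ph, grm)
    assert frame.n_samples == 8
    assert frame.n_dropped == 1
    assert frame.K.shape == (8, 8)
    keep = [0, 1, 3, 4, 5, 6, 7, 8]
    np.testing.assert_allclose(frame.K, grm.K[np.ix_(keep, keep)])


def test_frame_single_house_level_drops_column():
    ph = _phenotypes(n=10)
    ph.house[:] = 3
    with pytest.warns(UserWarning, match="house"):
        frame = build_model_frame(ph, _grm(10))
    assert "house_3" not in frame.X_names


def test_frame_order_invariance():
    ph = _phenotypes(n=12)
    grm = _grm(12)
    frame = build_model_frame(ph, grm)
    perm = np.random.default_rng(3).permutation(12)
    ph2 = PhenotypeTable(
        sample_ids=[ph.sample_ids[i] for i in perm],
        trait_names=ph.trait_names,
        trait_values=ph.trait_values[perm],
        sex=ph.sex[perm],
        house=ph.house[perm],
    )
    frame2 = build_model_frame(ph2, grm)
    order = [frame2.sample_ids.index(s) for s in frame.sample_ids]
    np.testing.assert_allclose(frame2.Y[order], frame.Y)
    np.testing.assert_allclose(frame2.K[np.ix_(order, order)], frame.K)


def test_frame_rank_deficient_design_names_columns():
    ph = _phenotypes(n=10)
    ph.house[:] = 2 + ph.sex  # house perfectly determined by sex
    with pytest.raises(ValueError, match="house"):
        build_model_frame(ph, _grm(10))


def dense_reml_loglik(frame, su, se):
    """Brute-force REML log-likelihood on the full (tn x tn) covariance."""
    n, t = frame.Y.shape
    V = np.kron(su, frame.K) + np.kron(se, np.eye(n))
    Xbar = np.kron(np.eye(t), frame.X)
    y = frame.Y.T.reshape(-1)  # trait-major stack
    Vinv = np.linalg.inv(V)
    C = Xbar.T @ Vinv @ Xbar
    P = Vinv - Vinv @ Xbar @ np.linalg.solve(C, Xbar.T @ Vinv)
    _, ldV = np.linalg.slogdet(V)
    _, ldC = np.linalg.slogdet(C)
    p = Xbar.shape[1]
    return -0.5 * (ldV + ldC + y @ P @ y + (n * t - p) * np.log(2 * np.pi))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_loglik_matches_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    n, t = 6, 2
    ph = _phenotypes(n=n, t=t, seed=seed)
    frame = build_model_frame(ph, _grm(n, seed + 10))
    a = rng.standard_normal((t, t))
    su = a @ a.T + 0.1 * np.eye(t)
    b = rng.standard_normal((t, t))
    se = b @ b.T + 0.1 * np.eye(t)
    assert reml_loglik(frame, su, se) == pytest.approx(
        dense_reml_loglik(frame, su, se), abs=1e-8
    )


def test_null_simulation_gives_near_zero_heritability():
    cfg = SimConfig(seed=31, n_individuals=400, n_snps=1500, t_traits=2,
                    sigma_u=np.zeros((2, 2)), sigma_e=np.eye(2))
    g, _ = simulate_genotypes(cfg)
    ph, _ = simulate_phenotypes(g, cfg)
    frame = build_model_frame(ph, vanraden_grm(g))
    vc = fit_multitrait_reml(frame)
    assert (vc.heritabilities() < 0.05).all()


def test_identity_kinship_warns_non_identifiable():
    ph = _phenotypes(n=30, seed=5)
    grm = GRM(np.eye(30), [f"s{i}" for i in range(30)], denominator=1.0, n_snps_used=10)
    frame = build_model_frame(ph, grm)
    with pytest.warns(UserWarning, match="identifiab"):
        vc = fit_multitrait_reml(frame, max_iter=20)
    assert not vc.identifiable


@pytest.mark.parametrize(
    "su, se, expected", [(1.0, 3.0, 0.25), (0.0, 1.0, 0.0), (2.0, 2.0, 0.5)]
)
def test_heritability_arithmetic(su, se, expected):
    vc = VarianceComponents(
        sigma_u=np.array([[su]]),
        sigma_e=np.array([[se]]),
        restricted_log_likelihood=0.0,
        converged=True,
        n_iterations=1,
    )
    assert heritability_from_vc(vc, 0) == pytest.approx(expected)


def test_heritability_zero_total_variance_is_an_error():
    vc = VarianceComponents(
        sigma_u=np.array([[0.0]]),
        sigma_e=np.array([[0.0]]),
        restricted_log_likelihood=0.0,
        converged=True,
        n_iterations=1,
    )
    with pytest.raises(ValueError):
        heritability_from_vc(vc, 0)


def test_loglik_trace_is_monotone(small_cohort):
    fitter = MultiTraitREML().fit(small_cohort["frame"])
    trace = np.array(fitter._trace)
    assert (np.diff(trace) >= -1e-9 * (1 + np.abs(trace[:-1]))).all()


def test_estimates_invariant_to_individual_reordering(small_cohort):
    frame = small_cohort["frame"]
    vc = small_cohort["vc"]
    perm = np.random.default_rng(1).permutation(frame.n_samples)
    frame2 = ModelFrame(
        sample_ids=[frame.sample_ids[i] for i in perm],
        trait_names=frame.trait_names,
        Y=frame.Y[perm],
        X=frame.X[perm],
        X_names=frame.X_names,
        K=frame.K[np.ix_(perm, perm)],
    )
    vc2 = fit_multitrait_reml(frame2)
    np.testing.assert_allclose(vc2.sigma_u, vc.sigma_u, atol=1e-4)
    np.testing.assert_allclose(vc2.sigma_e, vc.sigma_e, atol=1e-4)


def test_estimates_scale_with_trait_scaling(small_cohort):
    frame = small_cohort["frame"]
    vc = small_cohort["vc"]
    scale = np.array([2.0, 0.5, 3.0])
    frame2 = ModelFrame(
        sample_ids=frame.sample_ids,
        trait_names=frame.trait_names,
        Y=frame.Y * scale,
        X=frame.X,
        X_names=frame.X_names,
        K=frame.K,
    )
    vc2 = fit_multitrait_reml(frame2)
    S = np.outer(scale, scale)
    np.testing.assert_allclose(vc2.sigma_u, vc.sigma_u * S, rtol=0.02, atol=1e-3)
    np.testing.assert_allclose(vc2.heritabilities(), vc.heritabilities(), atol=0.01)


def test_genetic_correlations_unit_diagonal(small_cohort):
    rg = genetic_correlations(small_cohort["vc"])
    np.testing.assert_allclose(np.diag(rg), 1.0, atol=1e-8)
    assert (np.abs(rg) <= 1 + 1e-8).all()
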