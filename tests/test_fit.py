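"""EM/variational fitting and the downstream richness machinery."""

import numpy as np
import pytest

from lexcap import (
    MixtureConfig,
    ModelParams,
    ResourceSet,
    discovery_curve,
    estimate_richness,
    extrapolate_total_synonymy,
    fit,
    load_fit,
    model_comparison,
    save_fit,
    simulate_compendium,
    synonyms_per_headword_fit,
)

RES5 = ResourceSet(tuple("ABCDE"))


@pytest.fixture(scope="module")
def fitted_single_class():
    params = ModelParams.single_class([0.2, 0.3, 0.4, 0.3, 0.25], 0.5)
    comp, truth = simulate_compendium(params, 3000, RES5, seed=1)
    result = fit(comp, MixtureConfig(1, 1, restarts=1, seed=2))
    return params, comp, truth, result


def _monotone(trace, tol=1e-8):
    d = np.diff(trace)
    return bool((d >= -tol * (np.abs(trace[:-1]) + 1.0)).all())


def test_objective_trace_is_monotone(fitted_single_class):
    *_, result = fitted_single_class
    assert _monotone(result.objective_trace)


def test_single_class_parameter_recovery(fitted_single_class):
    params, _, _, result = fitted_single_class
    assert np.abs(result.params.q.ravel() - params.q.ravel()).max() < 0.05
    assert abs(result.params.theta[0] - params.theta[0]) < 0.05


def test_fit_is_deterministic_given_seed(fitted_single_class):
    _, comp, _, result = fitted_single_class
    again = fit(comp, MixtureConfig(1, 1, restarts=1, seed=2))
    assert np.array_equal(result.params.q, again.params.q)
    assert np.array_equal(result.params.theta, again.params.theta)
    assert np.array_equal(result.objective_trace, again.objective_trace)
    assert np.array_equal(result.responsibilities, again.responsibilities)


def test_extra_classes_collapse_or_merge(fitted_single_class):
    """Fitting 3 concept classes to single-class data: surviving classes
    carry either negligible weight or near-identical parameters."""
    _, comp, _, _ = fitted_single_class
    result = fit(comp, MixtureConfig(3, 1, restarts=3, seed=5))
    p = result.params
    big = p.w > 0.01
    assert big.any()
    assert p.theta[big].max() - p.theta[big].min() < 0.1
    assert np.abs(p.u[big] - p.u[big].mean()).max() < 0.05


def test_multiclass_trace_monotone_and_simplex_constraints():
    gen = ModelParams(
        w=[0.5, 0.5], theta=[0.3, 0.7],
        pi=[[0.8, 0.2], [0.3, 0.7]],
        q=[[0.5, 0.1], [0.4, 0.2], [0.3, 0.15]],
    )
    comp, _ = simulate_compendium(gen, 1500, ResourceSet(tuple("XYZ")), seed=3)
    result = fit(comp, MixtureConfig(2, 2, restarts=2, seed=4, max_iter=300))
    assert _monotone(result.objective_trace)
    p = result.params
    assert p.w.sum() == pytest.approx(1.0)
    assert np.allclose(p.pi.sum(axis=1), 1.0)
    assert ((p.q > 0) & (p.q < 1)).all()
    assert ((p.theta > 0) & (p.theta < 1)).all()


def test_fit_requires_two_resources():
    params = ModelParams.single_class([0.9], 0.5)
    comp, _ = simulate_compendium(params, 50, ResourceSet(("solo",)), seed=0)
    with pytest.raises(ValueError):
        fit(comp, MixtureConfig(1, 1))


def test_nonconvergence_is_flagged_not_raised(fitted_single_class):
    _, comp, _, _ = fitted_single_class
    result = fit(comp, MixtureConfig(1, 1, restarts=1, seed=2, max_iter=2))
    assert result.converged is False


# ---------------------------------------------------------------------------
# richness estimation
# ---------------------------------------------------------------------------


def test_saturated_detection_leaves_nothing_missing():
    params = ModelParams.single_class([0.999, 0.999, 0.999], 0.5)
    comp, truth = simulate_compendium(params, 1000, ResourceSet(tuple("XYZ")), seed=6)
    result = fit(comp, MixtureConfig(1, 1, restarts=1, seed=7))
    est = estimate_richness(result, comp, n_draws=1000, seed=8)
    assert est.n_latent_concepts < 1.0
    assert est.fraction_synonyms_missing < 0.01


def test_richness_estimate_consistency(fitted_single_class):
    _, comp, truth, result = fitted_single_class
    est = estimate_richness(result, comp, n_draws=4000, seed=9)
    assert est.n_total_concepts == pytest.approx(
        est.n_obs_concepts + est.n_latent_concepts)
    assert est.n_total_relationships == pytest.approx(
        est.n_obs_relationships
        + est.n_missing_synonyms_documented_concepts
        + est.n_missing_synonyms_latent_concepts)
    assert 0 <= est.fraction_concepts_missing <= 1
    assert 0 <= est.fraction_synonyms_missing <= 1
    # per-component breakdowns add to the totals
    comp_break = est.per_component
    assert sum(comp_break["undocumented_concepts"]) == pytest.approx(
        est.n_latent_concepts, rel=1e-6)
    assert sum(comp_break["documented_relationships"]) == pytest.approx(
        est.n_obs_relationships, rel=1e-6)
    # simulated truth near the point estimates and inside 99% intervals
    lo, hi = est.ci["n_latent_concepts"]
    assert lo <= truth.n_hidden_concepts <= hi


def test_save_load_round_trip(tmp_path, fitted_single_class):
    _, comp, _, result = fitted_single_class
    path = tmp_path / "fit.json"
    save_fit(result, path)
    back = load_fit(path, comp)
    assert np.allclose(back.params.q, result.params.q)
    assert np.allclose(back.responsibilities, result.responsibilities)
    est_a = estimate_richness(result, comp, n_draws=500, seed=1)
    est_b = estimate_richness(back, comp, n_draws=500, seed=1)
    assert est_a.n_latent_concepts == pytest.approx(est_b.n_latent_concepts)


# ---------------------------------------------------------------------------
# fit of the synonyms-per-headword distribution
# ---------------------------------------------------------------------------


def test_count_distribution_self_consistency(fitted_single_class):
    """Data simulated from the model's own family: high R^2 and matched
    histogram masses."""
    _, comp, _, result = fitted_single_class
    frame, r2 = synonyms_per_headword_fit(result, comp)
    assert frame["observed"].sum() == comp.n_concepts
    assert frame["expected"].sum() == pytest.approx(comp.n_concepts, rel=0.02)
    assert r2 > 0.95


def test_single_class_fit_underperforms_on_bimodal_data():
    gen = ModelParams(
        w=[0.5, 0.5], theta=[0.1, 0.92], pi=[[1.0], [1.0]],
        q=[[0.6], [0.6], [0.6]],
    )
    comp, _ = simulate_compendium(gen, 2500, ResourceSet(tuple("XYZ")), seed=10)
    r1 = fit(comp, MixtureConfig(1, 1, restarts=2, seed=11))
    r2m = fit(comp, MixtureConfig(2, 1, restarts=3, seed=12))
    _, r2_one = synonyms_per_headword_fit(r1, comp)
    _, r2_two = synonyms_per_headword_fit(r2m, comp)
    assert r2_one < r2_two


# ---------------------------------------------------------------------------
# discovery curve and extrapolation
# ---------------------------------------------------------------------------


def test_discovery_curve_shape_and_closed_form(fitted_single_class):
    _, comp, _, result = fitted_single_class
    curve = discovery_curve(result, [0, 1], r_max=50)
    assert curve[0] == 0.0
    assert (np.diff(curve) >= -1e-12).all()
    assert curve[-1] <= 1.0 + 1e-12
    # single class: curve(r) = 1 - m^r with m the subset miss probability
    m = float(np.prod(1 - result.params.q[[0, 1], 0]))
    expected = 1 - m ** np.arange(51)
    assert np.allclose(curve, expected, atol=1e-10)
    with pytest.raises(ValueError):
        discovery_curve(result, [], 10)


def test_extrapolation_linearity_and_consistency(fitted_single_class):
    _, comp, _, result = fitted_single_class
    est = estimate_richness(result, comp, n_draws=500, seed=2)
    zero, _ = extrapolate_total_synonymy(result, 0, n_draws=500, seed=2)
    assert zero == 0.0
    one, _ = extrapolate_total_synonymy(result, 1000, n_draws=500, seed=2)
    two, _ = extrapolate_total_synonymy(result, 2000, n_draws=500, seed=2)
    assert two == pytest.approx(2 * one)
    at_total, _ = extrapolate_total_synonymy(
        result, est.n_total_concepts, n_draws=500, seed=2)
    assert at_total == pytest.approx(est.n_total_relationships, rel=1e-6)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def test_geometric_data_scored_fairly():
    """On data whose count distribution *is* geometric, the geometric model
    scores within a couple of units of (here: above) the mixture."""
    params = ModelParams.single_class([0.3, 0.3, 0.3], 0.55)
    comp, _ = simulate_compendium(params, 2000, ResourceSet(tuple("XYZ")), seed=13)
    scores = model_comparison(comp, ["mixture", "geometric", "log-gaussian"])
    assert scores["geometric"] >= scores["mixture"] - 2.0


def test_bimodal_data_prefers_mixture():
    gen = ModelParams(
        w=[0.5, 0.5], theta=[0.15, 0.9], pi=[[1.0], [1.0]],
        q=[[0.6], [0.6], [0.6]],
    )
    comp, _ = simulate_compendium(gen, 2500, ResourceSet(tuple("XYZ")), seed=14)
    scores = model_comparison(comp, ["mixture", "geometric", "log-gaussian"])
    assert scores["mixture"] > scores["geometric"]
    assert scores["mixture"] > scores["log-gaussian"]


def test_degenerate_histogram_handled():
    """Every concept with exactly one term: all candidates stay finite."""
    params = ModelParams.single_class([0.99, 0.99], 1e-6)
    comp, _ = simulate_compendium(params, 300, ResourceSet(("A", "B")), seed=15)
    assert set(np.unique([len(e.terms) for e in comp.entries.values()])) == {1}
    scores = model_comparison(comp, ["mixture", "geometric", "log-gaussian"])
    assert all(np.isfinite(v) for v in scores.values())
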