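"""Synthetic-data generator: determinism, generative structure, predictors."""

import numpy as np
import pytest

import funnelmorph as fm
from funnelmorph import (
    EffectSpec,
    SimulationSpec,
    TEMPLATE,
    TEMPLATE_LANDMARK_NAMES,
    default_effect_vector,
    gpa,
    measure_predictors,
    mouse_study_spec,
    procrustes_distance,
    simulate_mutant_pair,
    simulate_population,
)
from funnelmorph.simulate import remove_similarity_components


def test_template_is_unit_size_and_named():
    assert TEMPLATE.shape == (18, 3)
    assert len(TEMPLATE_LANDMARK_NAMES) == 18
    assert np.abs(TEMPLATE.mean(axis=0)).max() < 1e-12
    assert np.linalg.norm(TEMPLATE) == pytest.approx(1.0)
    assert {"hormion", "opisthocranion"} <= set(TEMPLATE_LANDMARK_NAMES)


def test_same_seed_bit_identical():
    spec = mouse_study_spec(seed=42, n=10)
    d1 = simulate_population(spec)
    d2 = simulate_population(spec)
    np.testing.assert_array_equal(d1.coords_array(), d2.coords_array())
    assert d1.metadata.equals(d2.metadata)


def test_growing_n_preserves_earlier_specimens():
    s10 = mouse_study_spec(seed=3, n=10)
    s25 = mouse_study_spec(seed=3, n=25)
    d10 = simulate_population(s10)
    d25 = simulate_population(s25)
    np.testing.assert_array_equal(d25.coords_array()[:10], d10.coords_array())


def test_pure_nuisance_collapses_under_gpa():
    """No effects, no noise, no dimorphism: GPA must recover one shape
    exactly despite random rotation/translation/scale."""
    spec = SimulationSpec(n=8, seed=5, noise_sd=0.0, scale_jitter=0.2)
    ds = simulate_population(spec)
    # raw configurations genuinely differ
    assert np.abs(ds.coords_array()[0] - ds.coords_array()[1]).max() > 1.0
    res = gpa(ds)
    for i in range(8):
        assert procrustes_distance(res.aligned[i], res.aligned[0]) < 1e-8


def test_generative_recovery_through_pipeline():
    """Noiseless linear effect: pooled regression on the GPA output recovers
    the generating vector (small-effect regime where tangent curvature is
    below tolerance; nuisance rotation off so coordinate frames agree)."""
    V = default_effect_vector("brain_size")
    slope, sd = 5e-4, 0.05
    eff = EffectSpec("brain_size", V, slope, 7.66, sd)
    spec = SimulationSpec(n=40, seed=11, effects=(eff,), noise_sd=0.0, rotate=False)
    ds = simulate_population(spec)
    res = gpa(ds)
    x = ds.metadata["brain_size"].to_numpy()
    m = fm.pooled_within_regression(res, x, np.zeros(40, int), n_perm=0)
    assert np.linalg.norm(m.beta - slope * V) < 1e-8
    assert m.percent_var == pytest.approx(100.0, abs=1e-8)


def test_effect_vectors_unit_norm_and_tangent():
    for name in ("brain_size", "chondro_length", "log_centroid_size", "sex"):
        v = default_effect_vector(name)
        assert np.linalg.norm(v) == pytest.approx(1.0)
        # orthogonal to the similarity directions at the template
        assert np.linalg.norm(remove_similarity_components(v) - v) < 1e-10


def test_effect_spec_normalises_vector():
    e = EffectSpec("a", 2.0 * default_effect_vector("sex"), slope=0.5, mean=0.0, sd=1.0)
    assert np.linalg.norm(e.vector) == pytest.approx(1.0)
    assert e.slope == pytest.approx(1.0)  # magnitude folded into the slope


def test_spec_validation_lists_problems():
    with pytest.raises(ValueError, match="n must be >= 2.*noise_sd"):
        SimulationSpec(n=1, seed=0, noise_sd=-1.0)


def test_mutant_pair_predictor_shift_noiseless():
    V = default_effect_vector("chondro_length")
    slope = 1e-3
    eff = EffectSpec("chondro_length", V, slope, 13.6, 0.0)  # sd 0: no normal variation
    spec = SimulationSpec(n=6, seed=2, effects=(eff,), noise_sd=0.0, rotate=False)
    delta = 0.05
    ds = simulate_mutant_pair(spec, n_mutant=6, predictor="chondro_length", delta=delta)
    assert sorted(ds.metadata["group"].unique()) == ["mutant", "wildtype"]
    res = gpa(ds)
    con = fm.group_contrast(res, ds.metadata["group"].to_numpy(), "wildtype", "mutant", n_perm=0)
    assert con.distance == pytest.approx(slope * delta, rel=1e-6)


def test_mutant_pair_displacement_mode_and_errors():
    spec = SimulationSpec(n=4, seed=7, noise_sd=0.0)
    D = 0.01 * default_effect_vector("sex")
    ds = simulate_mutant_pair(spec, n_mutant=4, displacement=D)
    res = gpa(ds)
    con = fm.group_contrast(res, ds.metadata["group"].to_numpy(), "wildtype", "mutant", n_perm=0)
    assert con.distance == pytest.approx(np.linalg.norm(D), rel=1e-4)
    with pytest.raises(ValueError, match="not both"):
        simulate_mutant_pair(spec, 4, predictor="a", delta=1.0, displacement=D)
    with pytest.raises(ValueError, match="required"):
        simulate_mutant_pair(spec, 4)
    with pytest.raises(ValueError, match="no effect named"):
        simulate_mutant_pair(spec, 4, predictor="nope", delta=1.0)


def test_measure_predictors_consistency():
    spec = mouse_study_spec(seed=9, n=6)
    ds = measure_predictors(simulate_population(spec))
    meta = ds.metadata
    for i, cfg in enumerate(ds.configurations):
        assert meta["overall_size"][i] == pytest.approx(
            np.log(fm.centroid_size(cfg)), abs=1e-12
        )
        assert meta["chondrocranial_length"][i] == pytest.approx(
            fm.interlandmark_distance(cfg, "hormion", "opisthocranion")
        )
    # scale the raw coordinates: chondro length scales, log size shifts by ln c
    c = 2.5
    scaled = fm.LandmarkDataset(
        [
            fm.LandmarkConfiguration(cf.specimen_id, c * cf.coords, cf.landmark_names)
            for cf in ds.configurations
        ],
        ds.metadata[["specimen_id", "sex", "group"]].copy(),
    )
    sm = measure_predictors(scaled).metadata
    np.testing.assert_allclose(
        sm["chondrocranial_length"], c * meta["chondrocranial_length"]
    )
    np.testing.assert_allclose(sm["overall_size"], meta["overall_size"] + np.log(c))


def test_measure_predictors_requires_named_landmarks(small_dataset):
    with pytest.raises(KeyError, match="hormion"):
        measure_predictors(small_dataset)


def test_predictor_cv_converges_to_spec():
    """Empirical CV of each simulated latent approaches sd/mean, within 3 SE
    at n = 10,000 — both the low-CV (mouse-like) and high-CV (human-like)
    regimes are reachable."""
    n = 10_000
    for mean, cv in [(7.66, 0.048), (11.0, 0.102)]:
        eff = EffectSpec(
            "brain_size", default_effect_vector("brain_size"), 0.0, mean, cv * mean
        )
        spec = SimulationSpec(
            n=n, seed=17, effects=(eff,), noise_sd=0.0, rotate=False, translation=0.0
        )
        ds = simulate_population(spec)
        emp = fm.coefficient_of_variation(ds.metadata["brain_size"])
        se = cv / np.sqrt(2 * (n - 1))  # delta-method SE of a small CV
        assert abs(emp - cv) < 3 * se
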