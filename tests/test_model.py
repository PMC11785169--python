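"""Exact ring-model distribution and cooperativity inference."""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

from ringstate import (
    ConfigError,
    EmptySpectrumError,
    NonIdentifiableError,
    RingCouplingModel,
    RingModel,
    enumerate_classes,
    lrt_cooperativity,
    spectrum_from_counts,
)
from ringstate.ring import canonicalize


def brute_force_class_probabilities(n, h, J, classes):
    """Independent oracle: enumerate all 2^n spin arrangements directly."""
    weights = {}
    for spins in product((0, 1), repeat=n):
        energy = h * sum(spins) + J * sum(
            spins[i] * spins[(i + 1) % n] for i in range(n)
        )
        labels = tuple("A" if s else "R" for s in spins)
        canon = canonicalize(labels)
        weights[canon] = weights.get(canon, 0.0) + np.exp(energy)
    total = sum(weights.values())
    return np.array([weights[c.canonical] / total for c in classes])


# -- class probabilities --------------------------------------------------

def test_uniform_distribution_at_zero_field(classes4):
    model = RingModel(h=0.0, J=0.0)
    probs = model.class_probability_map(classes4)
    assert probs == pytest.approx(
        {"4R0A": 1 / 16, "3R1A": 4 / 16, "2R2A_ortho": 4 / 16,
         "2R2A_para": 2 / 16, "1R3A": 4 / 16, "0R4A": 1 / 16}
    )


@pytest.mark.parametrize("n", [2, 3, 4, 6, 8])
@pytest.mark.parametrize("h, J", [(0.0, 0.0), (-0.5, 0.8), (1.5, -1.0), (2.0, 0.3)])
def test_class_probabilities_match_brute_force(n, h, J):
    classes = enumerate_classes(n)
    model = RingModel(n=n, h=h, J=J)
    probs = model.class_probabilities(classes)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    oracle = brute_force_class_probabilities(n, h, J, classes)
    np.testing.assert_allclose(probs, oracle, atol=1e-12)


def test_independence_reduces_to_binomial_with_multiplicity(classes4):
    p = 0.8026
    model = RingModel.from_p(p)
    probs = model.class_probabilities(classes4)
    for c, prob in zip(classes4, probs):
        expected = c.orbit_size * p**c.active_count * (1 - p) ** (4 - c.active_count)
        assert prob == pytest.approx(expected, abs=1e-12)
    # tail matches the plain binomial
    assert model.predicted_open_fraction(3) == pytest.approx(
        sps.binom.sf(2, 4, p), abs=1e-12
    )


def test_strong_positive_coupling_concentrates_on_uniform_rings(classes4):
    probs = RingModel(h=0.0, J=10.0).class_probability_map(classes4)
    assert probs["4R0A"] + probs["0R4A"] > 0.999


@pytest.mark.parametrize(
    "p, k, expected",
    [(0.1582, 3, 0.0140), (0.5, 3, 5 / 16)],
)
def test_predicted_open_fraction_binomial_values(p, k, expected):
    assert RingModel.from_p(p).predicted_open_fraction(k) == pytest.approx(
        expected, abs=5e-4
    )


def test_predicted_open_fraction_saturates_at_p_one():
    model = RingModel(h=30.0, J=0.0)  # p -> 1
    for k in (1, 2, 3, 4):
        assert model.predicted_open_fraction(k) == pytest.approx(1.0, abs=1e-9)


# -- independence fit -----------------------------------------------------

def test_independent_fit_is_plugin_subunit_fraction(fixture_spectra):
    for spec in fixture_spectra.values():
        res = RingCouplingModel(spec).fit_independent()
        assert res.p_hat == pytest.approx(spec.active_fraction(), abs=1e-12)
        assert res.J_hat == 0.0 and not res.boundary


def test_independent_fit_boundary_flag():
    res = RingCouplingModel.from_counts({"0R4A": 50}).fit_independent()
    assert res.boundary and res.p_hat == 1.0
    assert np.isfinite(res.llf)


def test_exhaustive_orbit_spectrum_fits_at_origin(classes4):
    spec = spectrum_from_counts({c.name: c.orbit_size for c in classes4})
    res = RingCouplingModel(spec).fit()
    assert res.h_hat == pytest.approx(0.0, abs=1e-4)
    assert res.J_hat == pytest.approx(0.0, abs=1e-4)
    assert res.lrt_vs_independent().statistic == pytest.approx(0.0, abs=1e-6)


# -- coupled fit ----------------------------------------------------------

def test_coupled_fit_recovers_generating_parameters():
    truth = RingModel(h=-0.5, J=0.8)
    spec = truth.simulate_spectrum(100_000, seed=11)
    res = RingCouplingModel(spec).fit()
    assert res.converged
    assert res.h_hat == pytest.approx(-0.5, abs=0.05)
    assert res.J_hat == pytest.approx(0.8, abs=0.05)
    # coupled likelihood can never fall below the independence profile
    ll0 = RingCouplingModel(spec).fit_independent().llf
    assert res.llf >= ll0 - 1e-6


def test_coupled_fit_near_zero_when_independent():
    spec = RingModel.from_p(0.35).simulate_spectrum(100_000, seed=5)
    res = RingCouplingModel(spec).fit()
    assert res.J_hat == pytest.approx(0.0, abs=0.05)


def test_single_class_spectrum_not_identifiable():
    with pytest.raises(NonIdentifiableError):
        RingCouplingModel.from_counts({"4R0A": 99}).fit()
    with pytest.raises(EmptySpectrumError):
        RingCouplingModel.from_counts({})


def test_standard_errors_shrink_with_sample_size():
    truth = RingModel(h=-0.3, J=0.4)
    small = RingCouplingModel(truth.simulate_spectrum(2_000, seed=3)).fit()
    large = RingCouplingModel(truth.simulate_spectrum(200_000, seed=3)).fit()
    assert np.all(large.bse < small.bse)
    assert large.bse[1] == pytest.approx(small.bse[1] / 10, rel=0.35)


# -- cooperativity LRT ----------------------------------------------------

def test_lrt_large_for_heat_dataset(fixture_spectra):
    """At 37 C the >=3-activated tail (26.2%) far exceeds the 18.3% that
    independence at the same subunit fraction would give; the LRT sees it."""
    spec = fixture_spectra["apo_37C"]
    p = spec.active_fraction()
    indep_tail = float(sps.binom.sf(2, 4, p))
    assert indep_tail == pytest.approx(0.183, abs=5e-4)
    assert spec.occupancy_at_least(3) == pytest.approx(0.2617, abs=5e-4)
    test = lrt_cooperativity(spec)
    assert test.lrt > 1000
    assert test.pvalue < 1e-10
    assert test.coupled.J_hat > 0


def test_lrt_requires_coupled_results(fixture_spectra):
    res = RingCouplingModel(fixture_spectra["apo_18C"]).fit_independent()
    with pytest.raises(ConfigError):
        res.lrt_vs_independent()


def test_summary_renders(fixture_spectra):
    res = RingCouplingModel(fixture_spectra["apo_37C"]).fit()
    text = res.summary()
    assert "cooperativity LRT" in text and "J" in text
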