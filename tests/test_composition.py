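"""Occupancy statistics, intervals, and equilibrium summaries."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringstate import (
    BoundaryError,
    ConfigError,
    EmptySpectrumError,
    FoldChangeError,
    TetramerAssignment,
    bootstrap_interval,
    equilibrium,
    fold_change,
    goodman_intervals,
    interval,
    spectrum_from_counts,
    spectrum_from_tetramers,
    vant_hoff,
)


def make_spectrum(counts):
    return spectrum_from_counts(counts)


# -- spectrum construction ------------------------------------------------

def test_spectrum_from_tetramers_counts(classes4):
    tets = [
        TetramerAssignment("T1", tuple("AAAA")),
        TetramerAssignment("T2", tuple("AAAA")),
        TetramerAssignment("T3", tuple("RRRR")),
        TetramerAssignment("T4", tuple("ARAR")),
        TetramerAssignment("T5", tuple("AARR")),
    ]
    spec = spectrum_from_tetramers(tets, classes4)
    assert spec.counts == {
        "4R0A": 1, "3R1A": 0, "2R2A_ortho": 1, "2R2A_para": 1, "1R3A": 0, "0R4A": 2,
    }


def test_exhaustive_arrangements_reproduce_orbit_sizes(classes4):
    tets = [
        TetramerAssignment(f"T{i}", states)
        for i, states in enumerate(product("AR", repeat=4))
    ]
    spec = spectrum_from_tetramers(tets, classes4)
    assert spec.counts == {c.name: c.orbit_size for c in classes4}
    assert spec.active_fraction() == 0.5


def test_spectrum_rejects_unknown_class_and_negative_count():
    with pytest.raises(Exception, match="not enumerated"):
        spectrum_from_counts({"5R0A": 3})
    with pytest.raises(Exception, match="non-negative"):
        spectrum_from_counts({"4R0A": -1})


# -- subunit fraction and occupancy ---------------------------------------

def test_active_fraction_against_per_tetramer_oracle(classes4):
    """Spectrum-level fraction equals mean per-tetramer active count / n."""
    rng = np.random.default_rng(7)
    arrangements = ["".join(rng.choice(list("AR"), 4)) for _ in range(300)]
    tets = [TetramerAssignment(f"T{i}", tuple(a)) for i, a in enumerate(arrangements)]
    spec = spectrum_from_tetramers(tets, classes4)
    oracle = np.mean([a.count("A") for a in arrangements]) / 4
    assert spec.active_fraction() == pytest.approx(oracle, abs=1e-12)


def test_all_resting_spectrum_has_zero_active_fraction():
    assert make_spectrum({"4R0A": 123}).active_fraction() == 0.0


def test_occupancy_tail_properties(fixture_spectra):
    spec = fixture_spectra["apo_37C"]
    occ = [spec.occupancy_at_least(k) for k in range(5)]
    assert occ[0] == 1.0
    assert all(a >= b for a, b in zip(occ, occ[1:]))  # non-increasing
    assert occ[4] == spec.counts["0R4A"] / spec.total


def test_statistics_invariant_under_count_insertion_order(fixture_spectra):
    counts = fixture_spectra["apo_37C"].counts
    shuffled = dict(reversed(list(counts.items())))
    assert make_spectrum(shuffled).active_fraction() == pytest.approx(
        fixture_spectra["apo_37C"].active_fraction(), abs=0
    )


def test_empty_spectrum_statistics_raise():
    spec = make_spectrum({})
    for call in (spec.active_fraction, lambda: spec.occupancy_at_least(2)):
        with pytest.raises(EmptySpectrumError):
            call()


# -- fold changes ---------------------------------------------------------

def test_fold_change_identity_and_zero_denominator(fixture_spectra):
    spec = fixture_spectra["apo_18C"]
    assert fold_change(spec, spec, "occ3") == pytest.approx(1.0)
    zero = make_spectrum({"4R0A": 10})
    with pytest.raises(FoldChangeError):
        fold_change(spec, zero, "occ3")


def test_fold_change_p_active_between_conditions(fixture_spectra):
    fc = fold_change(
        fixture_spectra["primidone_18C"], fixture_spectra["apo_18C"], "p_active"
    )
    assert fc == pytest.approx(1.86, abs=0.005)


# -- intervals ------------------------------------------------------------

def test_bootstrap_is_deterministic_and_degenerate_spectrum_zero_width():
    spec = make_spectrum({"1R3A": 500})
    lo, hi = bootstrap_interval(spec, "occ3", B=200, seed=1)
    assert (lo, hi) == (1.0, 1.0)
    spec2 = make_spectrum({"4R0A": 300, "0R4A": 700})
    a = bootstrap_interval(spec2, "p_active", B=500, seed=42)
    b = bootstrap_interval(spec2, "p_active", B=500, seed=42)
    assert a == b
    assert a[0] < 0.7 < a[1]


def test_bootstrap_callable_statistic_agrees_with_string_path():
    spec = make_spectrum({"4R0A": 300, "2R2A_para": 200, "0R4A": 500})
    via_str = bootstrap_interval(spec, "p_active", B=300, seed=9)
    via_call = bootstrap_interval(spec, lambda s: s.active_fraction(), B=300, seed=9)
    assert via_str == pytest.approx(via_call, abs=1e-12)


def test_bootstrap_coverage_near_nominal():
    """~95% of bootstrap CIs on multinomial data cover the true p_active."""
    rng = np.random.default_rng(2024)
    true = make_spectrum({"4R0A": 240, "3R1A": 410, "2R2A_ortho": 175,
                          "2R2A_para": 90, "1R3A": 70, "0R4A": 15})
    probs = np.array(list(true.fractions().values()))
    p_true = true.active_fraction()
    names = list(true.counts)
    covered = 0
    reps = 200
    for i in range(reps):
        counts = rng.multinomial(2000, probs)
        spec = make_spectrum(dict(zip(names, (int(c) for c in counts))))
        lo, hi = bootstrap_interval(spec, "p_active", B=400, seed=i)
        covered += lo <= p_true <= hi
    rate = covered / reps
    # Monte-Carlo slack: 3 binomial SEs around 0.95 at 200 replicates
    assert abs(rate - 0.95) < 0.05


def test_goodman_intervals_contain_point_estimates(fixture_spectra):
    spec = fixture_spectra["apo_37C"]
    intervals = goodman_intervals(spec)
    for name, frac in spec.fractions().items():
        lo, hi = intervals[name]
        assert lo <= frac <= hi
        assert 0.0 <= lo <= hi <= 1.0


def test_interval_dispatcher_rejects_unknown_method(fixture_spectra):
    with pytest.raises(ConfigError):
        interval(fixture_spectra["apo_18C"], method="jackknife")


# -- equilibrium layer ----------------------------------------------------

def test_equilibrium_symmetric_point():
    eq = equilibrium(0.5, 25.0)
    assert eq.K == pytest.approx(1.0)
    assert eq.dG_kJ_mol == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "p, t, expected_K, expected_dG",
    [(0.1582, 18.0, 0.188, 4.05), (0.4034, 37.0, 0.676, 1.01)],
)
def test_equilibrium_closed_form(p, t, expected_K, expected_dG):
    eq = equilibrium(p, t)
    assert eq.K == pytest.approx(expected_K, abs=5e-4)
    assert eq.dG_kJ_mol == pytest.approx(expected_dG, abs=5e-3)


def test_equilibrium_boundary_raises():
    for p in (0.0, 1.0):
        with pytest.raises(BoundaryError):
            equilibrium(p, 20.0)


def test_vant_hoff_zero_and_symmetry():
    assert vant_hoff(0.3, 10.0, 0.3, 30.0) == pytest.approx(0.0, abs=1e-12)
    forward = vant_hoff(0.2, 18.0, 0.5, 37.0)
    backward = vant_hoff(0.5, 37.0, 0.2, 18.0)
    assert forward == pytest.approx(backward, abs=1e-9)
    with pytest.raises(ConfigError):
        vant_hoff(0.2, 25.0, 0.4, 25.0)


def test_vant_hoff_against_independent_arithmetic():
    """dH recomputed step by step: K ratios and inverse-temperature gap."""
    p1, p2 = 0.1582, 0.4034
    T1, T2 = 291.15, 310.15
    expected = (
        8.314 * math.log((p2 / (1 - p2)) / (p1 / (1 - p1)))
        / (1 / T1 - 1 / T2) / 1000
    )
    assert vant_hoff(p1, 18.0, p2, 37.0) == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(50.6, abs=0.1)


# -- permutation property -------------------------------------------------

@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.integers(0, 1000), min_size=6, max_size=6))
def test_summary_statistics_well_defined_for_any_counts(counts):
    names = ["4R0A", "3R1A", "2R2A_ortho", "2R2A_para", "1R3A", "0R4A"]
    spec = spectrum_from_counts(dict(zip(names, counts)))
    if spec.total == 0:
        with pytest.raises(EmptySpectrumError):
            spec.active_fraction()
        return
    p = spec.active_fraction()
    assert 0.0 <= p <= 1.0
    occs = [spec.occupancy_at_least(k) for k in range(5)]
    assert occs[0] == 1.0
    assert all(x >= y - 1e-15 for x, y in zip(occs, occs[1:]))
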