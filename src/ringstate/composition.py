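"""Composition spectra and occupancy statistics for ring-shaped oligomers.

A *composition spectrum* is the per-condition histogram of intact
tetramers over the six rotation classes.  From it this module computes

* the subunit-level activated fraction ``p = Σ a_c n_c / (n N)``,
* tetramer occupancy tails ``P(at least k activated subunits)``,
* fold changes of either statistic between conditions,
* uncertainty intervals (tetramer-level bootstrap, or Goodman
  simultaneous multinomial intervals for the class fractions), and
* two-state equilibrium summaries: ``K = p/(1-p)``,
  ``ΔG = -R T ln K`` and a two-temperature van't Hoff enthalpy
  ``ΔH = R ln(K2/K1) / (1/T1 - 1/T2)``.

The tetramer — not the subunit — is the independent sampling unit, so the
bootstrap resamples tetramers.  All statistics operate on intact
tetramers only (the exclusion rule is applied upstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    BoundaryError,
    ConfigError,
    EmptySpectrumError,
    FoldChangeError,
    FormatError,
)
from .io import ConditionMeta, TetramerAssignment
from .ring import TWO_STATE, CompositionClass, canonicalize, enumerate_classes

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314
#: Offset between Celsius and Kelvin scales.
KELVIN_OFFSET = 273.15

#: Default bootstrap settings (B resamples, seed for reproducibility).
DEFAULT_BOOTSTRAP_B = 2000
DEFAULT_BOOTSTRAP_SEED = 20250124


@dataclass
class CompositionSpectrum:
    """Counts of intact tetramers per composition class.

    ``counts`` maps class name -> non-negative integer and always carries
    a key for every enumerated class (absent classes count zero).
    """

    counts: dict[str, int]
    classes: list[CompositionClass] = field(default_factory=lambda: enumerate_classes(4))
    condition: ConditionMeta | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.classes]
        unknown = set(self.counts) - set(names)
        if unknown:
            raise FormatError(
                f"count keys {sorted(unknown)} are not enumerated classes {names}"
            )
        for k, v in self.counts.items():
            if v < 0 or int(v) != v:
                raise FormatError(f"count for {k!r} must be a non-negative integer")
        self.counts = {name: int(self.counts.get(name, 0)) for name in names}

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        """Ring size."""
        return self.classes[0].n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def count_vector(self) -> np.ndarray:
        return np.array([self.counts[c.name] for c in self.classes], dtype=np.int64)

    @property
    def active_counts(self) -> np.ndarray:
        return np.array([c.active_count for c in self.classes], dtype=np.int64)

    def _require_nonempty(self) -> None:
        if self.total == 0:
            raise EmptySpectrumError(
                "spectrum holds no intact tetramers; statistics undefined"
            )

    # -- statistics ------------------------------------------------------
    def active_fraction(self) -> float:
        """Fraction of subunits in the activated state."""
        self._require_nonempty()
        counts = self.count_vector
        return float((self.active_counts * counts).sum() / (self.n * counts.sum()))

    def occupancy_at_least(self, k: int) -> float:
        """Fraction of tetramers with >= k activated subunits."""
        if not 0 <= k <= self.n:
            raise ConfigError(f"occupancy threshold k={k} outside [0, {self.n}]")
        self._require_nonempty()
        counts = self.count_vector
        return float(counts[self.active_counts >= k].sum() / counts.sum())

    def fractions(self) -> dict[str, float]:
        self._require_nonempty()
        total = self.total
        return {name: cnt / total for name, cnt in self.counts.items()}

    # -- convenience -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        total = self.total
        for c in self.classes:
            cnt = self.counts[c.name]
            rows.append(
                {
                    "class_name": c.name,
                    "count": cnt,
                    "fraction": cnt / total if total else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def plot(self, ax=None, as_fraction: bool = True, **bar_kw):
        """Bar chart of the spectrum (fractions by default)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        names = [c.name for c in self.classes]
        total = self.total
        values = [
            self.counts[n] / total if (as_fraction and total) else self.counts[n]
            for n in names
        ]
        ax.bar(names, values, **bar_kw)
        ax.set_ylabel("fraction of tetramers" if as_fraction else "tetramer count")
        if self.condition is not None:
            ax.set_title(self.condition.condition)
        ax.tick_params(axis="x", rotation=45)
        return ax


def spectrum_from_tetramers(
    assignments: Iterable[TetramerAssignment],
    classes: Sequence[CompositionClass] | None = None,
    condition: ConditionMeta | None = None,
) -> CompositionSpectrum:
    """Histogram intact tetramer assignments over composition classes.

    All assignments must be intact (apply :func:`ringstate.io.filter_intact`
    first); an empty input raises :class:`EmptySpectrumError` because every
    downstream statistic would be undefined.
    """
    assignments = list(assignments)
    if not assignments:
        raise EmptySpectrumError("no intact tetramers to histogram")
    if classes is None:
        classes = enumerate_classes(len(assignments[0].states))
    index = {c.canonical: c for c in classes}
    alphabet = TWO_STATE
    counts = {c.name: 0 for c in classes}
    for t in assignments:
        if not t.intact:
            raise FormatError(
                f"tetramer {t.tetramer_id!r} is not intact; filter before computing "
                "a spectrum"
            )
        canon = canonicalize(t.arrangement, alphabet)
        counts[index[canon].name] += 1
    return CompositionSpectrum(counts=counts, classes=list(classes), condition=condition)


def spectrum_from_counts(
    counts: Mapping[str, int],
    condition: ConditionMeta | None = None,
    n: int = 4,
) -> CompositionSpectrum:
    """Build a spectrum directly from per-class counts (e.g. published tables)."""
    return CompositionSpectrum(
        counts=dict(counts), classes=enumerate_classes(n), condition=condition
    )


# -- module-level statistic helpers (thin wrappers over the methods) ------

def subunit_active_fraction(spectrum: CompositionSpectrum) -> float:
    return spectrum.active_fraction()


def occupancy_at_least(spectrum: CompositionSpectrum, k: int) -> float:
    return spectrum.occupancy_at_least(k)


def _resolve_statistic(
    statistic: str | Callable[[CompositionSpectrum], float],
) -> Callable[[CompositionSpectrum], float]:
    if callable(statistic):
        return statistic
    if statistic == "p_active":
        return subunit_active_fraction
    if statistic.startswith("occ"):
        try:
            k = int(statistic[3:])
        except ValueError:
            raise ConfigError(f"unknown statistic {statistic!r}") from None
        return lambda s: s.occupancy_at_least(k)
    raise ConfigError(
        f"unknown statistic {statistic!r}; expected 'p_active', 'occ<k>' or a callable"
    )


def fold_change(
    spec_a: CompositionSpectrum,
    spec_b: CompositionSpectrum,
    statistic: str | Callable[[CompositionSpectrum], float] = "occ3",
) -> float:
    """Ratio statistic(spec_a) / statistic(spec_b).

    Raises :class:`FoldChangeError` when the reference statistic is zero —
    report a one-sided bound from :func:`interval` instead of a ratio.
    """
    stat = _resolve_statistic(statistic)
    denom = stat(spec_b)
    if denom == 0:
        raise FoldChangeError(
            "reference statistic is zero; fold change undefined — report a "
            "one-sided interval bound instead"
        )
    return stat(spec_a) / denom


def bootstrap_interval(
    spectrum: CompositionSpectrum,
    statistic: str | Callable[[CompositionSpectrum], float] = "p_active",
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval, resampling tetramers with replacement.

    Resampling N tetramers from the empirical class distribution is a
    multinomial draw over the class counts, which keeps the procedure
    exact and fast even for millions of particles.  Deterministic for a
    fixed seed.
    """
    spectrum._require_nonempty()
    if B < 100:
        raise ConfigError(f"bootstrap needs B >= 100 resamples, got {B}")
    counts = spectrum.count_vector
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    resampled = rng.multinomial(total, counts / total, size=B)
    # common statistics are linear in the resampled counts: vectorize
    if statistic == "p_active":
        values = (resampled @ spectrum.active_counts) / (spectrum.n * total)
    elif isinstance(statistic, str) and statistic.startswith("occ"):
        _resolve_statistic(statistic)  # validates spelling
        k = int(statistic[3:])
        if not 0 <= k <= spectrum.n:
            raise ConfigError(f"occupancy threshold k={k} outside [0, {spectrum.n}]")
        values = resampled[:, spectrum.active_counts >= k].sum(axis=1) / total
    else:
        stat = _resolve_statistic(statistic)
        values = np.empty(B)
        for i, row in enumerate(resampled):
            boot = CompositionSpectrum(
                counts={c.name: int(v) for c, v in zip(spectrum.classes, row)},
                classes=spectrum.classes,
                condition=spectrum.condition,
            )
            values[i] = stat(boot)
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def goodman_intervals(
    spectrum: CompositionSpectrum, alpha: float = 0.05
) -> dict[str, tuple[float, float]]:
    """Goodman simultaneous confidence intervals for the class fractions.

    Closed-form quadratic inversion with a Bonferroni-adjusted chi-square
    quantile (1 df at level 1 - alpha/m for m classes), giving joint
    coverage >= 1 - alpha for all class fractions at once.
    """
    spectrum._require_nonempty()
    counts = spectrum.count_vector.astype(float)
    total = counts.sum()
    m = len(counts)
    a = sps.chi2.ppf(1 - alpha / m, df=1)
    out = {}
    for c, n_c in zip(spectrum.classes, counts):
        centre = a + 2 * n_c
        half = math.sqrt(a * (a + 4 * n_c * (total - n_c) / total))
        lo = (centre - half) / (2 * (total + a))
        hi = (centre + half) / (2 * (total + a))
        out[c.name] = (max(0.0, lo), min(1.0, hi))
    return out


def interval(
    spectrum: CompositionSpectrum,
    statistic: str | Callable[[CompositionSpectrum], float] = "p_active",
    method: str = "bootstrap",
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    alpha: float = 0.05,
):
    """95% (by default) uncertainty interval for a spectrum statistic.

    ``method='bootstrap'`` supports any statistic; ``method='goodman'``
    returns the simultaneous per-class fraction intervals (the statistic
    argument is ignored for it).
    """
    if method == "bootstrap":
        return bootstrap_interval(spectrum, statistic, B=B, seed=seed, alpha=alpha)
    if method == "goodman":
        return goodman_intervals(spectrum, alpha=alpha)
    raise ConfigError(f"unknown interval method {method!r}")


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition occupancy summary with bootstrap uncertainties."""

    condition: ConditionMeta | None
    n_tetramers: int
    p_active: float
    occupancy: dict[int, float]  # k -> P(>= k activated)
    intervals: dict[str, tuple[float, float]]
    interval_method: str = "bootstrap"

    def to_dict(self) -> dict:
        return {
            "condition": None if self.condition is None else vars(self.condition),
            "n_tetramers": self.n_tetramers,
            "p_active": self.p_active,
            "occupancy_at_least": {str(k): v for k, v in self.occupancy.items()},
            "intervals": self.intervals,
            "interval_method": self.interval_method,
        }


def summarize(
    spectrum: CompositionSpectrum,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> ConditionSummary:
    """Full occupancy summary: p_active and every tail P(>=k), with CIs."""
    spectrum._require_nonempty()
    n = spectrum.n
    occ = {k: spectrum.occupancy_at_least(k) for k in range(n + 1)}
    intervals = {
        "p_active": bootstrap_interval(spectrum, "p_active", B=B, seed=seed)
    }
    for k in range(1, n + 1):
        intervals[f"occ{k}"] = bootstrap_interval(spectrum, f"occ{k}", B=B, seed=seed)
    return ConditionSummary(
        condition=spectrum.condition,
        n_tetramers=spectrum.total,
        p_active=spectrum.active_fraction(),
        occupancy=occ,
        intervals=intervals,
    )


# -- two-state equilibrium layer ------------------------------------------

@dataclass(frozen=True)
class EquilibriumSummary:
    """Resting<->activated equilibrium at a single temperature.

    K is the dimensionless equilibrium constant p/(1-p) for the activated
    fraction p; dG_kJ_mol = -R T ln K is the standard free-energy
    difference of activation (positive when resting dominates).
    """

    p: float
    temperature_c: float
    K: float
    dG_kJ_mol: float


def equilibrium(p: float, temperature_c: float) -> EquilibriumSummary:
    """Two-state equilibrium constant and free energy at one temperature."""
    if not 0.0 < p < 1.0:
        raise BoundaryError(
            f"p={p} is on the boundary; K and dG are undefined — report an "
            "interval-based bound instead"
        )
    K = p / (1.0 - p)
    T = temperature_c + KELVIN_OFFSET
    dG = -R_GAS * T * math.log(K) / 1000.0
    return EquilibriumSummary(p=p, temperature_c=temperature_c, K=K, dG_kJ_mol=dG)


def vant_hoff(
    p1: float, t1_celsius: float, p2: float, t2_celsius: float
) -> float:
    """Two-temperature van't Hoff enthalpy of the subunit equilibrium, kJ/mol.

    dH = R ln(K2/K1) / (1/T1 - 1/T2) with temperatures in kelvin; assumes
    dH constant over [T1, T2].  Symmetric: swapping the two conditions
    leaves dH unchanged.
    """
    if t1_celsius == t2_celsius:
        raise ConfigError("van't Hoff enthalpy is degenerate at equal temperatures")
    k1 = equilibrium(p1, t1_celsius).K
    k2 = equilibrium(p2, t2_celsius).K
    T1 = t1_celsius + KELVIN_OFFSET
    T2 = t2_celsius + KELVIN_OFFSET
    return R_GAS * math.log(k2 / k1) / (1.0 / T1 - 1.0 / T2) / 1000.0
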