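"""Two-state ring models and cooperativity inference.

The probabilistic backbone is a nearest-neighbour Ising-type model on the
Cn ring.  Writing each subunit state as s_i in {0, 1} (0 resting, 1
activated), an arrangement s has probability

    P(s) = exp(h * sum_i s_i + J * sum_i s_i s_{i+1 mod n}) / Z

where h is the per-subunit activation field (h = logit(p), so p is the
activation probability of an isolated subunit), J the nearest-neighbour
coupling (J = 0 means subunits activate independently and the composition
spectrum is binomial with rotation multiplicities), and Z the normalizer
over all 2^n arrangements.  Both sums are rotation invariant, so every
arrangement in a composition class has the same probability and

    P(class c) = m_c * exp(h * a_c + J * g_c) / Z

with m_c the orbit size, a_c the activated count and g_c the number of
adjacent activated pairs of the class.  Only class counts are observable
(rotations are indistinguishable after symmetry expansion); the adjacent
vs diagonal split of the two-activated classes is what identifies J.

Fitting follows the statsmodels pattern: :class:`RingCouplingModel` is
built from a :class:`~ringstate.composition.CompositionSpectrum` and its
``fit`` method returns a :class:`RingCouplingResults` carrying estimates,
standard errors, log-likelihood and a ``summary()`` table; the
cooperativity likelihood-ratio test compares the coupled fit against the
independence fit (J fixed at 0, whose MLE for p is the plug-in subunit
fraction) on one chi-square degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special
from scipy import stats as sps

from .composition import CompositionSpectrum, spectrum_from_counts
from .errors import ConfigError, EmptySpectrumError, NonIdentifiableError
from .ring import ACTIVATED, TWO_STATE, CompositionClass, enumerate_classes

_LRT_TOL = 1e-6  # numerical slack on the non-negativity of the LRT statistic


def _class_features(
    classes: Sequence[CompositionClass], active_label: str = ACTIVATED
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(orbit sizes m_c, activated counts a_c, adjacent activated pairs g_c)."""
    m = np.array([c.orbit_size for c in classes], dtype=float)
    a = np.array([c.active_count for c in classes], dtype=float)
    g = np.empty(len(classes))
    for i, c in enumerate(classes):
        s = np.array([1 if lab == active_label else 0 for lab in c.canonical])
        g[i] = int((s * np.roll(s, -1)).sum()) if len(s) > 1 else int(s.sum())
    return m, a, g


@dataclass(frozen=True)
class RingModel:
    """Exact two-state nearest-neighbour model on a Cn ring.

    Parameters
    ----------
    n
        Ring size (4 for a homotetramer).
    h
        Activation field; p = expit(h) is the isolated-subunit activation
        probability.
    J
        Nearest-neighbour coupling; positive J favours like neighbours
        (cooperative activation), J = 0 is independence.
    """

    n: int = 4
    h: float = 0.0
    J: float = 0.0

    @classmethod
    def from_p(cls, p: float, J: float = 0.0, n: int = 4) -> "RingModel":
        if not 0.0 < p < 1.0:
            raise ConfigError(f"p must lie strictly in (0, 1), got {p}")
        return cls(n=n, h=float(special.logit(p)), J=J)

    @property
    def p(self) -> float:
        """Isolated-subunit activation probability expit(h)."""
        return float(special.expit(self.h))

    # -- exact distribution ---------------------------------------------
    def class_probabilities(
        self, classes: Sequence[CompositionClass] | None = None
    ) -> np.ndarray:
        """P(class) for each composition class, in class order; sums to 1."""
        if classes is None:
            classes = enumerate_classes(self.n)
        m, a, g = _class_features(classes)
        logw = np.log(m) + self.h * a + self.J * g
        logw -= special.logsumexp(logw)
        return np.exp(logw)

    def class_probability_map(
        self, classes: Sequence[CompositionClass] | None = None
    ) -> dict[str, float]:
        if classes is None:
            classes = enumerate_classes(self.n)
        return dict(zip((c.name for c in classes), self.class_probabilities(classes)))

    def arrangement_distribution(
        self,
    ) -> tuple[list[tuple[str, ...]], np.ndarray]:
        """All k^n arrangements with their exact probabilities.

        Expands each class over its orbit (every rotation of a class
        member has the same probability); used by the synthetic sampler.
        """
        classes = enumerate_classes(self.n)
        probs = self.class_probabilities(classes)
        arrangements: list[tuple[str, ...]] = []
        weights: list[float] = []
        for c, pc in zip(classes, probs):
            members = sorted({c.canonical[i:] + c.canonical[:i] for i in range(self.n)})
            for member in members:
                arrangements.append(member)
                weights.append(pc / c.orbit_size)
        return arrangements, np.asarray(weights)

    def predicted_open_fraction(
        self, k_req: int, classes: Sequence[CompositionClass] | None = None
    ) -> float:
        """P(>= k_req activated subunits) under the model.

        With a concerted-opening hypothesis requiring k_req activated
        subunits, this is the predicted fraction of channels able to open.
        """
        if classes is None:
            classes = enumerate_classes(self.n)
        if not 1 <= k_req <= self.n:
            raise ConfigError(f"k_req={k_req} outside [1, {self.n}]")
        probs = self.class_probabilities(classes)
        a = np.array([c.active_count for c in classes])
        return float(probs[a >= k_req].sum())

    # -- simulation ------------------------------------------------------
    def simulate_spectrum(
        self,
        n_tetramers: int,
        seed: int | np.random.Generator,
        classes: Sequence[CompositionClass] | None = None,
    ) -> CompositionSpectrum:
        """Multinomial draw of class counts from the exact distribution."""
        if n_tetramers < 1:
            raise ConfigError("n_tetramers must be >= 1")
        if classes is None:
            classes = enumerate_classes(self.n)
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n_tetramers, self.class_probabilities(classes))
        return spectrum_from_counts(
            {c.name: int(v) for c, v in zip(classes, counts)}, n=self.n
        )


class RingCouplingModel:
    """Multinomial likelihood of a composition spectrum under the ring model.

    Observations are the per-class counts of a
    :class:`~ringstate.composition.CompositionSpectrum`; the likelihood is
    the 6-class multinomial (for n=4) with class probabilities from
    :class:`RingModel`, evaluated exactly by enumeration of the small
    state space.

    Examples
    --------
    >>> from ringstate.datasets import load_fixture
    >>> res = RingCouplingModel(load_fixture("apo_37C")).fit()
    >>> res.lrt_vs_independent().pvalue  # doctest: +SKIP
    """

    #: Default deterministic initialisation grid for the coupled fit.
    GRID_H = np.arange(-4.0, 4.0 + 1e-9, 0.25)
    GRID_J = np.arange(-3.0, 3.0 + 1e-9, 0.25)

    def __init__(self, spectrum: CompositionSpectrum):
        if spectrum.total == 0:
            raise EmptySpectrumError("cannot fit a model to an empty spectrum")
        self.spectrum = spectrum
        self.classes = spectrum.classes
        self.counts = spectrum.count_vector.astype(float)
        self.nobs = int(self.counts.sum())
        self._m, self._a, self._g = _class_features(self.classes)
        self._log_m = np.log(self._m)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_counts(cls, counts: Mapping[str, int], n: int = 4) -> "RingCouplingModel":
        return cls(spectrum_from_counts(counts, n=n))

    @classmethod
    def from_tetramers(cls, assignments, classes=None) -> "RingCouplingModel":
        from .composition import spectrum_from_tetramers

        return cls(spectrum_from_tetramers(assignments, classes=classes))

    # -- likelihood ------------------------------------------------------
    def loglike(self, params: Sequence[float]) -> float:
        """Exact multinomial log-likelihood at params = (h, J).

        Omits the multinomial coefficient, which is parameter free.
        """
        h, J = params
        logw = self._log_m + h * self._a + J * self._g
        logp = logw - special.logsumexp(logw)
        return float(self.counts @ logp)

    def _loglike_grid(self, hs: np.ndarray, js: np.ndarray) -> np.ndarray:
        """Vectorized log-likelihood over an (h, J) grid."""
        logw = (
            self._log_m[None, None, :]
            + hs[:, None, None] * self._a[None, None, :]
            + js[None, :, None] * self._g[None, None, :]
        )
        logp = logw - special.logsumexp(logw, axis=-1, keepdims=True)
        return logp @ self.counts

    def _loglike_independent(self, p: float) -> float:
        # binomial-with-multiplicity likelihood; 0*log(0) := 0 at the boundary
        n = self.spectrum.n
        logp = (
            self._log_m
            + special.xlogy(self._a, p)
            + special.xlogy(n - self._a, 1.0 - p)
        )
        mask = self.counts > 0
        return float((self.counts[mask] * logp[mask]).sum())

    # -- fitting ---------------------------------------------------------
    def fit_independent(self) -> "RingCouplingResults":
        """Closed-form independence fit (J fixed at 0).

        The multinomial MLE for p is the plug-in subunit activated
        fraction; at a boundary estimate (p in {0, 1}) the field h is
        infinite and the result carries ``boundary=True``.
        """
        p_hat = float((self._a @ self.counts) / (self.spectrum.n * self.nobs))
        boundary = p_hat in (0.0, 1.0)
        h_hat = math.inf if p_hat == 1.0 else (-math.inf if p_hat == 0.0 else float(special.logit(p_hat)))
        llf = self._loglike_independent(p_hat)
        se_h = float("nan")
        if not boundary:
            # Fisher information for h from the 4N independent-subunit Bernoulli
            info = self.spectrum.n * self.nobs * p_hat * (1 - p_hat)
            se_h = 1.0 / math.sqrt(info)
        return RingCouplingResults(
            model=self,
            params=np.array([h_hat, 0.0]),
            llf=llf,
            df_model=1,
            coupled=False,
            converged=True,
            boundary=boundary,
            bse=np.array([se_h, 0.0]),
        )

    def fit(
        self,
        coupled: bool = True,
        xtol: float = 1e-8,
        grid_h: np.ndarray | None = None,
        grid_J: np.ndarray | None = None,
    ) -> "RingCouplingResults":
        """Maximum-likelihood fit.

        The coupled fit is deterministic: a coarse grid search over
        (h, J) picks the start, then a Nelder-Mead refinement converges
        to ``xtol``.  Requires at least two occupied classes — a single
        occupied class leaves (h, J) non-identifiable.
        """
        if not coupled:
            return self.fit_independent()
        if (self.counts > 0).sum() < 2:
            raise NonIdentifiableError(
                "coupled fit requires >= 2 occupied composition classes"
            )
        hs = self.GRID_H if grid_h is None else np.asarray(grid_h, dtype=float)
        js = self.GRID_J if grid_J is None else np.asarray(grid_J, dtype=float)
        ll = self._loglike_grid(hs, js)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        x0 = np.array([hs[i], js[j]])
        res = optimize.minimize(
            lambda x: -self.loglike(x),
            x0,
            method="Nelder-Mead",
            options={"xatol": xtol, "fatol": 1e-12, "maxiter": 2000},
        )
        bse = self._bse(res.x)
        return RingCouplingResults(
            model=self,
            params=res.x,
            llf=float(-res.fun),
            df_model=2,
            coupled=True,
            converged=bool(res.success),
            boundary=False,
            bse=bse,
        )

    def _bse(self, params: np.ndarray, step: float = 1e-4) -> np.ndarray:
        """Standard errors from the finite-difference observed information."""
        hess = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                e_i = np.eye(2)[i] * step
                e_j = np.eye(2)[j] * step
                hess[i, j] = (
                    self.loglike(params + e_i + e_j)
                    - self.loglike(params + e_i - e_j)
                    - self.loglike(params - e_i + e_j)
                    + self.loglike(params - e_i - e_j)
                ) / (4 * step * step)
        try:
            cov = np.linalg.inv(-hess)
            diag = np.diag(cov)
            if np.any(diag <= 0):
                return np.full(2, np.nan)
            return np.sqrt(diag)
        except np.linalg.LinAlgError:
            return np.full(2, np.nan)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of nearest-neighbour cooperativity (J = 0)."""

    statistic: float
    pvalue: float
    df: int = 1


@dataclass
class RingCouplingResults:
    """Results of a ring-model fit, statsmodels style.

    ``params`` is (h_hat, J_hat); ``bse`` the matching standard errors
    (observed-information for the coupled fit).  ``p_hat`` is expit(h_hat)
    — the isolated-subunit activation probability, which equals the
    observed subunit fraction only under independence.
    """

    model: RingCouplingModel
    params: np.ndarray
    llf: float
    df_model: int
    coupled: bool
    converged: bool
    boundary: bool
    bse: np.ndarray

    @property
    def h_hat(self) -> float:
        return float(self.params[0])

    @property
    def J_hat(self) -> float:
        return float(self.params[1])

    @property
    def p_hat(self) -> float:
        return float(special.expit(self.params[0]))

    @property
    def fitted_model(self) -> RingModel:
        return RingModel(n=self.model.spectrum.n, h=self.h_hat, J=self.J_hat)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Expected class counts under the fitted model."""
        probs = self.fitted_model.class_probabilities(self.model.classes)
        return self.model.nobs * probs

    def lrt_vs_independent(self) -> LRTResult:
        """Cooperativity LRT: coupled (h, J) against independence (h, 0).

        2*(ll_coupled - ll_independent) referred to chi-square with one
        degree of freedom; tiny negative statistics from optimizer
        round-off are clipped to zero.
        """
        if not self.coupled:
            raise ConfigError("call lrt_vs_independent on a coupled fit")
        ll0 = self.model.fit_independent().llf
        stat = 2.0 * (self.llf - ll0)
        if stat < -_LRT_TOL:
            raise RuntimeError(
                f"coupled likelihood below independence likelihood (lrt={stat}); "
                "optimization failed"
            )
        stat = max(stat, 0.0)
        return LRTResult(statistic=stat, pvalue=float(sps.chi2.sf(stat, df=1)))

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            "Ring coupling model" if self.coupled else "Ring independence model",
            "=" * 46,
            f"ring size            {self.model.spectrum.n:>10d}",
            f"tetramers (N)        {self.model.nobs:>10d}",
            f"log-likelihood       {self.llf:>14.3f}",
            f"converged            {str(self.converged):>10s}",
        ]
        if self.boundary:
            lines.append("NOTE: boundary estimate (p_hat in {0, 1})")
        lines.append("-" * 46)
        lines.append(f"{'param':<8}{'estimate':>12}{'std err':>12}")
        for name, est, se in zip(("h", "J"), self.params, self.bse):
            lines.append(f"{name:<8}{est:>12.4f}{se:>12.4f}")
        lines.append(f"{'p':<8}{self.p_hat:>12.4f}")
        if self.coupled:
            lrt = self.lrt_vs_independent()
            lines.append("-" * 46)
            lines.append(
                f"cooperativity LRT    {lrt.statistic:>12.3f}  "
                f"p={lrt.pvalue:.3g} (chi2, 1 df)"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class CooperativityTest:
    """Bundled output of the cooperativity analysis of one spectrum."""

    independent: RingCouplingResults
    coupled: RingCouplingResults
    lrt: float
    pvalue: float


def lrt_cooperativity(spectrum: CompositionSpectrum) -> CooperativityTest:
    """Fit both models to a spectrum and test J = 0 on chi-square(1)."""
    model = RingCouplingModel(spectrum)
    coupled = model.fit(coupled=True)
    independent = model.fit_independent()
    lrt = coupled.lrt_vs_independent()
    return CooperativityTest(
        independent=independent,
        coupled=coupled,
        lrt=lrt.statistic,
        pvalue=lrt.pvalue,
    )
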