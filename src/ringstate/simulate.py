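"""Seeded synthetic particle tables with known ground truth.

Emulates the label-level output of a symmetry-expanded per-subunit 3D
classification so the whole pipeline (read -> trace-back -> intactness
filter -> spectrum -> fit) can be exercised without any experimental
download.  Generation proceeds in three stages, per tetramer:

1. the true arrangement is drawn i.i.d. from the exact 2^n-state
   distribution of a :class:`~ringstate.model.RingModel`;
2. each subunit is independently replaced by D (disordered) with
   probability delta — modelling unclassifiable density, which triggers
   whole-tetramer exclusion downstream;
3. each surviving R/A label is flipped with probability epsilon
   (symmetric by default; an asymmetric pair (eps_RA, eps_AR) is
   available because classification confusion need not be symmetric).

Disorder is applied before mislabeling: a D subunit cannot also be
mislabeled.  A single global seeded stream drives the whole run, so a
fixed config reproduces its output byte for byte.  What this generator
does *not* emulate: images, maps, alignment errors, or classification
posteriors correlated with particle quality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    ConditionMeta,
    SubunitRecord,
    TetramerAssignment,
    write_particle_table,
)
from .model import RingModel
from .ring import ACTIVATED, DISORDERED, RESTING


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for one synthetic dataset.

    Defaults mirror a heat-ramp-style condition: a sizeable minority of
    activated subunits (p = 0.4) with no coupling, 2% symmetric label
    confusion and 5% per-subunit disorder.
    """

    n_tetramers: int
    model: RingModel = field(default_factory=lambda: RingModel.from_p(0.4))
    mislabel_rate: float = 0.02
    disorder_rate: float = 0.05
    mislabel_rate_ra: float | None = None  # P(true R emitted as A); overrides symmetric
    mislabel_rate_ar: float | None = None  # P(true A emitted as R)
    condition: ConditionMeta | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tetramers < 1:
            raise ConfigError(f"n_tetramers must be >= 1, got {self.n_tetramers}")
        if not 0.0 <= self.mislabel_rate <= 0.5:
            raise ConfigError(
                f"mislabel_rate must lie in [0, 0.5], got {self.mislabel_rate}"
            )
        if not 0.0 <= self.disorder_rate <= 1.0:
            raise ConfigError(
                f"disorder_rate must lie in [0, 1], got {self.disorder_rate}"
            )
        for name in ("mislabel_rate_ra", "mislabel_rate_ar"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")

    @property
    def eps_ra(self) -> float:
        return self.mislabel_rate if self.mislabel_rate_ra is None else self.mislabel_rate_ra

    @property
    def eps_ar(self) -> float:
        return self.mislabel_rate if self.mislabel_rate_ar is None else self.mislabel_rate_ar

    def to_dict(self) -> dict:
        return {
            "n_tetramers": self.n_tetramers,
            "model": {"n": self.model.n, "h": self.model.h, "J": self.model.J,
                      "p": self.model.p},
            "mislabel_rate": self.mislabel_rate,
            "mislabel_rate_ra": self.mislabel_rate_ra,
            "mislabel_rate_ar": self.mislabel_rate_ar,
            "disorder_rate": self.disorder_rate,
            "condition": None if self.condition is None else vars(self.condition),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class GroundTruth:
    """Truth record for a generated dataset.

    ``true_states`` are the uncorrupted arrangements (label matrices of
    shape (N, n)); the flag matrices mark which subunits were set to D
    and which surviving labels were flipped, and are consistent with the
    emitted labels by construction.
    """

    true_states: np.ndarray  # dtype <U1, shape (N, n)
    emitted_states: np.ndarray  # dtype <U1, shape (N, n)
    disorder_flags: np.ndarray  # bool, shape (N, n)
    mislabel_flags: np.ndarray  # bool, shape (N, n)

    @property
    def n_tetramers(self) -> int:
        return self.true_states.shape[0]

    @property
    def true_active_fraction(self) -> float:
        return float((self.true_states == ACTIVATED).mean())

    def summary(self) -> dict:
        return {
            "n_tetramers": int(self.n_tetramers),
            "true_active_fraction": self.true_active_fraction,
            "n_disordered_subunits": int(self.disorder_flags.sum()),
            "n_mislabeled_subunits": int(self.mislabel_flags.sum()),
            "n_intact_tetramers": int((~self.disorder_flags.any(axis=1)).sum()),
        }


def _tetramer_ids(n: int) -> list[str]:
    width = max(6, len(str(n - 1)))
    return [f"T{i:0{width}d}" for i in range(n)]


def sample_tetramers(
    config: GeneratorConfig,
) -> tuple[list[TetramerAssignment], GroundTruth]:
    """Draw a synthetic dataset of tetramer assignments plus ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.model.n
    N = config.n_tetramers
    arrangements, probs = config.model.arrangement_distribution()
    arr_matrix = np.array(arrangements, dtype="<U1")  # (2^n, n)
    choice = rng.choice(len(arrangements), size=N, p=probs)
    true = arr_matrix[choice]

    disorder = rng.random((N, n)) < config.disorder_rate
    flip_draw = rng.random((N, n))
    flip_prob = np.where(true == RESTING, config.eps_ra, config.eps_ar)
    mislabel = (~disorder) & (flip_draw < flip_prob)

    emitted = true.copy()
    emitted[mislabel & (true == RESTING)] = ACTIVATED
    emitted[mislabel & (true == ACTIVATED)] = RESTING
    emitted[disorder] = DISORDERED

    cond_tag = None if config.condition is None else config.condition.condition
    ids = _tetramer_ids(N)
    assignments = [
        TetramerAssignment(tid, tuple(row), cond_tag)
        for tid, row in zip(ids, emitted)
    ]
    truth = GroundTruth(
        true_states=true,
        emitted_states=emitted,
        disorder_flags=disorder,
        mislabel_flags=mislabel,
    )
    return assignments, truth


def generate_particle_table(
    config: GeneratorConfig,
    path: str | Path,
    dialect: str | None = None,
) -> GroundTruth:
    """Write a synthetic per-subunit particle table plus a truth sidecar.

    The table holds n * n_tetramers rows in the requested dialect (TSV by
    default, STAR for ``.star`` paths); the sidecar ``<path>.truth.json``
    echoes the config and a ground-truth summary so a run is fully
    reproducible from its outputs.
    """
    path = Path(path)
    assignments, truth = sample_tetramers(config)
    records = [
        SubunitRecord(t.tetramer_id, i, s, t.condition)
        for t in assignments
        for i, s in enumerate(t.states)
        if s is not None
    ]
    write_particle_table(records, path, dialect=dialect)
    sidecar = path.with_name(path.name + ".truth.json")
    sidecar.write_text(
        json.dumps(
            {"config": config.to_dict(), "ground_truth": truth.summary()},
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    return truth


def expected_observed_fraction(p: float, eps: float) -> float:
    """Observed activated fraction under symmetric mislabeling.

    A true activated subunit is reported A with probability 1 - eps, a
    true resting one with probability eps, hence p(1-eps) + (1-p)eps.
    """
    return p * (1.0 - eps) + (1.0 - p) * eps


def corruption_effect_report(
    mislabel_rates: Sequence[float],
    model: RingModel | None = None,
    n_tetramers: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bias of the observed activated fraction across mislabel rates.

    For each epsilon, simulates a dataset (disorder off), measures the
    observed subunit activated fraction among emitted labels, and
    tabulates it against the closed form p(1-eps) + (1-p)eps together
    with the induced bias relative to the true p.
    """
    if model is None:
        model = RingModel.from_p(0.4)
    rows = []
    for i, eps in enumerate(mislabel_rates):
        config = GeneratorConfig(
            n_tetramers=n_tetramers,
            model=model,
            mislabel_rate=float(eps),
            disorder_rate=0.0,
            seed=seed + i,
        )
        _, truth = sample_tetramers(config)
        observed = float((truth.emitted_states == ACTIVATED).mean())
        p_true = truth.true_active_fraction
        expected = expected_observed_fraction(model.p, float(eps))
        rows.append(
            {
                "mislabel_rate": float(eps),
                "p_model": model.p,
                "p_true_sampled": p_true,
                "observed_fraction": observed,
                "expected_observed_fraction": expected,
                "bias_vs_model_p": observed - model.p,
                "expected_bias": expected - model.p,
            }
        )
    return pd.DataFrame(rows)
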