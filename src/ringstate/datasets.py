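"""Published rTRPM3 composition-count fixtures and their replication report.

Four symmetry-expanded cryo-EM datasets of the rat TRPM3 channel are
shipped as per-class intact-tetramer particle counts (transcribed from
the published processing of each dataset; see the CSV headers under
``ringstate/data``):

====================  =====================================  ===========
key                   condition                              tetramers
====================  =====================================  ===========
``cim_18C``           CIM0216 superagonist, 18 °C              1,381,027
``apo_18C``           apo, 18 °C                               2,191,867
``apo_37C``           apo, 37 °C (heat)                          477,026
``primidone_18C``     primidone antagonist, 18 °C              1,271,284
====================  =====================================  ===========

:func:`replicate_all` recomputes every headline composition statistic of
that study from these counts alone — subunit activated fractions,
tetramer occupancy tails, the heat-induced fold change — compares each
against the value printed in the study at integer-percent granularity,
and flags the two published figures (27% for the ≥3-activated tail at
37 °C; 30% activated subunits with primidone) whose table-derived values
(26.2% and 29.5%) round to a different integer.  Those two discrepancies
are surfaced, not suppressed: they presumably reflect a different
rounding pipeline or slightly different particle sets upstream of the
published tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .composition import (
    CompositionSpectrum,
    equilibrium,
    EquilibriumSummary,
    fold_change,
    vant_hoff,
)
from .errors import ConfigError
from .io import ConditionMeta, read_spectrum

#: Fixture registry: key -> (data file, condition metadata).
FIXTURES: dict[str, tuple[str, ConditionMeta]] = {
    "cim_18C": (
        "cim0216_18c.csv",
        ConditionMeta("CIM0216, 18C", temperature_c=18.0, ligand="CIM0216"),
    ),
    "apo_18C": ("apo_18c.csv", ConditionMeta("Apo, 18C", temperature_c=18.0)),
    "apo_37C": ("apo_37c.csv", ConditionMeta("Apo, 37C", temperature_c=37.0)),
    "primidone_18C": (
        "primidone_18c.csv",
        ConditionMeta("Primidone, 18C", temperature_c=18.0, ligand="primidone"),
    ),
}


def load_fixture(condition: str) -> CompositionSpectrum:
    """Load one of the published count fixtures as a spectrum."""
    key = condition.strip()
    if key not in FIXTURES:
        raise ConfigError(
            f"unknown fixture {condition!r}; available: {sorted(FIXTURES)}"
        )
    filename, meta = FIXTURES[key]
    with resources.as_file(
        resources.files("ringstate.data").joinpath(filename)
    ) as path:
        return read_spectrum(path, n=4, condition=meta)


def round_percent(fraction: float) -> int:
    """Round a fraction to the nearest integer percent, half away from zero."""
    return int(math.floor(100.0 * fraction + 0.5))


@dataclass(frozen=True)
class ReplicationEntry:
    """One recomputed statistic paired with the study's printed value."""

    key: str
    description: str
    value: float  # raw (fraction or ratio)
    display: float  # on the printed scale (percent, or fold)
    printed: float | None  # value printed in the study, same scale
    matches: bool | None  # at integer granularity; None when nothing printed
    note: str = ""


@dataclass
class ReplicationReport:
    """All recomputed composition statistics with match flags."""

    entries: list[ReplicationEntry]
    equilibria: dict[str, EquilibriumSummary]
    dH_vant_hoff_kJ_mol: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])

    def to_dict(self) -> dict:
        return {
            "entries": [vars(e) for e in self.entries],
            "equilibria": {k: vars(v) for k, v in self.equilibria.items()},
            "dH_vant_hoff_kJ_mol": self.dH_vant_hoff_kJ_mol,
        }

    @property
    def all_targeted_match(self) -> bool:
        """True iff every statistic with a printed counterpart that is
        expected to match (note-free) does match."""
        return all(e.matches for e in self.entries if e.matches is not None and not e.note)

    @property
    def mismatches(self) -> list[ReplicationEntry]:
        return [e for e in self.entries if e.matches is False]


def _percent_entry(
    key: str,
    description: str,
    fraction: float,
    printed: float | None,
    note: str = "",
) -> ReplicationEntry:
    display = 100.0 * fraction
    matches = None if printed is None else (round_percent(fraction) == printed)
    return ReplicationEntry(key, description, fraction, display, printed, matches, note)


def replicate_all() -> ReplicationReport:
    """Recompute every headline composition statistic from the fixtures.

    Pure integer/rational arithmetic on the shipped counts; runs in well
    under a second and is identical across platforms.
    """
    spectra = {key: load_fixture(key) for key in FIXTURES}
    cim, apo18, apo37, prim = (
        spectra["cim_18C"],
        spectra["apo_18C"],
        spectra["apo_37C"],
        spectra["primidone_18C"],
    )
    entries = [
        _percent_entry(
            "cim_18C_subunit_active",
            "activated subunit fraction, CIM0216 18C",
            cim.active_fraction(),
            80,
        ),
        _percent_entry(
            "cim_18C_subunit_resting",
            "resting subunit fraction, CIM0216 18C",
            1.0 - cim.active_fraction(),
            20,
        ),
        _percent_entry(
            "apo_18C_subunit_resting",
            "resting subunit fraction, apo 18C",
            1.0 - apo18.active_fraction(),
            84,
        ),
        _percent_entry(
            "apo_18C_subunit_active",
            "activated subunit fraction, apo 18C (primidone baseline)",
            apo18.active_fraction(),
            16,
        ),
        _percent_entry(
            "apo_37C_subunit_active",
            "activated subunit fraction, apo 37C",
            apo37.active_fraction(),
            40,
        ),
        _percent_entry(
            "apo_18C_occ3",
            "tetramers with >=3 activated subunits, apo 18C",
            apo18.occupancy_at_least(3),
            2,
        ),
        _percent_entry(
            "cim_18C_occ3",
            "tetramers with >=3 activated subunits, CIM0216 18C",
            cim.occupancy_at_least(3),
            83,
        ),
        _percent_entry(
            "apo_37C_occ3",
            "tetramers with >=3 activated subunits, apo 37C",
            apo37.occupancy_at_least(3),
            27,
            note=(
                "table-derived value is 26.2%, which rounds to 26, not the "
                "printed 27; deliberate mismatch, surfaced rather than matched"
            ),
        ),
        _percent_entry(
            "primidone_18C_subunit_active",
            "activated subunit fraction, primidone 18C",
            prim.active_fraction(),
            30,
            note=(
                "table-derived value is 29.5%, which rounds to 29, not the "
                "printed 30; deliberate mismatch, surfaced rather than matched"
            ),
        ),
    ]
    fold = fold_change(apo37, apo18, statistic="occ3")
    entries.append(
        ReplicationEntry(
            key="heat_fold_change_occ3",
            description="fold increase of >=3-activated tetramer fraction, 18C -> 37C",
            value=fold,
            display=fold,
            printed=14,
            matches=int(math.floor(fold + 0.5)) == 14,
        )
    )
    prim_fold = fold_change(prim, apo18, statistic="p_active")
    entries.append(
        ReplicationEntry(
            key="primidone_fold_change_p_active",
            description="fold increase of activated subunit fraction, apo -> primidone (18C)",
            value=prim_fold,
            display=prim_fold,
            printed=None,
            matches=None,
        )
    )
    equilibria = {
        key: equilibrium(spec.active_fraction(), spec.condition.temperature_c)
        for key, spec in spectra.items()
    }
    dH = vant_hoff(
        apo18.active_fraction(), 18.0, apo37.active_fraction(), 37.0
    )
    return ReplicationReport(
        entries=entries, equilibria=equilibria, dH_vant_hoff_kJ_mol=dH
    )
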