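"""Per-subunit particle tables: reading, writing, trace-back, intactness.

The observable layer of a symmetry-expanded focused classification is a
table with one row per subunit particle: the parent tetramer identifier,
the subunit position on the ring, and a hard state assignment (R resting,
A activated, D disordered/broken), optionally with a classification
posterior and a condition tag.  Two dialects are supported:

* TSV — UTF-8, tab-separated, header row with columns
  ``tetramer_id  subunit_index  state`` (``condition`` and ``posterior``
  optional);
* STAR — a single data block with one ``loop_`` whose tags are the TSV
  column names prefixed with an underscore (``_tetramer_id`` ...), parsed
  and written with gemmi so the files interoperate with cryo-EM tooling.

``assemble_tetramers`` performs the trace-back from subunit rows to
per-tetramer state vectors; ``filter_intact`` applies the exclusion rule
that discards any tetramer with a missing or disordered subunit before it
can enter composition statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from gemmi import cif

from .errors import AmbiguityError, FormatError, InvalidLabelError
from .ring import DISORDERED, THREE_STATE

REQUIRED_COLUMNS = ("tetramer_id", "subunit_index", "state")
OPTIONAL_COLUMNS = ("condition", "posterior")


@dataclass(frozen=True)
class SubunitRecord:
    """One classified subunit particle.

    ``subunit_index`` is 0-based and must be < ring size; ``posterior``,
    when present, is the classification confidence in [0, 1].
    """

    tetramer_id: str
    subunit_index: int
    state: str
    condition: str | None = None
    posterior: float | None = None


@dataclass(frozen=True)
class ConditionMeta:
    """Experimental condition attached to a dataset (sidecar metadata)."""

    condition: str
    temperature_c: float
    ligand: str | None = None
    ligand_conc: float | None = None
    conc_unit: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature_c):
            raise FormatError(f"temperature must be finite, got {self.temperature_c}")


@dataclass(frozen=True)
class TetramerAssignment:
    """A tetramer's per-subunit state vector after trace-back.

    ``states`` holds one label per ring position; a position whose subunit
    record was absent is ``None``.  The tetramer is *intact* iff all
    positions are present and none is disordered — only intact tetramers
    enter composition statistics.
    """

    tetramer_id: str
    states: tuple[str | None, ...]
    condition: str | None = None

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def complete(self) -> bool:
        return all(s is not None for s in self.states)

    @property
    def intact(self) -> bool:
        return self.complete and DISORDERED not in self.states

    @property
    def arrangement(self) -> tuple[str, ...]:
        if not self.complete:
            raise FormatError(
                f"tetramer {self.tetramer_id!r} is incomplete; no arrangement"
            )
        return tuple(s for s in self.states if s is not None)


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "star"):
            raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'star'")
        return dialect
    return "star" if path.suffix.lower() == ".star" else "tsv"


def _records_from_frame(
    df: pd.DataFrame,
    alphabet: Sequence[str],
    condition: str | None,
    source: str,
    first_data_line: int,
) -> list[SubunitRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing required column(s) {missing}")
    records: list[SubunitRecord] = []
    has_cond = "condition" in df.columns
    has_post = "posterior" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        line = first_data_line + i
        state = str(getattr(row, "state"))
        if state not in alphabet:
            raise InvalidLabelError(
                f"{source}, line {line}: state {state!r} not in alphabet "
                f"{tuple(alphabet)!r}"
            )
        try:
            idx = int(getattr(row, "subunit_index"))
        except (TypeError, ValueError):
            raise FormatError(
                f"{source}, line {line}: subunit_index "
                f"{getattr(row, 'subunit_index')!r} is not an integer"
            ) from None
        if idx < 0:
            raise FormatError(f"{source}, line {line}: subunit_index {idx} < 0")
        post = None
        if has_post:
            raw = getattr(row, "posterior")
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                post = float(raw)
                if not 0.0 <= post <= 1.0:
                    raise FormatError(
                        f"{source}, line {line}: posterior {post} outside [0, 1]"
                    )
        cond = condition
        if has_cond:
            raw_cond = getattr(row, "condition")
            if raw_cond is not None and not (
                isinstance(raw_cond, float) and math.isnan(raw_cond)
            ):
                cond = str(raw_cond)
        records.append(
            SubunitRecord(
                tetramer_id=str(getattr(row, "tetramer_id")),
                subunit_index=idx,
                state=state,
                condition=cond,
                posterior=post,
            )
        )
    return records


def read_particle_table(
    path: str | Path,
    dialect: str | None = None,
    alphabet: Sequence[str] = THREE_STATE,
    condition: str | None = None,
) -> list[SubunitRecord]:
    """Read a per-subunit particle table (TSV or STAR).

    Every row is validated: labels must belong to ``alphabet`` and
    ``subunit_index`` must be a non-negative integer; violations raise
    with the offending line number.  ``condition`` supplies a file-level
    tag used when the table has no condition column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"tetramer_id": str, "state": str})
        return _records_from_frame(df, alphabet, condition, str(path), 2)
    doc = cif.read(str(path))
    block = doc.sole_block()
    cols: dict[str, list[str]] = {}
    for name in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        loop = block.find_loop(f"_{name}")
        values = list(loop)
        if values:
            cols[name] = [cif.as_string(v) for v in values]
    missing = [c for c in REQUIRED_COLUMNS if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing required STAR tag(s) _{'_, _'.join(missing)}")
    length = len(cols["tetramer_id"])
    if any(len(v) != length for v in cols.values()):
        raise FormatError(f"{path}: ragged loop_ (unequal column lengths)")
    df = pd.DataFrame(cols)
    if "posterior" in df.columns:
        df["posterior"] = df["posterior"].replace({"": None, ".": None}).astype(float)
    return _records_from_frame(df, alphabet, condition, str(path), 1)


def write_particle_table(
    records: Iterable[SubunitRecord],
    path: str | Path,
    dialect: str | None = None,
) -> None:
    """Write records in TSV or STAR dialect (round-trips losslessly)."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    records = list(records)
    with_cond = any(r.condition is not None for r in records)
    with_post = any(r.posterior is not None for r in records)
    columns = list(REQUIRED_COLUMNS)
    if with_cond:
        columns.append("condition")
    if with_post:
        columns.append("posterior")

    def cell(r: SubunitRecord, c: str) -> str:
        v = getattr(r, {"posterior": "posterior"}.get(c, c))
        if v is None:
            return ""
        if c == "posterior":
            return format(float(v), ".6g")
        return str(v)

    if dialect == "tsv":
        lines = ["\t".join(columns)]
        lines += ["\t".join(cell(r, c) for c in columns) for r in records]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    doc = cif.Document()
    block = doc.add_new_block("particles")
    loop = block.init_loop("_", columns)
    for r in records:
        loop.add_row(
            [cif.quote(cell(r, c)) if cell(r, c) else "." for c in columns]
        )
    doc.write_file(str(path))


def apply_posterior_threshold(
    records: Iterable[SubunitRecord], posterior_min: float
) -> list[SubunitRecord]:
    """Demote low-confidence assignments to disordered.

    Records whose posterior is present and below ``posterior_min`` have
    their state replaced by D; records without a posterior pass through
    (the hard assignment is trusted when no confidence was recorded).
    """
    if not 0.0 <= posterior_min <= 1.0:
        raise FormatError(f"posterior_min {posterior_min} outside [0, 1]")
    out = []
    for r in records:
        if r.posterior is not None and r.posterior < posterior_min:
            r = SubunitRecord(
                r.tetramer_id, r.subunit_index, DISORDERED, r.condition, r.posterior
            )
        out.append(r)
    return out


def assemble_tetramers(
    records: Iterable[SubunitRecord],
    n: int = 4,
    posterior_min: float | None = None,
) -> list[TetramerAssignment]:
    """Trace subunit records back to their parent tetramers.

    Returns one assignment per distinct ``tetramer_id``, in order of first
    appearance, with states ordered by subunit index.  Tetramers with
    fewer than ``n`` subunit records are flagged non-intact; duplicate
    (tetramer_id, subunit_index) slots raise an :class:`AmbiguityError`
    naming the tetramer, and subunit indices ``>= n`` are rejected rather
    than re-mapped.
    """
    if posterior_min is not None:
        records = apply_posterior_threshold(records, posterior_min)
    slots: dict[str, list[str | None]] = {}
    conditions: dict[str, str | None] = {}
    for r in records:
        if r.subunit_index >= n:
            raise FormatError(
                f"tetramer {r.tetramer_id!r}: subunit_index {r.subunit_index} "
                f">= ring size {n}"
            )
        states = slots.setdefault(r.tetramer_id, [None] * n)
        if states[r.subunit_index] is not None:
            raise AmbiguityError(
                f"duplicate subunit record for tetramer {r.tetramer_id!r}, "
                f"position {r.subunit_index}"
            )
        states[r.subunit_index] = r.state
        conditions.setdefault(r.tetramer_id, r.condition)
    return [
        TetramerAssignment(tid, tuple(states), conditions[tid])
        for tid, states in slots.items()
    ]


def flatten_tetramers(
    assignments: Iterable[TetramerAssignment],
) -> list[SubunitRecord]:
    """Inverse of :func:`assemble_tetramers` for complete assignments."""
    out = []
    for t in assignments:
        for i, s in enumerate(t.states):
            if s is not None:
                out.append(SubunitRecord(t.tetramer_id, i, s, t.condition))
    return out


def filter_intact(
    assignments: Iterable[TetramerAssignment],
) -> tuple[list[TetramerAssignment], list[TetramerAssignment]]:
    """Split assignments into (intact, excluded).

    A tetramer is excluded if any subunit is missing or disordered — the
    exclusion rule applied before any composition statistic.  Every input
    appears in exactly one of the two lists.
    """
    intact: list[TetramerAssignment] = []
    excluded: list[TetramerAssignment] = []
    for t in assignments:
        (intact if t.intact else excluded).append(t)
    return intact, excluded


def write_spectrum(spectrum, path: str | Path) -> None:
    """Write a composition spectrum as CSV (class_name, count, fraction).

    Fractions sum to 1 within 1e-9 for non-empty spectra; an empty
    spectrum produces a header-only file.
    """
    path = Path(path)
    df = spectrum.to_frame()
    if spectrum.total == 0:
        df = df.iloc[0:0]
    try:
        df.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise FormatError(f"could not write spectrum to {path}: {exc}") from exc


def read_spectrum(path: str | Path, n: int = 4, condition=None):
    """Read a spectrum CSV written by :func:`write_spectrum`.

    Only ``class_name`` and ``count`` are used; the fraction column, if
    present, is recomputed rather than trusted.
    """
    from .composition import spectrum_from_counts

    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("class_name", "count") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    counts = {str(r.class_name): int(r.count) for r in df.itertuples(index=False)}
    return spectrum_from_counts(counts, condition=condition, n=n)
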