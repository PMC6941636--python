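"""Long-format counting-process event histories and covariate schemas.

The package's canonical data layout is the Andersen–Gill counting-process
table: one row per at-risk interval per event type per subject, with columns
``subject_id, event_type, start, stop, status``.  Event type ``"1"`` denotes
local recurrence, ``"2"`` metastatic recurrence, and ``"D"`` the optional
terminal event (death).  Intervals are half-open ``(start, stop]`` on a
calendar time axis measured in months since surgery; an event occurs at
``stop`` when ``status == 1``.

Covariates are fixed (one row per subject) and declared in a
:class:`CovariateSchema` that fixes the categorical levels, the reference
level of each variable, and which variables enter each linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

LOCAL = "1"
METASTASIS = "2"
TERMINAL = "D"
RECURRENT_TYPES = (LOCAL, METASTASIS)
EVENT_TYPES = (LOCAL, METASTASIS, TERMINAL)

EVENT_COLUMNS = ["subject_id", "event_type", "start", "stop", "status"]


class SchemaError(ValueError):
    """A file or table does not match the declared schema."""


class EventHistoryParseError(ValueError):
    """A CSV cell could not be parsed; the message names the row."""


class ValidationError(ValueError):
    """An event history violates the counting-process invariants."""


@dataclass(frozen=True)
class Covariate:
    """One covariate: categorical (levels + reference) or numeric (levels None)."""

    name: str
    levels: tuple[str, ...] | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.levels is not None:
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"covariate {self.name!r}: duplicate levels")
            if self.reference is None:
                object.__setattr__(self, "reference", self.levels[0])
            if self.reference not in self.levels:
                raise SchemaError(
                    f"covariate {self.name!r}: reference {self.reference!r} "
                    f"not among levels {self.levels}"
                )

    @property
    def is_categorical(self) -> bool:
        return self.levels is not None

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        if not self.is_categorical:
            return ()
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class CovariateSchema:
    """Declared covariate dictionary plus the design of each linear predictor.

    ``design_1`` / ``design_2`` / ``design_d`` name the covariates entering
    the local-recurrence, metastasis, and terminal-event hazards (the two
    recurrence designs may select different columns).
    """

    covariates: tuple[Covariate, ...]
    design_1: tuple[str, ...] = ()
    design_2: tuple[str, ...] = ()
    design_d: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate covariate names in schema")
        for design in (self.design_1, self.design_2, self.design_d):
            for name in design:
                if name not in names:
                    raise SchemaError(f"design references unknown covariate {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def design_for(self, event_type: str) -> tuple[str, ...]:
        return {LOCAL: self.design_1, METASTASIS: self.design_2,
                TERMINAL: self.design_d}[event_type]

    def design_columns(self, names: tuple[str, ...] | None = None) -> list[tuple[str, str | None]]:
        """Expanded (covariate, level) dummy columns, reference levels omitted."""
        if names is None:
            names = self.names
        cols: list[tuple[str, str | None]] = []
        for name in names:
            cov = self[name]
            if cov.is_categorical:
                cols.extend((name, lvl) for lvl in cov.nonreference_levels)
            else:
                cols.append((name, None))
        return cols

    def design_matrix(self, covariates: pd.DataFrame,
                      names: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
        """Reference-level dummy encoding of ``names`` for every subject row."""
        cols = self.design_columns(tuple(names))
        labels: list[str] = []
        arrays: list[np.ndarray] = []
        for name, level in cols:
            if level is None:
                arrays.append(covariates[name].to_numpy(dtype=float))
                labels.append(name)
            else:
                arrays.append((covariates[name].to_numpy() == level).astype(float))
                labels.append(f"{name}[{level}]")
        if not arrays:
            return np.empty((len(covariates), 0)), []
        return np.column_stack(arrays), labels

    def to_dict(self) -> dict:
        return {
            "covariates": [
                {"name": c.name, "levels": list(c.levels) if c.levels else None,
                 "reference": c.reference}
                for c in self.covariates
            ],
            "design_1": list(self.design_1),
            "design_2": list(self.design_2),
            "design_d": list(self.design_d),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSchema":
        covs = tuple(
            Covariate(
                name=c["name"],
                levels=tuple(c["levels"]) if c.get("levels") else None,
                reference=c.get("reference"),
            )
            for c in d["covariates"]
        )
        return cls(
            covariates=covs,
            design_1=tuple(d.get("design_1", ())),
            design_2=tuple(d.get("design_2", ())),
            design_d=tuple(d.get("design_d", ())),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CovariateSchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class Violation:
    """One counting-process rule violation, locating subject/type/rule."""

    subject_id: str
    event_type: str | None
    rule: str
    detail: str = ""

    def __str__(self) -> str:
        loc = f"subject {self.subject_id}"
        if self.event_type is not None:
            loc += f", type {self.event_type}"
        msg = f"{loc}: {self.rule}"
        return f"{msg} ({self.detail})" if self.detail else msg


@dataclass
class EventHistory:
    """A validated cohort: counting-process records plus per-subject covariates.

    ``events`` has columns ``subject_id, event_type, start, stop, status``
    sorted by (subject_id, event_type, start); ``covariates`` has one row per
    subject with ``subject_id`` plus the schema's columns, sorted by
    subject_id.
    """

    events: pd.DataFrame
    covariates: pd.DataFrame
    schema: CovariateSchema
    time_unit: str = "months"

    def __post_init__(self) -> None:
        self.events = _normalize_events(self.events)
        self.covariates = _normalize_covariates(self.covariates, self.schema)

    @property
    def subjects(self) -> list[str]:
        return list(self.covariates["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def records_for(self, subject_id: str) -> pd.DataFrame:
        return self.events[self.events["subject_id"] == subject_id]

    def modeled_types(self) -> tuple[str, ...]:
        present = set(self.events["event_type"])
        return tuple(t for t in EVENT_TYPES if t in present)

    def design_matrix(self, event_type: str) -> tuple[np.ndarray, list[str]]:
        names = self.schema.design_for(event_type)
        return self.schema.design_matrix(self.covariates, names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventHistory):
            return NotImplemented
        return (
            self.time_unit == other.time_unit
            and self.schema == other.schema
            and self.events.reset_index(drop=True).equals(other.events.reset_index(drop=True))
            and self.covariates.reset_index(drop=True).equals(
                other.covariates.reset_index(drop=True))
        )


def _normalize_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"events table missing column(s): {', '.join(missing)}")
    ev = events.loc[:, EVENT_COLUMNS].copy()
    ev["subject_id"] = ev["subject_id"].astype(str)
    ev["event_type"] = ev["event_type"].astype(str)
    for col in ("start", "stop"):
        ev[col] = _parse_time_column(ev[col], col)
    ev["status"] = _parse_status_column(ev["status"])
    ev = ev.sort_values(["subject_id", "event_type", "start"], kind="mergesort")
    return ev.reset_index(drop=True)


def _normalize_covariates(cov: pd.DataFrame, schema: CovariateSchema) -> pd.DataFrame:
    if "subject_id" not in cov.columns:
        raise SchemaError("covariates table missing column(s): subject_id")
    missing = [n for n in schema.names if n not in cov.columns]
    if missing:
        raise SchemaError(f"covariates table missing column(s): {', '.join(missing)}")
    out = cov.loc[:, ["subject_id", *schema.names]].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    for name in schema.names:
        covariate = schema[name]
        if covariate.is_categorical:
            out[name] = out[name].astype(str)
        else:
            out[name] = _parse_time_column(out[name], name)
    out = out.sort_values("subject_id", kind="mergesort")
    return out.reset_index(drop=True)


def _parse_time_column(col: pd.Series, name: str) -> pd.Series:
    parsed = pd.to_numeric(col, errors="coerce")
    bad = parsed.isna() & col.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise EventHistoryParseError(
            f"column {name!r}: unparseable value {col.iloc[row]!r} at row {row}")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise EventHistoryParseError(f"column {name!r}: missing value at row {row}")
    return parsed.astype(float)


def _parse_status_column(col: pd.Series) -> pd.Series:
    parsed = pd.to_numeric(col, errors="coerce")
    if parsed.isna().any() or not parsed.isin([0, 1]).all():
        bad = ~parsed.isin([0, 1]) | parsed.isna()
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise EventHistoryParseError(
            f"column 'status': value {col.iloc[row]!r} at row {row} is not 0/1")
    return parsed.astype(int)


def validate_counting_process(history: EventHistory) -> list[Violation]:
    """Check every counting-process invariant; return violations, never raise.

    Rules checked per (subject, event type): strictly increasing half-open
    intervals with ``start < stop``; no overlap; at most one terminal record
    per subject; no recurrent interval extending past the subject's terminal
    or final censoring stop; every subject present in the covariate table
    (and vice versa); no unknown event types or categorical levels.
    """
    v: list[Violation] = []
    ev = history.events
    cov = history.covariates

    ev_subjects = set(ev["subject_id"])
    cov_subjects = set(cov["subject_id"])
    for s in sorted(ev_subjects - cov_subjects):
        v.append(Violation(s, None, "missing covariate row"))
    for s in sorted(cov_subjects - ev_subjects):
        v.append(Violation(s, None, "subject has no event records"))
    if cov["subject_id"].duplicated().any():
        for s in sorted(set(cov.loc[cov["subject_id"].duplicated(), "subject_id"])):
            v.append(Violation(s, None, "duplicate covariate row"))

    for name in history.schema.names:
        covariate = history.schema[name]
        if covariate.is_categorical:
            bad = ~cov[name].isin(covariate.levels)
            for s in cov.loc[bad, "subject_id"]:
                v.append(Violation(str(s), None, "unknown covariate level",
                                   f"{name}={cov.loc[cov['subject_id'] == s, name].iloc[0]!r}"))

    unknown = ~ev["event_type"].isin(EVENT_TYPES)
    for _, row in ev.loc[unknown].iterrows():
        v.append(Violation(row["subject_id"], row["event_type"], "unknown event type"))

    for (subj, etype), grp in ev.loc[~unknown].groupby(["subject_id", "event_type"], sort=True):
        starts = grp["start"].to_numpy()
        stops = grp["stop"].to_numpy()
        if (starts < 0).any():
            v.append(Violation(subj, etype, "start < 0"))
        bad_len = starts >= stops
        if bad_len.any():
            i = int(np.flatnonzero(bad_len)[0])
            v.append(Violation(subj, etype, "start < stop violated",
                               f"interval ({starts[i]}, {stops[i]}]"))
        if len(grp) > 1:
            if (starts[1:] < stops[:-1]).any():
                v.append(Violation(subj, etype, "overlapping intervals"))
        if etype == TERMINAL and len(grp) > 1:
            v.append(Violation(subj, etype, "multiple terminal records"))

    # recurrent intervals must not extend past the subject's final stop
    final_stop = ev.groupby("subject_id")["stop"].max()
    term = ev[ev["event_type"] == TERMINAL]
    term_stop = dict(zip(term["subject_id"], term["stop"]))
    for subj, stop in term_stop.items():
        rec = ev[(ev["subject_id"] == subj) & (ev["event_type"] != TERMINAL)]
        if len(rec) and (rec["stop"] > stop + 1e-12).any():
            v.append(Violation(subj, None, "recurrent interval extends past terminal stop"))
    del final_stop
    return v


def read_event_history(events_path, covariates_path,
                       schema: CovariateSchema) -> EventHistory:
    """Read and validate a cohort from the two-CSV on-disk layout.

    Raises :class:`SchemaError` for missing columns,
    :class:`EventHistoryParseError` for unparseable cells (naming the row),
    and :class:`ValidationError` when the counting-process invariants fail.
    """
    events = pd.read_csv(events_path, dtype={"subject_id": str, "event_type": str},
                         float_precision="round_trip")
    covariates = pd.read_csv(covariates_path, dtype={"subject_id": str},
                             float_precision="round_trip")
    history = EventHistory(events=events, covariates=covariates, schema=schema)
    violations = validate_counting_process(history)
    if violations:
        lines = "\n".join(f"  - {viol}" for viol in violations)
        raise ValidationError(f"invalid event history:\n{lines}")
    return history


def write_event_history(history: EventHistory, events_path, covariates_path) -> None:
    """Write the two-CSV layout with deterministic row and column order.

    ``read_event_history(write_event_history(h)) == h`` and a second
    write of the re-read object is byte-identical to the first.
    """
    history.events.to_csv(events_path, index=False, float_format="%.17g")
    history.covariates.to_csv(covariates_path, index=False, float_format="%.17g")
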