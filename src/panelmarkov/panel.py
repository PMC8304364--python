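"""Panel-data model: observation sequences, EPDS classification, descriptives.

A panel dataset is a long-format table with one row per subject-visit
(subject id, time in weeks postpartum, severity state 1-3 or raw EPDS score,
optional covariate columns). Transitions between visits are unobserved; the
likelihood layer consumes only the per-subject (state, time) sequences plus
time-fixed covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import DEFAULT_STATES, N_STATES, StateSpace, TransitionTable

__all__ = [
    "DEFAULT_EPDS_THRESHOLDS",
    "Observation",
    "SubjectSeries",
    "PanelDataset",
    "ChangeSummary",
    "classify_epds",
    "read_panel",
    "write_panel",
    "observed_transition_table",
    "summarize_changes",
]

#: Default EPDS cutpoints: <10 normal, 10-12 mild, >=13 severe.
DEFAULT_EPDS_THRESHOLDS = (10, 13)

EPDS_MIN, EPDS_MAX = 0, 30


def classify_epds(score: int, thresholds: tuple[int, int] = DEFAULT_EPDS_THRESHOLDS) -> int:
    """Map an EPDS total score to a severity state (1, 2 or 3).

    With the default cutpoints, scores below 10 are state 1 (normal), 10-12
    state 2 (mild) and 13 or above state 3 (severe).
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError(f"thresholds must be increasing, got {thresholds}")
    if not (EPDS_MIN <= score <= EPDS_MAX):
        raise ValueError(f"EPDS score must be in [{EPDS_MIN}, {EPDS_MAX}], got {score}")
    if score < lo:
        return 1
    if score < hi:
        return 2
    return 3


@dataclass(frozen=True)
class Observation:
    """One subject-visit row."""

    subject_id: str
    time: float
    state: int | None = None
    epds: int | None = None
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be non-negative, got {self.time}")
        if self.state is None and self.epds is None:
            raise ValueError(f"subject {self.subject_id}: need a state or an EPDS score")
        if self.state is not None and self.state not in (1, 2, 3):
            raise ValueError(f"subject {self.subject_id}: state must be 1, 2 or 3, got {self.state}")
        if self.epds is not None and not (EPDS_MIN <= self.epds <= EPDS_MAX):
            raise ValueError(f"subject {self.subject_id}: EPDS out of range: {self.epds}")

    def resolved_state(self, thresholds: tuple[int, int] = DEFAULT_EPDS_THRESHOLDS) -> int:
        if self.state is not None:
            return self.state
        return classify_epds(self.epds, thresholds)


@dataclass(frozen=True)
class SubjectSeries:
    """Time-ordered observation sequence for one subject."""

    subject_id: str
    times: np.ndarray
    states: np.ndarray  # 1-based
    covariates: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return max(len(self.times) - 1, 0)


class PanelDataset:
    """Validated collection of subject series, sorted by subject and time."""

    def __init__(
        self,
        observations: Sequence[Observation],
        thresholds: tuple[int, int] = DEFAULT_EPDS_THRESHOLDS,
        states: StateSpace = DEFAULT_STATES,
    ) -> None:
        self.states = states
        self.thresholds = thresholds
        by_subject: dict[str, list[Observation]] = {}
        for obs in observations:
            by_subject.setdefault(str(obs.subject_id), []).append(obs)
        series = []
        for sid in sorted(by_subject):
            rows = sorted(by_subject[sid], key=lambda o: o.time)
            times = np.array([o.time for o in rows], dtype=float)
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"subject {sid}: visit times must be strictly increasing "
                                 f"(duplicate or out-of-order times {times.tolist()})")
            covs: dict[str, float] = {}
            for o in rows:
                covs.update(o.covariates)
            series.append(
                SubjectSeries(
                    subject_id=sid,
                    times=times,
                    states=np.array([o.resolved_state(thresholds) for o in rows], dtype=int),
                    covariates=covs,
                )
            )
        self._series = series
        names: set[str] = set()
        for s in series:
            names.update(s.covariates)
        self.covariate_names = tuple(sorted(names))

    def __len__(self) -> int:
        return len(self._series)

    def __iter__(self) -> Iterator[SubjectSeries]:
        return iter(self._series)

    @property
    def subjects(self) -> tuple[SubjectSeries, ...]:
        return tuple(self._series)

    @property
    def n_observations(self) -> int:
        return sum(len(s.times) for s in self._series)

    @property
    def n_pairs(self) -> int:
        return sum(s.n_pairs for s in self._series)

    @property
    def singletons(self) -> tuple[str, ...]:
        """Subjects with a single visit; retained but contribute no pairs."""
        return tuple(s.subject_id for s in self._series if len(s.times) < 2)

    def pairs(self) -> Iterator[tuple[SubjectSeries, int, int, float]]:
        """Yield (series, from_state, to_state, dt) for consecutive visits."""
        for s in self._series:
            for k in range(s.n_pairs):
                yield s, int(s.states[k]), int(s.states[k + 1]), float(s.times[k + 1] - s.times[k])

    def covariate_means(self, names: Sequence[str]) -> np.ndarray:
        out = []
        for name in names:
            vals = [s.covariates[name] for s in self._series if name in s.covariates]
            if not vals:
                raise KeyError(f"covariate {name!r} not present in dataset")
            out.append(float(np.mean(vals)))
        return np.array(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self._series:
            for t, st in zip(s.times, s.states):
                row = {"subject": s.subject_id, "time": t, "state": int(st)}
                row.update(s.covariates)
                rows.append(row)
        return pd.DataFrame(rows)


_DEFAULT_COLUMNS = {"subject": "subject", "time": "time", "state": "state", "epds": "epds"}


def read_panel(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    covariates: Sequence[str] | None = None,
    thresholds: tuple[int, int] = DEFAULT_EPDS_THRESHOLDS,
) -> PanelDataset:
    """Read a long-format panel CSV into a :class:`PanelDataset`.

    ``columns`` remaps the logical names (subject, time, state, epds) onto
    the file's header. A state column takes precedence; otherwise raw EPDS
    scores are classified with ``thresholds``. ``covariates`` selects extra
    numeric columns (default: every unmapped column).
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    for logical in ("subject", "time"):
        if colmap[logical] not in df.columns:
            raise ValueError(f"required column {colmap[logical]!r} ({logical}) missing from {path}")
    has_state = colmap["state"] in df.columns
    has_epds = colmap["epds"] in df.columns
    if not has_state and not has_epds:
        raise ValueError(f"need a {colmap['state']!r} or {colmap['epds']!r} column in {path}")

    dup = df.duplicated(subset=[colmap["subject"], colmap["time"]], keep=False)
    if dup.any():
        offenders = df.loc[dup, [colmap["subject"], colmap["time"]]].drop_duplicates()
        raise ValueError(
            "duplicate (subject, time) rows: "
            + "; ".join(f"{r[0]} @ {r[1]}" for r in offenders.itertuples(index=False))
        )
    if has_state:
        bad = ~df[colmap["state"]].isin((1, 2, 3))
        if bad.any():
            codes = sorted(df.loc[bad, colmap["state"]].unique().tolist())
            raise ValueError(f"unknown state codes {codes}; expected 1, 2 or 3")

    if covariates is None:
        mapped = {colmap[k] for k in colmap}
        covariates = [c for c in df.columns if c not in mapped]
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariate column(s) not found: {', '.join(missing)}")

    observations = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        observations.append(
            Observation(
                subject_id=str(rec[colmap["subject"]]),
                time=float(rec[colmap["time"]]),
                state=int(rec[colmap["state"]]) if has_state else None,
                epds=int(rec[colmap["epds"]]) if (has_epds and not has_state) else None,
                covariates={c: float(rec[c]) for c in covariates if pd.notna(rec[c])},
            )
        )
    return PanelDataset(observations, thresholds=thresholds)


def write_panel(data: PanelDataset, path: str | Path) -> None:
    """Write a panel dataset as a long-format CSV (RFC-4180, header row)."""
    data.to_frame().to_csv(path, index=False)


def observed_transition_table(data: PanelDataset) -> TransitionTable:
    """Count consecutive-visit transitions; entry (i, j) = pairs i -> j."""
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    for _, frm, to, _dt in data.pairs():
        counts[frm - 1, to - 1] += 1
    return TransitionTable(counts, kind="counts", states=data.states)


@dataclass(frozen=True)
class ChangeSummary:
    """Deterioration / improvement / no-change split of transition pairs."""

    n_transitions: int
    n_worse: int
    n_better: int
    n_same: int

    def __post_init__(self) -> None:
        if self.n_worse + self.n_better + self.n_same != self.n_transitions:
            raise ValueError("change counts must add up to the total")

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_transitions if self.n_transitions else 0.0

    @property
    def pct_worse(self) -> float:
        return self._pct(self.n_worse)

    @property
    def pct_better(self) -> float:
        return self._pct(self.n_better)

    @property
    def pct_same(self) -> float:
        return self._pct(self.n_same)

    def to_text(self) -> str:
        return (
            f"transitions: {self.n_transitions}\n"
            f"  deteriorated: {self.n_worse} ({self.pct_worse:.1f}%)\n"
            f"  improved:     {self.n_better} ({self.pct_better:.1f}%)\n"
            f"  unchanged:    {self.n_same} ({self.pct_same:.1f}%)"
        )


def summarize_changes(counts: TransitionTable) -> ChangeSummary:
    """Split a count table into worse / better / same by severity order.

    Severity follows the state index order (normal < mild < severe), so
    above-diagonal cells are deteriorations and below-diagonal improvements.
    """
    if counts.kind != "counts":
        raise ValueError("change summary requires a count table")
    v = counts.values
    worse = int(np.triu(v, 1).sum())
    better = int(np.tril(v, -1).sum())
    same = int(np.trace(v))
    return ChangeSummary(
        n_transitions=worse + better + same, n_worse=worse, n_better=better, n_same=same
    )
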