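"""Panel-data container: per-subject visit times, observed states and
covariates — the data object of the interval-censored likelihood."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import DEFAULT_STATES, StateSpace


@dataclass
class SubjectRecord:
    """One subject's observation sequence.

    times are years from study entry, strictly increasing; state_idx are
    indices into the state space; covariates is the subject's (time-constant)
    covariate vector.
    """

    subject_id: str
    times: np.ndarray
    state_idx: np.ndarray
    covariates: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.state_idx = np.asarray(self.state_idx, dtype=int)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.times.shape != self.state_idx.shape:
            raise ValueError(f"subject {self.subject_id}: times/states length mismatch")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"subject {self.subject_id}: times must be strictly increasing")


@dataclass
class PanelDataset:
    """Collection of subject records plus covariate names and state space.

    Invariant: within each subject, once the absorbing state is observed
    every later observation is the absorbing state (checked on build).
    """

    subjects: list
    covariate_names: tuple = ()
    states: StateSpace = field(default_factory=lambda: DEFAULT_STATES)
    #: optional per-subject group label (e.g. diagnostic group at entry)
    groups: dict = field(default_factory=dict)
    #: true generating parameters, populated by the synthetic generator
    truth: dict | None = None

    def __post_init__(self) -> None:
        p = len(self.covariate_names)
        absorbing_idx = {self.states.index(a) for a in self.states.absorbing}
        for s in self.subjects:
            if s.covariates.shape != (p,):
                raise ValueError(
                    f"subject {s.subject_id}: covariate length {s.covariates.size}, expected {p}"
                )
            if np.any(s.state_idx < 0) or np.any(s.state_idx >= self.states.n_states):
                raise ValueError(f"subject {s.subject_id}: invalid state index")
            seen_absorbing = False
            for st in s.state_idx:
                if seen_absorbing and st not in absorbing_idx:
                    raise ValueError(
                        f"subject {s.subject_id}: observation after the absorbing "
                        "state is not absorbing"
                    )
                seen_absorbing = seen_absorbing or st in absorbing_idx

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per visit, columns subject_id, time_years,
        state, then one column per covariate."""
        rows = []
        for s in self.subjects:
            for t, st in zip(s.times, s.state_idx):
                row = {"subject_id": s.subject_id, "time_years": t,
                       "state": self.states.names[st]}
                row.update(dict(zip(self.covariate_names, s.covariates)))
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariate_names=None,
                       states: StateSpace | None = None) -> "PanelDataset":
        states = states or DEFAULT_STATES
        required = {"subject_id", "time_years", "state"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel data missing required columns: {sorted(missing)}")
        if covariate_names is None:
            covariate_names = tuple(c for c in df.columns if c not in required)
        bad = ~df["state"].isin(states.names)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"row {df.index[i]}: unknown state {df['state'].iloc[i]!r}; "
                f"expected one of {states.names}"
            )
        subjects = []
        for sid, g in df.groupby("subject_id", sort=False):
            g = g.sort_values("time_years")
            cov = g.iloc[0][list(covariate_names)].to_numpy(dtype=float) \
                if covariate_names else np.zeros(0)
            subjects.append(SubjectRecord(
                subject_id=str(sid),
                times=g["time_years"].to_numpy(dtype=float),
                state_idx=np.array([states.index(s) for s in g["state"]]),
                covariates=cov,
            ))
        return cls(subjects=subjects, covariate_names=tuple(covariate_names), states=states)

    def transition_counts(self) -> np.ndarray:
        """Counts of observed consecutive-visit state pairs (m x m)."""
        m = self.states.n_states
        counts = np.zeros((m, m), dtype=int)
        for s in self.subjects:
            np.add.at(counts, (s.state_idx[:-1], s.state_idx[1:]), 1)
        return counts

    def total_followup(self) -> float:
        """Total observed follow-up time in subject-years."""
        return float(sum(s.times[-1] - s.times[0] for s in self.subjects if len(s.times) > 1))
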