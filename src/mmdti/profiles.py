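"""Container for AFQ-style tract profiles.

Automated fiber quantification resamples each white-matter tract to a fixed
number of nodes (default 100) and reports a diffusion metric per node.  A
`TractProfileSet` holds, per subject and tract, the fractional-anisotropy
(FA) and mean-diffusivity (MD) node arrays together with a tracking-success
flag and the subject's group, age and sex.  MD is carried in units of
1e-3 mm^2/s so typical values are O(1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METRICS = ("FA", "MD")

#: the 20-tract AFQ set
AFQ_TRACTS = (
    "Left Thalamic Radiation", "Right Thalamic Radiation",
    "Left Corticospinal", "Right Corticospinal",
    "Left Cingulum Cingulate", "Right Cingulum Cingulate",
    "Left Cingulum Hippocampus", "Right Cingulum Hippocampus",
    "Callosum Forceps Major", "Callosum Forceps Minor",
    "Left IFOF", "Right IFOF",
    "Left SLF", "Right SLF",
    "Left ILF", "Right ILF",
    "Left Uncinate", "Right Uncinate",
    "Left Arcuate", "Right Arcuate",
)


@dataclass
class TractProfileSet:
    """subjects × tracts × nodes × {FA, MD} with tracking flags.

    Attributes
    ----------
    subject_ids : list of str
    tracts : tuple of str
    fa, md : ndarray, shape (n_subjects, n_tracts, n_nodes)
    tracked : ndarray of bool, shape (n_subjects, n_tracts)
    group : ndarray of str, per subject
    age : ndarray of float, per subject
    sex : ndarray of int, per subject (1 = male, 0 = female)
    """

    subject_ids: list
    tracts: tuple
    fa: np.ndarray
    md: np.ndarray
    tracked: np.ndarray
    group: np.ndarray
    age: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        n, t = len(self.subject_ids), len(self.tracts)
        if self.fa.shape[:2] != (n, t) or self.md.shape != self.fa.shape:
            raise ValueError("fa/md shapes inconsistent with subjects × tracts")
        if self.tracked.shape != (n, t):
            raise ValueError("tracked flag shape must be subjects × tracts")
        if np.any((self.fa <= 0) | (self.fa >= 1)):
            raise ValueError("FA values must lie strictly in (0, 1)")
        if np.any(self.md <= 0):
            raise ValueError("MD values must be positive")

    @property
    def n_nodes(self) -> int:
        return self.fa.shape[2]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def tract_index(self, tract: str) -> int:
        try:
            return self.tracts.index(tract)
        except ValueError:
            raise KeyError(f"unknown tract {tract!r}") from None

    def metric_array(self, metric: str) -> np.ndarray:
        if metric not in METRICS:
            raise KeyError(f"metric must be one of {METRICS}, got {metric!r}")
        return self.fa if metric == "FA" else self.md

    def failure_counts(self) -> pd.Series:
        """Per-tract count of subjects whose tract could not be tracked."""
        return pd.Series((~self.tracked).sum(axis=0), index=list(self.tracts),
                         name="n_failures")

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long format: subject_id, tract, metric, node (0-based), value, tracked."""
        n, t, k = self.fa.shape
        frames = []
        for metric in METRICS:
            arr = self.metric_array(metric)
            df = pd.DataFrame({
                "subject_id": np.repeat(self.subject_ids, t * k),
                "tract": np.tile(np.repeat(self.tracts, k), n),
                "metric": metric,
                "node": np.tile(np.arange(k), n * t),
                "value": arr.reshape(-1),
                "tracked": np.repeat(self.tracked.astype(int).reshape(-1), k),
            })
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long_dataframe(cls, df: pd.DataFrame, group=None, age=None,
                            sex=None) -> "TractProfileSet":
        """Rebuild from the long format; subject metadata passed as dicts
        keyed by subject_id (defaults: empty group, NaN age, 0 sex)."""
        required = {"subject_id", "tract", "metric", "node", "value", "tracked"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"profile data missing columns: {sorted(missing)}")
        subject_ids = list(pd.unique(df["subject_id"]))
        tracts = tuple(pd.unique(df["tract"]))
        nodes = np.sort(pd.unique(df["node"]))
        k = len(nodes)
        sid_ix = {s: i for i, s in enumerate(subject_ids)}
        tr_ix = {t: i for i, t in enumerate(tracts)}
        shape = (len(subject_ids), len(tracts), k)
        fa = np.full(shape, np.nan)
        md = np.full(shape, np.nan)
        tracked = np.ones(shape[:2], dtype=bool)
        i_s = df["subject_id"].map(sid_ix).to_numpy()
        i_t = df["tract"].map(tr_ix).to_numpy()
        i_n = df["node"].to_numpy(dtype=int)
        vals = df["value"].to_numpy(dtype=float)
        is_fa = (df["metric"] == "FA").to_numpy()
        fa[i_s[is_fa], i_t[is_fa], i_n[is_fa]] = vals[is_fa]
        md[i_s[~is_fa], i_t[~is_fa], i_n[~is_fa]] = vals[~is_fa]
        trk = df["tracked"].to_numpy(dtype=int)
        tracked[i_s, i_t] = trk.astype(bool)
        if np.isnan(fa).any() or np.isnan(md).any():
            raise ValueError("profile data incomplete: some subject/tract/node "
                             "cells missing")
        g = np.array([(group or {}).get(s, "") for s in subject_ids])
        a = np.array([(age or {}).get(s, np.nan) for s in subject_ids], dtype=float)
        x = np.array([(sex or {}).get(s, 0) for s in subject_ids], dtype=int)
        return cls(subject_ids, tracts, fa, md, tracked, g, a, x)
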