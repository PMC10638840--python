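"""Seeded synthetic-cohort generators.

Two generators drive all testing without any external data:

* :func:`generate_cohort` — longitudinal panel observations drawn from a
  known continuous-time Markov process on NC/aMCI/AD with
  covariate-proportional intensities; the true generating parameters are
  stored on the dataset so parameter-recovery tests can compare against
  them.
* :func:`generate_tract_profiles` — AFQ-style 20-tract × 100-node FA/MD
  profiles with group-dependent mean curves (FA losses concentrated in
  cingulum/uncinate tracts, MD elevations in the IFOF and forceps minor)
  plus per-tract tracking-failure indicators.

Default cohort structure mirrors a three-group memory-clinic sample:
34 aMCI, 47 AD and 39 NC subjects (120 total), ages ~69 ± 8, roughly
balanced sex, MMSE separated by group.  Visits default to 4 per subject at
i.i.d. Uniform(0.75, 1.25)-year gaps (annual follow-up with scheduling
jitter).  Identical config + seed reproduces identical output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markov import RateMatrixModel, _validate_rate_matrix
from .panel import PanelDataset, SubjectRecord
from .profiles import AFQ_TRACTS, METRICS, TractProfileSet
from .states import AD, AMCI, DEFAULT_STATES, DEFAULT_STRUCTURE, NC

# ----------------------------------------------------------------- cohort

DEFAULT_GROUP_SIZES = {AMCI: 34, AD: 47, NC: 39}

#: baseline transition rates per year for the generating process; the
#: aMCI→AD value sits in the commonly cited 10–20%/yr MCI-conversion band
DEFAULT_TRUE_RATES = {(NC, AMCI): 0.08, (AMCI, NC): 0.05, (AMCI, AD): 0.15}

DEFAULT_COVARIATE_SPEC = {
    "age": {"dist": "normal",
            "mean": {AMCI: 69.5, AD: 69.7, NC: 68.5},
            "sd": {AMCI: 8.8, AD: 9.3, NC: 7.1}},
    "sex_male": {"dist": "bernoulli",
                 "p": {AMCI: 13 / 34, AD: 20 / 47, NC: 18 / 39}},
    "mmse": {"dist": "normal",
             "mean": {AMCI: 26.6, AD: 16.1, NC: 28.5},
             "sd": {AMCI: 2.5, AD: 7.3, NC: 1.4}},
}


@dataclass
class CohortConfig:
    """Configuration of the synthetic longitudinal cohort.

    Coefficients in `true_betas` apply to covariates on the scale they are
    drawn on; the defaults are zero (covariates carried but inert).
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    true_rates: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_RATES))
    true_betas: dict = field(default_factory=dict)
    covariate_spec: dict = field(default_factory=lambda: {
        k: {kk: (dict(vv) if isinstance(vv, dict) else vv) for kk, vv in v.items()}
        for k, v in DEFAULT_COVARIATE_SPEC.items()})
    n_visits: int = 4
    visit_gap: tuple = (0.75, 1.25)  # Uniform(lo, hi) years between visits
    visit_missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must be nonempty")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group size for {g} must be >= 0")
            if g not in DEFAULT_STATES.names:
                raise ValueError(f"unknown group {g!r}")
        for pair, r in self.true_rates.items():
            if r < 0:
                raise ValueError(f"rate for {pair} must be >= 0")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        lo, hi = self.visit_gap
        if lo <= 0 or hi < lo:
            raise ValueError("visit_gap must satisfy 0 < lo <= hi")
        if not 0 <= self.visit_missing_prob < 1:
            raise ValueError("visit_missing_prob must be in [0, 1)")

    @property
    def covariate_names(self) -> tuple:
        return tuple(self.covariate_spec)


def simulate_ctmc_path(rate_matrix: np.ndarray, initial_state: int, t_max: float,
                       rng: np.random.Generator) -> list:
    """Forward-simulate one CTMC trajectory by the Gillespie algorithm.

    Returns the jump-time path as a list of ``(time, state_index)`` pairs
    starting at ``(0.0, initial_state)``.  Holding time in each state is
    exponential with rate equal to the total exit rate; a state with zero
    exit rate (absorbing) ends the path.
    """
    Q = _validate_rate_matrix(rate_matrix)
    if t_max < 0:
        raise ValueError(f"t_max must be nonnegative, got {t_max}")
    m = Q.shape[0]
    if not 0 <= initial_state < m:
        raise ValueError(f"initial_state {initial_state} out of range for {m} states")
    t, state = 0.0, int(initial_state)
    path = [(0.0, state)]
    while True:
        exit_rate = -Q[state, state]
        if exit_rate <= 0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t > t_max:
            break
        probs = Q[state].clip(min=0.0)
        probs[state] = 0.0
        state = int(rng.choice(m, p=probs / probs.sum()))
        path.append((t, state))
    return path


def sample_panel(path: list, obs_times: np.ndarray) -> list:
    """Interval-censor a jump-time path: the state at each visit time.

    Exact transition instants are discarded — only the visit-time states
    survive, which is what the panel likelihood sees.
    """
    obs_times = np.asarray(obs_times, dtype=float)
    if np.any(np.diff(obs_times) < 0):
        raise ValueError("obs_times must be sorted")
    if np.any(obs_times < 0):
        raise ValueError("obs_times must be nonnegative")
    jump_times = np.array([t for t, _ in path])
    states = np.array([s for _, s in path])
    idx = np.searchsorted(jump_times, obs_times, side="right") - 1
    return [(float(t), int(states[i])) for t, i in zip(obs_times, idx)]


def _draw_covariate(spec: dict, group: str, rng: np.random.Generator) -> float:
    def per_group(v):
        return v[group] if isinstance(v, dict) else v

    dist = spec.get("dist", "normal")
    if dist == "normal":
        return float(rng.normal(per_group(spec["mean"]), per_group(spec["sd"])))
    if dist == "bernoulli":
        return float(rng.random() < per_group(spec["p"]))
    if dist == "uniform":
        return float(rng.uniform(per_group(spec["low"]), per_group(spec["high"])))
    raise ValueError(f"unknown covariate distribution {dist!r}")


def generate_cohort(config: CohortConfig) -> PanelDataset:
    """Simulate the full panel cohort under the configured Markov process.

    Each subject starts in their diagnostic group's state at entry, follows
    a CTMC with intensity matrix Q(V) built from the true rates/betas and
    the subject's covariates, and is observed at their own visit schedule.
    The generating truth is attached as ``dataset.truth``.
    """
    rng = np.random.default_rng(config.seed)
    cov_names = config.covariate_names
    structure = DEFAULT_STRUCTURE
    rates = {p: config.true_rates.get(p, 0.0) for p in structure}
    betas = {p: np.asarray(config.true_betas.get(p, np.zeros(len(cov_names))), float)
             for p in structure}
    # RateMatrixModel requires strictly positive baselines; a configured
    # zero rate is honoured by zeroing the matrix entry afterwards.
    model = RateMatrixModel(structure, {p: max(r, 1e-300) for p, r in rates.items()},
                            betas, cov_names)
    zero_pairs = [p for p, r in rates.items() if r == 0.0]

    subjects, groups = [], {}
    counter = 0
    for group in config.group_sizes:  # insertion order: deterministic
        for _ in range(config.group_sizes[group]):
            sid = f"S{counter:04d}"
            counter += 1
            V = np.array([_draw_covariate(config.covariate_spec[c], group, rng)
                          for c in cov_names])
            Q = model.rate_matrix(V)
            for a, b in zero_pairs:
                ia, ib = structure.states.index(a), structure.states.index(b)
                Q[ia, ib] = 0.0
            Q[np.arange(3), np.arange(3)] = 0.0
            Q[np.arange(3), np.arange(3)] = -Q.sum(axis=1)
            gaps = rng.uniform(*config.visit_gap, size=config.n_visits - 1)
            times = np.concatenate([[0.0], np.cumsum(gaps)])
            if config.visit_missing_prob > 0 and len(times) > 1:
                keep = rng.random(len(times) - 1) >= config.visit_missing_prob
                times = np.concatenate([times[:1], times[1:][keep]])
            path = simulate_ctmc_path(Q, structure.states.index(group),
                                      float(times[-1]), rng)
            obs = sample_panel(path, times)
            subjects.append(SubjectRecord(
                subject_id=sid,
                times=np.array([t for t, _ in obs]),
                state_idx=np.array([s for _, s in obs]),
                covariates=V,
            ))
            groups[sid] = group
    return PanelDataset(
        subjects=subjects, covariate_names=cov_names, states=DEFAULT_STATES,
        groups=groups,
        truth={"rates": dict(rates), "betas": {p: b.copy() for p, b in betas.items()},
               "config": config},
    )


# ----------------------------------------------------------- tract profiles

DEFAULT_FA_EFFECT_TRACTS = ("Left Cingulum Cingulate", "Right Cingulum Cingulate",
                            "Right Uncinate")
DEFAULT_MD_EFFECT_TRACTS = ("Left IFOF", "Right IFOF", "Callosum Forceps Minor")

#: tracking-failure probabilities emulating the observed pattern: only the
#: cingulum hippocampus bundles are frequently untrackable
DEFAULT_TRACKING_FAILURE = {
    "Left Cingulum Hippocampus": 62 / 120,
    "Right Cingulum Hippocampus": 32 / 120,
}


@dataclass
class ProfileConfig:
    """Configuration of the synthetic tract-profile generator.

    Group mean curves are smooth functions of the along-tract coordinate
    x ∈ [0, 1]: FA is a parabola peaking mid-tract (crossing-fiber regions
    at tract ends depress FA), MD a shallow inverted parabola.  Group
    effects are additive shifts confined to `effect_window` nodes of the
    designated tracts, ordered NC > aMCI > AD in FA and NC < aMCI < AD
    in MD.  `extra_effects` lets tests inject arbitrary localized effects
    as ``(tract, metric, group, node_lo, node_hi, delta)`` tuples
    (inclusive 0-based node range).
    """

    tract_names: tuple = AFQ_TRACTS
    n_nodes: int = 100
    noise_sd: dict = field(default_factory=lambda: {"FA": 0.04, "MD": 0.04})
    fa_effect_tracts: tuple = DEFAULT_FA_EFFECT_TRACTS
    md_effect_tracts: tuple = DEFAULT_MD_EFFECT_TRACTS
    effect_window: tuple = (30, 70)  # inclusive 0-based node range
    fa_group_shift: dict = field(default_factory=lambda: {NC: 0.0, AMCI: -0.025, AD: -0.05})
    md_group_shift: dict = field(default_factory=lambda: {NC: 0.0, AMCI: 0.03, AD: 0.06})
    tracking_failure_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_TRACKING_FAILURE))
    extra_effects: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        for tract, p in self.tracking_failure_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"tracking failure prob for {tract} not in [0, 1]")
        for m, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise sd for {m} must be >= 0")

    def mean_curve(self, tract: str, metric: str, group: str) -> np.ndarray:
        """Group mean profile for one tract/metric, length n_nodes."""
        x = np.linspace(0.0, 1.0, self.n_nodes)
        if metric == "FA":
            base = 0.35 + 0.25 * 4 * x * (1 - x)
        elif metric == "MD":
            base = 0.80 + 0.10 * (1 - 4 * (x - 0.5) ** 2)  # 1e-3 mm^2/s
        else:
            raise KeyError(f"metric must be one of {METRICS}")
        curve = base.copy()
        lo, hi = self.effect_window
        win = slice(lo, hi + 1)
        if metric == "FA" and tract in self.fa_effect_tracts:
            curve[win] += self.fa_group_shift.get(group, 0.0)
        if metric == "MD" and tract in self.md_effect_tracts:
            curve[win] += self.md_group_shift.get(group, 0.0)
        for trk, met, grp, nlo, nhi, delta in self.extra_effects:
            if trk == tract and met == metric and grp == group:
                curve[nlo:nhi + 1] += delta
        return curve


def generate_tract_profiles(config: ProfileConfig, group_assignments: dict,
                            age=None, sex=None) -> TractProfileSet:
    """Draw per-subject tract profiles: group mean curve + i.i.d. Gaussian
    node noise, with FA clipped into (0, 1) and a per-tract tracked flag.

    Parameters
    ----------
    group_assignments : dict
        subject_id → group label; iteration order fixes subject order.
    age, sex : dict, optional
        subject_id → value; used by downstream covariate adjustment.
    """
    rng = np.random.default_rng(config.seed)
    groups = set(group_assignments.values())
    known = {NC, AMCI, AD}
    unknown = groups - known
    if unknown:
        raise ValueError(f"unknown groups in assignments: {sorted(unknown)}")
    subject_ids = list(group_assignments)
    n, t, k = len(subject_ids), len(config.tract_names), config.n_nodes
    fa = np.empty((n, t, k))
    md = np.empty((n, t, k))
    tracked = np.ones((n, t), dtype=bool)
    curves = {(tr, m, g): config.mean_curve(tr, m, g)
              for tr in config.tract_names for m in METRICS for g in groups}
    for i, sid in enumerate(subject_ids):
        g = group_assignments[sid]
        for j, tract in enumerate(config.tract_names):
            fa[i, j] = curves[(tract, "FA", g)] + rng.normal(0, config.noise_sd["FA"], k)
            md[i, j] = curves[(tract, "MD", g)] + rng.normal(0, config.noise_sd["MD"], k)
            pfail = config.tracking_failure_probs.get(tract, 0.0)
            if pfail > 0 and rng.random() < pfail:
                tracked[i, j] = False
    eps = 1e-6
    fa = np.clip(fa, eps, 1 - eps)
    md = np.clip(md, eps, None)
    return TractProfileSet(
        subject_ids=subject_ids, tracts=tuple(config.tract_names),
        fa=fa, md=md, tracked=tracked,
        group=np.array([group_assignments[s] for s in subject_ids]),
        age=np.array([(age or {}).get(s, np.nan) for s in subject_ids], dtype=float),
        sex=np.array([(sex or {}).get(s, 0) for s in subject_ids], dtype=int),
    )


def generate_summary_table(dataset: PanelDataset):
    """Per-group n, mean and sd of each continuous covariate plus M/F
    counts — the shape of a demographics table.

    Returns a dict ``{variable: {group: GroupSummary}}``; binary covariates
    named like sex are additionally summarized as counts under 'sex (M/F)'.
    """
    from .tractstats import GroupSummary  # deferred: avoid import cycle

    if not len(dataset):
        raise ValueError("dataset is empty")
    if not dataset.groups:
        raise ValueError("dataset carries no group labels")
    out: dict = {}
    group_order = list(dict.fromkeys(dataset.groups.values()))
    for ci, name in enumerate(dataset.covariate_names):
        is_binary = name.startswith("sex")
        per_group: dict = {}
        for g in group_order:
            vals = np.array([s.covariates[ci] for s in dataset.subjects
                             if dataset.groups[s.subject_id] == g])
            if is_binary:
                per_group[g] = (int(vals.sum()), int(len(vals) - vals.sum()))
            else:
                per_group[g] = GroupSummary(n=len(vals), mean=float(vals.mean()),
                                            sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        out["sex (M/F)" if is_binary else name] = per_group
    return out
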