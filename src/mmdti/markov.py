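"""Continuous-time Markov chain engine: rate matrices, transition
probabilities and the interval-censored panel log-likelihood.

The model is a time-homogeneous CTMC on the clinical states with
covariate-proportional transition intensities

    q_{ab}(V) = r0_{ab} * exp(beta_{ab} . V)

for each allowed transition a→b, where r0_{ab} > 0 is a baseline rate per
year and beta_{ab} is a vector of log-rate-ratio coefficients on the
subject's covariates V.  Transition probabilities over an interval of
length t are P(t) = expm(t Q(V)).  Panel data observe the state only at
visit times, so a subject's likelihood is the product of consecutive-visit
transition probabilities, conditioning on the first observed state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .states import DEFAULT_STRUCTURE, TransitionStructure

#: transition probabilities below this are clipped before log to avoid -inf
#: from round-off; true structural impossibilities are caught separately.
_PROB_FLOOR = 1e-300


@dataclass
class RateMatrixModel:
    """Parameterized transition-rate matrix Q(V).

    Parameters
    ----------
    structure : TransitionStructure
        Allowed transitions; disallowed off-diagonals of Q are structurally 0.
    baseline_rates : dict
        ``{(from_state, to_state): rate}`` in events per year, strictly
        positive, one entry per allowed transition.
    betas : dict
        ``{(from_state, to_state): array}`` covariate coefficients, one
        vector per allowed transition, all the same length.
    covariate_names : tuple of str
        Names matching the beta vectors' entries (empty for no covariates).
    """

    structure: TransitionStructure = field(default_factory=lambda: DEFAULT_STRUCTURE)
    baseline_rates: dict = field(default_factory=dict)
    betas: dict = field(default_factory=dict)
    covariate_names: tuple = ()

    def __post_init__(self) -> None:
        p = len(self.covariate_names)
        for pair in self.structure:
            if pair not in self.baseline_rates:
                raise ValueError(f"missing baseline rate for transition {pair}")
            if self.baseline_rates[pair] <= 0:
                raise ValueError(f"baseline rate for {pair} must be > 0")
            beta = np.asarray(self.betas.get(pair, np.zeros(p)), dtype=float)
            if beta.shape != (p,):
                raise ValueError(
                    f"beta for {pair} has length {beta.size}, expected {p}"
                )
            self.betas[pair] = beta

    def intensity(self, frm: str, to: str, V=None) -> float:
        """Transition intensity r0 * exp(beta . V) for one allowed transition.

        Raises
        ------
        KeyError
            If (frm, to) is not an allowed transition — the rate is then a
            structural zero, not an evaluable quantity.
        """
        if (frm, to) not in self.structure:
            raise KeyError(f"transition {frm}->{to} is not in the structure")
        V = np.zeros(len(self.covariate_names)) if V is None else np.asarray(V, float)
        if V.shape != (len(self.covariate_names),):
            raise ValueError("covariate vector length mismatch")
        return float(self.baseline_rates[(frm, to)] * np.exp(self.betas[(frm, to)] @ V))

    def rate_matrix(self, V=None) -> np.ndarray:
        """Materialize Q(V): off-diagonals from `intensity`, rows sum to 0."""
        m = self.structure.states.n_states
        Q = np.zeros((m, m))
        ix = self.structure.states.index
        for frm, to in self.structure:
            Q[ix(frm), ix(to)] = self.intensity(frm, to, V)
        np.fill_diagonal(Q, 0.0)
        Q[np.arange(m), np.arange(m)] = -Q.sum(axis=1)
        return Q


def transition_intensity(frm: str, to: str, V, model: RateMatrixModel) -> float:
    """Functional alias for :meth:`RateMatrixModel.intensity`."""
    return model.intensity(frm, to, V)


def build_rate_matrix(V, model: RateMatrixModel,
                      structure: TransitionStructure | None = None) -> np.ndarray:
    """Materialize the rate matrix Q(V) for covariates V."""
    if structure is not None and structure is not model.structure:
        model = RateMatrixModel(structure, model.baseline_rates, model.betas,
                                model.covariate_names)
    return model.rate_matrix(V)


def _validate_rate_matrix(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError(f"rate matrix must be square, got shape {Q.shape}")
    off = Q[~np.eye(Q.shape[0], dtype=bool)]
    if np.any(off < -1e-12):
        raise ValueError("rate matrix off-diagonals must be nonnegative")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-8 * (1 + np.abs(Q).max())):
        raise ValueError("rate matrix rows must sum to zero")
    return Q


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition probability matrix P(t) = expm(t*Q).

    Rows sum to 1; entries are clipped into [0, 1] to absorb round-off at
    the 1e-12 level.
    """
    Q = _validate_rate_matrix(Q)
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    P = expm(t * Q)
    return np.clip(P, 0.0, 1.0)


def transition_probability_many(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """P(t) for an array of interval lengths, shape (len(ts), m, m).

    Uses one eigendecomposition of Q and propagates all intervals at once;
    falls back to per-interval scaling-and-squaring when the eigenbasis is
    ill-conditioned (near-defective Q).
    """
    Q = _validate_rate_matrix(Q)
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise ValueError("times must be nonnegative")
    try:
        lam, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        cond = np.linalg.cond(U)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        E = np.exp(np.multiply.outer(ts, lam))  # (n, m)
        P = np.einsum("ij,nj,jk->nik", U, E, Uinv)
        P = np.real(P)
    else:
        P = np.stack([expm(t * Q) for t in ts])
    return np.clip(P, 0.0, 1.0)


def _reachable(structure: TransitionStructure) -> np.ndarray:
    """Boolean matrix: can state a reach state b through allowed transitions."""
    m = structure.states.n_states
    adj = np.eye(m, dtype=bool)
    for a, b in structure.index_pairs():
        adj[a, b] = True
    reach = adj.copy()
    for _ in range(m):
        reach = reach | (reach @ adj)
    return reach


def panel_log_likelihood(data, model: RateMatrixModel) -> float:
    """Interval-censored panel log-likelihood.

    Sum over subjects j and visits i ≥ 2 of
    ``log P_{T_{j,i-1}, T_{j,i}}(s_{j,i} - s_{j,i-1})`` under the subject's
    Q(V_j).  The first-visit term is 1 (the likelihood conditions on the
    first observed state).  An observed transition that is structurally
    impossible yields -inf with a warning flagging the data/structure
    conflict.

    Parameters
    ----------
    data : PanelDataset
    model : RateMatrixModel
    """
    reach = _reachable(model.structure)
    total = 0.0
    for subj in data.subjects:
        states = subj.state_idx
        if len(states) < 2:
            continue
        frm, to = states[:-1], states[1:]
        if not reach[frm, to].all():
            bad = np.argmin(reach[frm, to])
            warnings.warn(
                f"subject {subj.subject_id}: observed transition "
                f"{data.states.names[frm[bad]]}->{data.states.names[to[bad]]} "
                "is impossible under the transition structure",
                stacklevel=2,
            )
            return -np.inf
        dts = np.diff(subj.times)
        P = transition_probability_many(model.rate_matrix(subj.covariates), dts)
        probs = P[np.arange(len(dts)), frm, to]
        total += float(np.log(np.clip(probs, _PROB_FLOOR, None)).sum())
    return total
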