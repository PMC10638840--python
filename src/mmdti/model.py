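"""Maximum-likelihood fitting of the multi-state progression model.

`MarkovPanelModel` is built from a :class:`~mmdti.panel.PanelDataset` (or a
long-format DataFrame) and a transition structure; ``fit()`` maximizes the
interval-censored panel likelihood over log baseline rates and covariate
coefficients and returns a :class:`MarkovResults` carrying estimates,
observed-information standard errors, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from statsmodels.iolib.table import SimpleTable
from statsmodels.tools.numdiff import approx_hess1

from .markov import (
    RateMatrixModel,
    _PROB_FLOOR,
    _reachable,
    transition_probability,
    transition_probability_many,
)
from .panel import PanelDataset
from .states import DEFAULT_STRUCTURE, TransitionStructure

#: floor for crude initial rates (events per year)
_RATE_FLOOR = 1e-3


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails; carries the last iterate."""

    def __init__(self, message: str, last_result=None):
        super().__init__(message)
        self.last_result = last_result


class MarkovPanelModel:
    """Continuous-time multi-state Markov model for interval-censored panel data.

    Parameters
    ----------
    data : PanelDataset
        Subject visit times, observed states and covariates.
    structure : TransitionStructure, optional
        Allowed transitions (default NC↔aMCI, aMCI→AD with AD absorbing).
    covariate_names : sequence of str, optional
        Subset of the dataset's covariates to enter the intensity model;
        default: all of them.

    Notes
    -----
    Internal parameterization is unconstrained: log baseline rates followed
    by raw covariate coefficients, ordered transition-major.  This keeps
    every rate positive without constrained optimization.
    """

    def __init__(self, data: PanelDataset, structure: TransitionStructure | None = None,
                 covariate_names=None):
        self.data = data
        self.structure = structure or DEFAULT_STRUCTURE
        if self.structure.states.names != data.states.names:
            raise ValueError("structure and data use different state spaces")
        if covariate_names is None:
            covariate_names = data.covariate_names
        self.covariate_names = tuple(covariate_names)
        unknown = set(self.covariate_names) - set(data.covariate_names)
        if unknown:
            raise ValueError(f"covariates not in dataset: {sorted(unknown)}")
        self._cov_cols = [data.covariate_names.index(c) for c in self.covariate_names]
        self._prepare()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariates=None,
                       structure: TransitionStructure | None = None) -> "MarkovPanelModel":
        data = PanelDataset.from_dataframe(df, covariate_names=covariates)
        return cls(data, structure=structure)

    # ------------------------------------------------------------------ setup

    def _prepare(self) -> None:
        """Flatten the panel into interval arrays grouped by covariate row."""
        dts, frms, tos, covs = [], [], [], []
        for s in self.data.subjects:
            if len(s.times) < 2:
                continue
            k = len(s.times) - 1
            dts.append(np.diff(s.times))
            frms.append(s.state_idx[:-1])
            tos.append(s.state_idx[1:])
            covs.append(np.tile(s.covariates[self._cov_cols], (k, 1)))
        if dts:
            self._dt = np.concatenate(dts)
            self._frm = np.concatenate(frms)
            self._to = np.concatenate(tos)
            cov = np.vstack(covs)
        else:
            self._dt = np.zeros(0)
            self._frm = np.zeros(0, int)
            self._to = np.zeros(0, int)
            cov = np.zeros((0, len(self.covariate_names)))
        # group intervals by unique covariate row: one eigendecomposition each
        if cov.shape[1]:
            uniq, inv = np.unique(cov, axis=0, return_inverse=True)
        else:
            uniq = np.zeros((1 if len(self._dt) else 0, 0))
            inv = np.zeros(len(self._dt), int)
        self._cov_rows = uniq
        self._cov_gid = inv
        # internal standardization of covariates: optimization runs on
        # z-scored covariates (well-conditioned), estimates are mapped back
        if cov.shape[1] and cov.shape[0]:
            self._cov_mean = cov.mean(axis=0)
            sd = cov.std(axis=0)
            self._cov_sd = np.where(sd > 0, sd, 1.0)
        else:
            self._cov_mean = np.zeros(cov.shape[1])
            self._cov_sd = np.ones(cov.shape[1])
        self._cov_rows_std = (uniq - self._cov_mean) / self._cov_sd \
            if uniq.size else uniq
        reach = _reachable(self.structure)
        self._structure_ok = bool(reach[self._frm, self._to].all()) if len(self._dt) else True
        self._pairs = self.structure.index_pairs()
        self._npairs = len(self._pairs)
        self._ncov = len(self.covariate_names)

    @property
    def param_names(self) -> list:
        names = [f"log_rate[{a}->{b}]" for a, b in self.structure]
        for a, b in self.structure:
            names += [f"beta[{a}->{b}].{c}" for c in self.covariate_names]
        return names

    @property
    def k_params(self) -> int:
        return self._npairs * (1 + self._ncov)

    def _unpack(self, params: np.ndarray) -> RateMatrixModel:
        params = np.asarray(params, float)
        log_r = params[: self._npairs]
        betas = params[self._npairs:].reshape(self._npairs, self._ncov)
        return RateMatrixModel(
            structure=self.structure,
            baseline_rates={p: float(np.exp(lr)) for p, lr in zip(self.structure, log_r)},
            betas={p: b.copy() for p, b in zip(self.structure, betas)},
            covariate_names=self.covariate_names,
        )

    # ------------------------------------------------------------- likelihood

    def loglike(self, params: np.ndarray) -> float:
        """Panel log-likelihood at the given parameter vector (log baseline
        rates then covariate coefficients, transition-major, raw scale)."""
        return self._loglike(params, self._cov_rows)

    def _loglike(self, params: np.ndarray, cov_rows: np.ndarray) -> float:
        if not self._structure_ok:
            return -np.inf
        if len(self._dt) == 0:
            return 0.0
        params = np.asarray(params, float)
        log_r = params[: self._npairs]
        betas = params[self._npairs:].reshape(self._npairs, self._ncov)
        m = self.structure.states.n_states
        total = 0.0
        for gid in range(len(cov_rows)):
            mask = self._cov_gid == gid
            V = cov_rows[gid]
            rates = np.exp(log_r + betas @ V)
            Q = np.zeros((m, m))
            for (a, b), r in zip(self._pairs, rates):
                Q[a, b] = r
            Q[np.arange(m), np.arange(m)] = -Q.sum(axis=1)
            P = transition_probability_many(Q, self._dt[mask])
            probs = P[np.arange(mask.sum()), self._frm[mask], self._to[mask]]
            total += float(np.log(np.clip(probs, _PROB_FLOOR, None)).sum())
        return total

    def start_params(self) -> np.ndarray:
        """Crude initialization: observed transition counts over total
        follow-up, floored at 1e-3/yr; coefficients start at zero."""
        counts = self.data.transition_counts()
        followup = max(self.data.total_followup(), 1e-12)
        log_r = np.empty(self._npairs)
        for i, (a, b) in enumerate(self._pairs):
            log_r[i] = np.log(max(counts[a, b] / followup, _RATE_FLOOR))
        return np.concatenate([log_r, np.zeros(self._npairs * self._ncov)])

    # ------------------------------------------------ scale transformations

    def _raw_to_std(self, params: np.ndarray) -> np.ndarray:
        params = np.asarray(params, float)
        log_r = params[: self._npairs].copy()
        betas = params[self._npairs:].reshape(self._npairs, self._ncov)
        log_r += betas @ self._cov_mean
        return np.concatenate([log_r, (betas * self._cov_sd).ravel()])

    def _std_to_raw_matrix(self) -> np.ndarray:
        """Linear map A with params_raw = A @ params_std."""
        k = self.k_params
        A = np.eye(k)
        for i in range(self._npairs):
            off = self._npairs + i * self._ncov
            for c in range(self._ncov):
                A[i, off + c] = -self._cov_mean[c] / self._cov_sd[c]
                A[off + c, off + c] = 1.0 / self._cov_sd[c]
        return A

    # -------------------------------------------------------------------- fit

    def fit(self, start_params=None, maxiter: int = 500, gtol: float = 1e-6,
            compute_se: bool = True) -> "MarkovResults":
        """Maximize the panel likelihood by quasi-Newton (BFGS).

        Convergence requires gradient norm < `gtol`; standard errors come
        from the inverse observed information (numerical Hessian of the
        negative log-likelihood at the optimum).  Deterministic given the
        data and starting values.
        """
        counts = self.data.transition_counts()
        for a, b in self.structure:
            ia, ib = self.structure.states.index(a), self.structure.states.index(b)
            if counts[ia, ib] == 0:
                warnings.warn(
                    f"transition {a}->{b} never observed between consecutive "
                    "visits; its rate may sit at the initialization floor",
                    stacklevel=2,
                )
        x0 = self.start_params() if start_params is None else np.asarray(start_params, float)
        if not np.isfinite(self.loglike(x0)):
            raise ValueError(
                "log-likelihood is -inf at the starting values: the data "
                "contain transitions impossible under the structure"
            )
        # optimize on the standardized-covariate scale (well-conditioned)
        neg = lambda p: -self._loglike(p, self._cov_rows_std)
        res = minimize(neg, self._raw_to_std(x0), method="BFGS",
                       options={"gtol": gtol, "maxiter": maxiter})
        grad_norm = float(np.max(np.abs(res.jac)))
        # finite-difference gradients bottom out near sqrt(eps)*scale; a
        # tiny residual gradient after a "precision loss" stop is converged
        converged = bool(res.success or grad_norm < 1e-3)
        if not converged:
            raise ConvergenceError(
                f"optimizer did not converge after {res.nit} iterations "
                f"(gradient norm {grad_norm:.2e})", last_result=res)
        A = self._std_to_raw_matrix()
        params = A @ res.x
        bse = np.full_like(params, np.nan)
        cov = None
        if compute_se:
            H = approx_hess1(res.x, neg)
            try:
                cov_std = np.linalg.inv(H)
                cov = A @ cov_std @ A.T
                d = np.diag(cov).copy()
                d[d < 0] = np.nan
                bse = np.sqrt(d)
            except np.linalg.LinAlgError:
                warnings.warn("observed information is singular; SEs unavailable",
                              stacklevel=2)
        return MarkovResults(self, params, bse, cov_params=cov,
                             llf=float(-res.fun), llf_start=float(self.loglike(x0)),
                             niter=int(res.nit), grad_norm=grad_norm,
                             converged=converged)


class MarkovResults:
    """Fit results: estimates, standard errors, diagnostics, predictions."""

    def __init__(self, model: MarkovPanelModel, params, bse, cov_params, llf,
                 llf_start, niter, grad_norm, converged):
        self.model = model
        self.params = np.asarray(params, float)
        self.bse = np.asarray(bse, float)
        self.cov_params = cov_params
        self.llf = llf
        self.llf_start = llf_start
        self.niter = niter
        self.grad_norm = grad_norm
        self.converged = converged

    @property
    def param_names(self) -> list:
        return self.model.param_names

    @property
    def rate_model(self) -> RateMatrixModel:
        """The fitted intensity model Q(V)."""
        return self.model._unpack(self.params)

    @property
    def rates(self) -> dict:
        """Fitted baseline rates per transition, events per year."""
        return self.rate_model.baseline_rates

    @property
    def betas(self) -> dict:
        return self.rate_model.betas

    def rate_matrix(self, V=None) -> np.ndarray:
        return self.rate_model.rate_matrix(V)

    def predict_onset(self, V=None, current_state: str = "NC",
                      horizon: float = 5.0) -> float:
        """Probability of being in the absorbing (AD) state after `horizon`
        years, starting from `current_state` with covariates V."""
        return predict_onset(self.rate_model, V, current_state, horizon)

    def summary(self) -> SimpleTable:
        """Estimation summary on the natural scale: rates with asymmetric
        log-normal CIs, coefficients with Wald CIs."""
        rows = []
        names = self.param_names
        for i, name in enumerate(names):
            est, se = self.params[i], self.bse[i]
            if name.startswith("log_rate"):
                rate = np.exp(est)
                lo, hi = np.exp(est - 1.96 * se), np.exp(est + 1.96 * se)
                rows.append([name.replace("log_rate", "rate"),
                             f"{rate:.4f}", f"{se:.4f}", f"{lo:.4f}", f"{hi:.4f}"])
            else:
                rows.append([name, f"{est:.4f}", f"{se:.4f}",
                             f"{est - 1.96 * se:.4f}", f"{est + 1.96 * se:.4f}"])
        title = (f"Multi-state Markov model  (n={self.model.data.n_subjects} subjects, "
                 f"loglik={self.llf:.3f}, iter={self.niter})")
        return SimpleTable(rows, headers=["parameter", "estimate", "se(log/raw)",
                                          "ci_low", "ci_high"], title=title)

    def to_dict(self) -> dict:
        """JSON-ready representation of the fit."""
        return {
            "states": list(self.model.structure.states.names),
            "transitions": [list(p) for p in self.model.structure],
            "covariates": list(self.model.covariate_names),
            "params": {n: float(v) for n, v in zip(self.param_names, self.params)},
            "bse": {n: float(v) for n, v in zip(self.param_names, self.bse)},
            "rates": {f"{a}->{b}": float(r) for (a, b), r in self.rates.items()},
            "loglik": self.llf,
            "convergence": {"converged": self.converged, "iterations": self.niter,
                            "grad_norm": self.grad_norm,
                            "loglik_start": self.llf_start},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def predict_onset(model: RateMatrixModel, V=None, current_state: str = "NC",
                  horizon: float = 5.0) -> float:
    """P(absorbing state at `horizon` | `current_state` now, covariates V).

    Computed as the (current_state, AD) entry of expm(horizon * Q(V));
    nondecreasing in the horizon because AD is absorbing.
    """
    if horizon < 0:
        raise ValueError(f"horizon must be nonnegative, got {horizon}")
    states = model.structure.states
    P = transition_probability(model.rate_matrix(V), horizon)
    return float(P[states.index(current_state), states.index(states.absorbing[0])])


def load_fit_json(path) -> RateMatrixModel:
    """Rebuild the fitted intensity model from a results JSON file."""
    with open(path) as fh:
        d = json.load(fh)
    from .states import StateSpace

    states = StateSpace(tuple(d["states"]), (d["states"][-1],))
    structure = TransitionStructure(tuple(tuple(p) for p in d["transitions"]), states)
    covs = tuple(d["covariates"])
    rates, betas = {}, {}
    for a, b in structure:
        rates[(a, b)] = d["rates"][f"{a}->{b}"]
        betas[(a, b)] = np.array([d["params"][f"beta[{a}->{b}].{c}"] for c in covs])
    return RateMatrixModel(structure, rates, betas, covs)
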