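"""Gaussian hidden Markov modelling of metric observation sequences.

A latent Markov chain with ``n`` states emits 4-dimensional observations
(one per frequency band) from state-specific multivariate Gaussians with
full covariance.  Parameters are estimated by multi-sequence Baum-Welch EM
(participants' sequences are independent realisations sharing one parameter
set), with restarts from random initialisations; decoding is Viterbi; the
per-participant summary is the dwell-time: the proportion of observations
spent in each state, overall and per EO/EC condition.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``score``, fitted attributes with a trailing underscore); the module-level
functions expose the individual algorithm stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

try:  # sklearn provides get_params/set_params and pipeline compatibility
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

from .network_metrics import ObservationSeries

__all__ = [
    "HMMParams",
    "StatePath",
    "DwellProfile",
    "zscore_observations",
    "init_model",
    "fit_em",
    "best_of_restarts",
    "viterbi",
    "dwell_times",
    "canonical_state_order",
    "permute_states",
    "state_sweep",
    "GaussianHMM",
    "NumericalFailure",
]

_SIMPLEX_TOL = 1e-9


class NumericalFailure(FloatingPointError):
    """Raised when likelihood evaluation or EM produces non-finite values."""


def _check_simplex(v: np.ndarray, what: str) -> None:
    if np.any(v < -_SIMPLEX_TOL) or abs(v.sum() - 1.0) > 1e-6:
        raise ValueError(f"{what} must lie on the probability simplex, got {v}")


@dataclass(frozen=True)
class HMMParams:
    """Gaussian HMM parameters: initial pi, means mu, covariances Sigma, transition P."""

    initial: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "initial", np.asarray(self.initial, float))
        object.__setattr__(self, "means", np.asarray(self.means, float))
        object.__setattr__(self, "covariances", np.asarray(self.covariances, float))
        object.__setattr__(self, "transition", np.asarray(self.transition, float))
        n, d = self.means.shape
        if self.initial.shape != (n,) or self.transition.shape != (n, n):
            raise ValueError("inconsistent parameter shapes")
        if self.covariances.shape != (n, d, d):
            raise ValueError("covariances must be n x d x d")
        _check_simplex(self.initial, "initial distribution")
        for i, row in enumerate(self.transition):
            _check_simplex(row, f"transition row {i}")
        for i, c in enumerate(self.covariances):
            if not np.allclose(c, c.T, atol=1e-8):
                raise ValueError(f"covariance {i} is not symmetric")

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class StatePath:
    """Decoded 0-based state sequence with its joint log-probability."""

    states: np.ndarray
    loglik: float

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class DwellProfile:
    """Per-state occupancy proportions, overall and per condition."""

    overall: np.ndarray
    by_condition: dict = field(default_factory=dict)


def _as_array(seq) -> np.ndarray:
    if isinstance(seq, ObservationSeries):
        return seq.values
    return np.asarray(seq, float)


def zscore_observations(series: ObservationSeries) -> ObservationSeries:
    """Standardise each observation dimension to mean 0, sample SD 1 (N-1)."""
    x = series.values
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(series.band_names[i] for i in bad)
        raise ValueError(f"zero-variance observation dimension(s): {names}")
    z = (x - x.mean(axis=0)) / sd
    return ObservationSeries(
        z, series.times, series.condition, series.metric, series.band_names
    )


def init_model(n: int, data: np.ndarray, seed: int = 0) -> HMMParams:
    """Random initialisation: means from random data rows, pooled covariance.

    Covariances start at the pooled data covariance plus diagonal jitter;
    the initial distribution and each transition row are flat-Dirichlet
    draws.  Deterministic given (data, seed).
    """
    data = np.asarray(data, float)
    if n < 2:
        raise ValueError("need at least 2 states")
    if data.shape[0] <= n:
        raise ValueError("need more data rows than states")
    rng = np.random.default_rng(seed)
    d = data.shape[1]
    rows = rng.choice(data.shape[0], size=n, replace=False)
    means = data[rows].copy()
    pooled = np.cov(data.T).reshape(d, d) + 1e-3 * np.eye(d)
    covs = np.repeat(pooled[None], n, axis=0)
    initial = rng.dirichlet(np.ones(n))
    transition = rng.dirichlet(np.ones(n), size=n)
    return HMMParams(initial, means, covs, transition)


def _log_emission(x: np.ndarray, params: HMMParams) -> np.ndarray:
    """T x n Gaussian log-densities."""
    T, d = x.shape
    out = np.empty((T, params.n_states))
    for s in range(params.n_states):
        try:
            cho = linalg.cho_factor(params.covariances[s], lower=True)
        except linalg.LinAlgError as exc:
            raise NumericalFailure(f"covariance of state {s} is not PD") from exc
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        diff = x - params.means[s]
        sol = linalg.cho_solve(cho, diff.T)
        maha = np.einsum("ij,ji->i", diff, sol)
        out[:, s] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    if not np.isfinite(out).all():
        raise NumericalFailure("non-finite emission log-density")
    return out


def _forward_backward(x: np.ndarray, params: HMMParams):
    """Scaled forward-backward: returns (loglik, gamma, xi_sum, gamma0)."""
    logb = _log_emission(x, params)
    c = logb.max(axis=1)
    B = np.exp(logb - c[:, None])
    T, n = B.shape
    P = params.transition
    alpha = np.empty((T, n))
    scale = np.empty(T)
    a = params.initial * B[0]
    scale[0] = a.sum()
    if scale[0] == 0:
        raise NumericalFailure("zero forward probability at t=0")
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ P) * B[t]
        scale[t] = a.sum()
        if scale[t] == 0:
            raise NumericalFailure(f"zero forward probability at t={t}")
        alpha[t] = a / scale[t]
    beta = np.empty((T, n))
    beta[-1] = 1.0
    xi_sum = np.zeros((n, n))
    for t in range(T - 2, -1, -1):
        w = B[t + 1] * beta[t + 1]
        beta[t] = (P @ w) / scale[t + 1]
        xi = (alpha[t][:, None] * P) * w[None, :] / scale[t + 1]
        xi_sum += xi
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(scale).sum() + c.sum())
    if not np.isfinite(loglik):
        raise NumericalFailure("non-finite log-likelihood")
    return loglik, gamma, xi_sum, gamma[0]


def fit_em(
    params: HMMParams,
    sequences,
    tol: float = 0.005,
    max_iter: int = 500,
    covariance_floor: float = 1e-6,
) -> tuple[HMMParams, np.ndarray]:
    """Multi-sequence Baum-Welch EM with per-step scaling.

    Sequences are independent realisations sharing one parameter set.
    Iterates until the absolute change in total log-likelihood falls below
    ``tol`` (default 0.005) or ``max_iter`` is reached; returns the fitted
    parameters and the (non-decreasing) log-likelihood trace.
    """
    xs = [_as_array(s) for s in sequences]
    if not xs:
        raise ValueError("need at least one sequence")
    n, d = params.n_states, params.n_dims
    trace: list[float] = []
    for _ in range(max_iter):
        ll_total = 0.0
        g_sum = np.zeros(n)
        gx_sum = np.zeros((n, d))
        xi_tot = np.zeros((n, n))
        g0_sum = np.zeros(n)
        gammas = []
        for x in xs:
            ll, gamma, xi_sum, g0 = _forward_backward(x, params)
            ll_total += ll
            g_sum += gamma.sum(axis=0)
            gx_sum += gamma.T @ x
            xi_tot += xi_sum
            g0_sum += g0
            gammas.append(gamma)
        trace.append(ll_total)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
        # M-step
        initial = g0_sum / g0_sum.sum()
        rows = xi_tot.sum(axis=1, keepdims=True)
        transition = np.where(rows > 0, xi_tot / np.where(rows == 0, 1, rows), 1.0 / n)
        means = gx_sum / np.where(g_sum == 0, 1, g_sum)[:, None]
        covs = np.empty((n, d, d))
        for s in range(n):
            acc = np.zeros((d, d))
            for x, gamma in zip(xs, gammas):
                diff = x - means[s]
                acc += (gamma[:, s][:, None] * diff).T @ diff
            denom = g_sum[s] if g_sum[s] > 0 else 1.0
            cov = acc / denom
            cov = (cov + cov.T) / 2.0 + covariance_floor * np.eye(d)
            # guard against collapse onto a subspace
            jitter = covariance_floor
            while np.linalg.eigvalsh(cov).min() <= 0:
                jitter *= 10.0
                cov += jitter * np.eye(d)
                warnings.warn(
                    f"covariance of state {s} collapsed; regularised with "
                    f"diagonal jitter {jitter:g}",
                    RuntimeWarning,
                    stacklevel=2,
                )
            covs[s] = cov
        params = HMMParams(initial, means, covs, transition)
    return params, np.asarray(trace)


def loglik(params: HMMParams, sequences) -> float:
    """Total log-likelihood of independent sequences under the model."""
    return float(sum(_forward_backward(_as_array(s), params)[0] for s in sequences))


def best_of_restarts(
    n: int,
    sequences,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 0.005,
    max_iter: int = 500,
    covariance_floor: float = 1e-6,
) -> tuple[HMMParams, float, list[float]]:
    """Fit from ``restarts`` random initialisations; keep the best by log-likelihood.

    Returns (best params, best log-likelihood, per-restart log-likelihoods).
    Restart seeds are derived from ``seed``; raises an aggregated error only
    if every restart fails numerically.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    xs = [_as_array(s) for s in sequences]
    pooled = np.vstack(xs)
    seeds = np.random.SeedSequence(seed).generate_state(restarts)
    best: tuple[HMMParams, float] | None = None
    logliks: list[float] = []
    failures: list[Exception] = []
    for s in seeds:
        try:
            p0 = init_model(n, pooled, int(s))
            fitted, trace = fit_em(p0, xs, tol=tol, max_iter=max_iter,
                                   covariance_floor=covariance_floor)
            ll = float(trace[-1])
        except (NumericalFailure, np.linalg.LinAlgError) as exc:
            failures.append(exc)
            continue
        logliks.append(ll)
        if best is None or ll > best[1]:
            best = (fitted, ll)
    if best is None:
        raise NumericalFailure(
            f"all {restarts} restarts failed numerically: {failures}"
        )
    return best[0], best[1], logliks


def viterbi(params: HMMParams, sequence) -> StatePath:
    """Most probable joint state path (log-space; ties to the lower index)."""
    x = _as_array(sequence)
    if x.shape[1] != params.n_dims:
        raise ValueError("sequence dimension does not match model")
    logb = _log_emission(x, params)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.initial)
        logP = np.log(params.transition)
    T, n = logb.shape
    delta = logpi + logb[0]
    back = np.zeros((T, n), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logP
        back[t] = cand.argmax(axis=0)  # argmax takes the first (lowest) index on ties
        delta = cand[back[t], np.arange(n)] + logb[t]
    states = np.empty(T, dtype=int)
    states[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return StatePath(states, float(delta.max()))


def dwell_times(path: StatePath | np.ndarray, n: int, condition=None) -> DwellProfile:
    """Occupancy proportions per state; states absent from the path get 0."""
    states = path.states if isinstance(path, StatePath) else np.asarray(path, int)
    if states.size == 0:
        raise ValueError("empty state path")
    overall = np.bincount(states, minlength=n) / states.size
    by_cond: dict[str, np.ndarray] = {}
    if condition is not None:
        condition = np.asarray(condition)
        if condition.shape != states.shape:
            raise ValueError("condition labels must match path length")
        for lab in np.unique(condition):
            sel = states[condition == lab]
            by_cond[str(lab)] = np.bincount(sel, minlength=n) / sel.size
    return DwellProfile(overall, by_cond)


def canonical_state_order(dwells: np.ndarray) -> np.ndarray:
    """Permutation sorting states by descending mean overall dwell-time.

    Model state labels are arbitrary; a fixed ordering makes outputs
    comparable across runs.  ``dwells`` is participants x states (or a
    single dwell vector).
    """
    d = np.atleast_2d(np.asarray(dwells, float)).mean(axis=0)
    return np.argsort(-d, kind="stable")


def permute_states(params: HMMParams, perm: np.ndarray) -> HMMParams:
    """Relabel states by ``perm`` (new index i holds old state perm[i])."""
    perm = np.asarray(perm, int)
    return HMMParams(
        params.initial[perm],
        params.means[perm],
        params.covariances[perm],
        params.transition[np.ix_(perm, perm)],
    )


def state_sweep(
    sequences,
    n_values=(3, 4, 5, 6),
    restarts: int = 10,
    seed: int = 0,
    conditions=None,
    tol: float = 0.005,
    max_iter: int = 500,
) -> dict[int, dict]:
    """Fit one best-of-restarts model per state count and tabulate dwell-times.

    Returns ``{n: {"params", "loglik", "paths", "dwell"}}`` where ``dwell``
    is a participants x states array in canonical (descending-dwell) order.
    """
    n_values = sorted(set(int(n) for n in n_values))
    if not n_values:
        raise ValueError("n_values must be nonempty")
    out: dict[int, dict] = {}
    seeds = np.random.SeedSequence(seed).spawn(len(n_values))
    for n, ss in zip(n_values, seeds):
        params, ll, _ = best_of_restarts(
            n, sequences, restarts=restarts, seed=int(ss.generate_state(1)[0]),
            tol=tol, max_iter=max_iter,
        )
        paths = [viterbi(params, s) for s in sequences]
        dwell = np.vstack([dwell_times(p, n).overall for p in paths])
        perm = canonical_state_order(dwell)
        params = permute_states(params, perm)
        relabel = np.empty(n, dtype=int)
        relabel[perm] = np.arange(n)
        paths = [StatePath(relabel[p.states], p.loglik) for p in paths]
        dwell = dwell[:, perm]
        profiles = None
        if conditions is not None:
            profiles = [
                dwell_times(p, n, c) for p, c in zip(paths, conditions)
            ]
        out[n] = {
            "params": params,
            "loglik": ll,
            "paths": paths,
            "dwell": dwell,
            "profiles": profiles,
        }
    return out


class GaussianHMM(BaseEstimator):
    """Scikit-learn-style Gaussian HMM with random restarts.

    Parameters
    ----------
    n_states : number of hidden states (the profile count, default 4).
    n_restarts : random initialisations; the fit with the highest total
        log-likelihood is kept (default 10).
    tol : EM stopping rule — absolute change in total log-likelihood
        (default 0.005).
    max_iter : EM iteration cap per restart.
    covariance_floor : diagonal added to every covariance for stability.
    random_state : seed for initialisation.

    ``fit(X, lengths=None)`` accepts a single T x d array or a concatenated
    array with per-sequence ``lengths`` (hmmlearn convention).  Fitted
    attributes: ``startprob_``, ``means_``, ``covariances_``, ``transmat_``,
    ``loglik_``, ``restart_logliks_``.
    """

    def __init__(
        self,
        n_states: int = 4,
        n_restarts: int = 10,
        tol: float = 0.005,
        max_iter: int = 500,
        covariance_floor: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.covariance_floor = covariance_floor
        self.random_state = random_state

    @staticmethod
    def _split(X, lengths):
        X = np.asarray(X, float)
        if lengths is None:
            return [X]
        if sum(lengths) != len(X):
            raise ValueError("lengths must sum to the number of rows in X")
        idx = np.cumsum(lengths)[:-1]
        return np.split(X, idx)

    def fit(self, X, y=None, lengths=None):
        xs = self._split(X, lengths)
        seed = 0 if self.random_state is None else int(self.random_state)
        params, ll, lls = best_of_restarts(
            self.n_states, xs, restarts=self.n_restarts, seed=seed,
            tol=self.tol, max_iter=self.max_iter,
            covariance_floor=self.covariance_floor,
        )
        self.params_ = params
        self.startprob_ = params.initial
        self.means_ = params.means
        self.covariances_ = params.covariances
        self.transmat_ = params.transition
        self.loglik_ = ll
        self.restart_logliks_ = lls
        return self

    def predict(self, X, lengths=None) -> np.ndarray:
        """Viterbi state labels for (possibly concatenated) sequences."""
        xs = self._split(X, lengths)
        return np.concatenate([viterbi(self.params_, x).states for x in xs])

    def score(self, X, y=None, lengths=None) -> float:
        """Total log-likelihood of the sequences under the fitted model."""
        return loglik(self.params_, self._split(X, lengths))
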