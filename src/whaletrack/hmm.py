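"""Two-state hidden Markov model for behavioural segmentation.

Regularized 3-h steps are classified into *area-restricted search* (ARS:
short steps, weakly concentrated turning angles — the movement signature of
foraging on patchy krill) versus *transit* (long, directed steps).  Step
lengths follow a state-specific gamma distribution, turning angles a
state-specific von Mises distribution; the hidden state is a first-order
Markov chain shared across animals (animals are independent chains with
common parameters).

Numerics: the forward recursion and Viterbi run entirely in log space, so
sequences of 10^4 intervals cause no underflow.  Likelihood maximisation
works on unconstrained transforms (log for positive scalars, logit for the
transition off-diagonals, a sin/cos pair through atan2 for the angle means)
with multiple jittered restarts around data quantiles, because HMM surfaces
are multimodal and a single bad start is the classic failure mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numba
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, i0e, logsumexp

log = logging.getLogger(__name__)

ARS, TRANSIT = 0, 1
STATE_LABELS = ("ARS", "transit")


@dataclass
class HMMModel:
    """Fitted (or hypothesised) 2-state model.

    Gamma emissions are parameterised by per-state mean/sd in km
    (shape = (mean/sd)^2, scale = sd^2/mean); angles by von Mises location
    (rad) and concentration kappa.  State 0 is ARS by the labelling
    convention enforced in :func:`normalize_labels`.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    angle_mean: np.ndarray
    angle_kappa: np.ndarray
    transition: np.ndarray
    initial: np.ndarray | None = None  # None => stationary distribution

    def __post_init__(self):
        self.step_mean = np.asarray(self.step_mean, dtype=float)
        self.step_sd = np.asarray(self.step_sd, dtype=float)
        self.angle_mean = np.asarray(self.angle_mean, dtype=float)
        self.angle_kappa = np.asarray(self.angle_kappa, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("step means and sds must be positive")
        if np.any(self.angle_kappa < 0):
            raise ValueError("angle concentrations must be non-negative")
        if self.transition.shape != (2, 2) or np.any(self.transition < 0) \
                or np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("transition must be 2x2 row-stochastic")
        if self.initial is not None:
            self.initial = np.asarray(self.initial, dtype=float)

    @property
    def gamma_shape(self) -> np.ndarray:
        return (self.step_mean / self.step_sd) ** 2

    @property
    def gamma_scale(self) -> np.ndarray:
        return self.step_sd**2 / self.step_mean

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the transition matrix (used as the
        initial state distribution when none is given)."""
        a, b = self.transition[0, 1], self.transition[1, 0]
        if a + b == 0:
            return np.array([0.5, 0.5])
        return np.array([b / (a + b), a / (a + b)])

    def initial_dist(self) -> np.ndarray:
        return self.initial if self.initial is not None else self.stationary()

    def to_series(self) -> pd.Series:
        """Flat key-value view for the plain-text parameter file."""
        d = {}
        for s, lab in enumerate(STATE_LABELS):
            d[f"step_mean_km[{lab}]"] = self.step_mean[s]
            d[f"step_sd_km[{lab}]"] = self.step_sd[s]
            d[f"angle_mean_rad[{lab}]"] = self.angle_mean[s]
            d[f"angle_kappa[{lab}]"] = self.angle_kappa[s]
        for i in range(2):
            for j in range(2):
                d[f"transition[{STATE_LABELS[i]}->{STATE_LABELS[j]}]"] = self.transition[i, j]
        return pd.Series(d)


def _gamma_logpdf(x, shape, scale):
    with np.errstate(invalid="ignore", divide="ignore"):
        return (shape - 1.0) * np.log(x) - x / scale - shape * np.log(scale) - gammaln(shape)


def _vonmises_logpdf(x, mu, kappa):
    # log I0(kappa) = log i0e(kappa) + kappa keeps large kappa finite
    return kappa * np.cos(x - mu) - np.log(2.0 * np.pi) - (np.log(i0e(kappa)) + kappa)


def emission_loglik(model: HMMModel, steps: pd.DataFrame) -> np.ndarray:
    """(n, 2) log emission densities.

    Missing turning angles (NaN) contribute the step density only, which is
    the correct marginal likelihood when the angle is unobserved.
    """
    step = steps["step_km"].to_numpy(dtype=float)
    turn = steps["turn_rad"].to_numpy(dtype=float)
    n = len(step)
    ll = np.zeros((n, 2))
    for s in range(2):
        ls = _gamma_logpdf(step, model.gamma_shape[s], model.gamma_scale[s])
        if model.angle_kappa[s] == 0:
            la = np.where(np.isnan(turn), 0.0, -np.log(2.0 * np.pi))
        else:
            la = np.where(
                np.isnan(turn), 0.0,
                _vonmises_logpdf(np.nan_to_num(turn), model.angle_mean[s],
                                 model.angle_kappa[s]))
        ll[:, s] = ls + la
    if not np.all(np.isfinite(ll[np.isfinite(step)])):
        bad = int(np.flatnonzero(~np.isfinite(ll).all(axis=1))[0])
        raise ValueError(f"non-finite emission density at interval {bad} "
                         f"(step={step[bad]}, turn={turn[bad]})")
    return ll


def _split_by_animal(steps: pd.DataFrame):
    if "animal_id" in steps.columns and steps["animal_id"].nunique() > 1:
        return [g for _, g in steps.groupby("animal_id", sort=True)]
    return [steps]


@numba.njit(cache=False)
def _forward_ll(le: np.ndarray, lt: np.ndarray, linit: np.ndarray) -> float:
    """Log-space forward recursion for 2 states (JIT-compiled)."""
    a0 = linit[0] + le[0, 0]
    a1 = linit[1] + le[0, 1]
    for k in range(1, le.shape[0]):
        x00 = a0 + lt[0, 0]
        x10 = a1 + lt[1, 0]
        x01 = a0 + lt[0, 1]
        x11 = a1 + lt[1, 1]
        m0 = x00 if x00 > x10 else x10
        m1 = x01 if x01 > x11 else x11
        a0 = m0 + np.log(np.exp(x00 - m0) + np.exp(x10 - m0)) + le[k, 0]
        a1 = m1 + np.log(np.exp(x01 - m1) + np.exp(x11 - m1)) + le[k, 1]
    m = a0 if a0 > a1 else a1
    return m + np.log(np.exp(a0 - m) + np.exp(a1 - m))


@numba.njit(cache=False)
def _viterbi_core(le: np.ndarray, lt: np.ndarray, linit: np.ndarray) -> np.ndarray:
    """Most probable path for 2 states; ties resolved toward state 0 (ARS)."""
    n = le.shape[0]
    back = np.zeros((n, 2), dtype=np.int64)
    d0 = linit[0] + le[0, 0]
    d1 = linit[1] + le[0, 1]
    for k in range(1, n):
        c00 = d0 + lt[0, 0]
        c10 = d1 + lt[1, 0]
        c01 = d0 + lt[0, 1]
        c11 = d1 + lt[1, 1]
        back[k, 0] = 0 if c00 >= c10 else 1
        back[k, 1] = 0 if c01 >= c11 else 1
        d0 = (c00 if c00 >= c10 else c10) + le[k, 0]
        d1 = (c01 if c01 >= c11 else c11) + le[k, 1]
    path = np.zeros(n, dtype=np.int64)
    path[n - 1] = 0 if d0 >= d1 else 1
    for k in range(n - 2, -1, -1):
        path[k] = back[k + 1, path[k + 1]]
    return path


def hmm_negloglik(model: HMMModel, steps: pd.DataFrame) -> float:
    """Exact negative log-likelihood via the forward recursion in log space.

    ``steps`` may contain several animals (independent chains, summed
    log-likelihoods); rows with NaN step length (the undefined first step of
    a track) are skipped.  Log-space throughout: no underflow at 10^4
    intervals.
    """
    total = 0.0
    lt = np.log(model.transition + 1e-300)
    linit = np.log(model.initial_dist() + 1e-300)
    for chunk in _split_by_animal(steps):
        chunk = chunk[np.isfinite(chunk["step_km"].to_numpy(dtype=float))]
        if len(chunk) == 0:
            continue
        le = emission_loglik(model, chunk)
        total += float(_forward_ll(le, lt, linit))
    return -total


def viterbi(model: HMMModel, steps: pd.DataFrame) -> pd.DataFrame:
    """Globally most probable state path (ties broken toward ARS).

    Returns ``steps`` with a ``state`` column of 0/1 codes and a
    ``state_label`` column; one path per animal.
    """
    out = []
    for chunk in _split_by_animal(steps):
        chunk = chunk.copy()
        ok = np.isfinite(chunk["step_km"].to_numpy(dtype=float))
        sub = chunk[ok]
        if len(sub) == 0:
            chunk["state"] = np.array([], dtype=int) if len(chunk) == 0 else np.nan
            out.append(chunk)
            continue
        le = emission_loglik(model, sub)
        lt = np.log(model.transition + 1e-300)
        linit = np.log(model.initial_dist() + 1e-300)
        path = _viterbi_core(le, lt, linit)
        states = np.full(len(chunk), np.nan)
        states[ok] = path
        chunk["state"] = states
        chunk["state_label"] = [STATE_LABELS[int(s)] if np.isfinite(s) else ""
                                for s in states]
        out.append(chunk)
    return pd.concat(out, ignore_index=True) if out else steps.assign(state=[], state_label=[])


# ---------------------------------------------------------------------------
# fitting

def _pack(model: HMMModel) -> np.ndarray:
    def logit(p):
        p = min(max(p, 1e-9), 1 - 1e-9)
        return np.log(p / (1 - p))
    return np.array([
        *np.log(model.step_mean), *np.log(model.step_sd),
        *np.sin(model.angle_mean), *np.cos(model.angle_mean),
        *np.log(np.maximum(model.angle_kappa, 1e-8)),
        logit(model.transition[0, 1]), logit(model.transition[1, 0]),
    ])


def _unpack(theta: np.ndarray) -> HMMModel:
    sm = np.exp(theta[0:2])
    ss = np.exp(theta[2:4])
    mu = np.arctan2(theta[4:6], theta[6:8])
    kap = np.exp(theta[8:10])
    a = 1.0 / (1.0 + np.exp(-theta[10]))  # ARS -> transit
    b = 1.0 / (1.0 + np.exp(-theta[11]))  # transit -> ARS
    return HMMModel(step_mean=sm, step_sd=ss, angle_mean=mu, angle_kappa=kap,
                    transition=np.array([[1 - a, a], [b, 1 - b]]))


def normalize_labels(model: HMMModel) -> HMMModel:
    """Enforce the labelling convention: state 0 (ARS) has the smaller step
    mean, and must also have the smaller angular concentration.

    ARS is biologically defined by *both* short steps and weak directional
    persistence; if the fitted states separate on step length but the
    shorter-stepped state is the more directed one, the two criteria
    disagree and the model is rejected rather than silently relabelled.
    """
    order = np.argsort(model.step_mean)
    m = HMMModel(
        step_mean=model.step_mean[order], step_sd=model.step_sd[order],
        angle_mean=model.angle_mean[order], angle_kappa=model.angle_kappa[order],
        transition=model.transition[np.ix_(order, order)],
        initial=None if model.initial is None else model.initial[order],
    )
    if m.angle_kappa[ARS] > m.angle_kappa[TRANSIT]:
        raise ValueError(
            "state labelling ambiguous: the short-step state has the higher "
            "angular concentration (kappa %.3g > %.3g); ARS cannot be identified"
            % (m.angle_kappa[ARS], m.angle_kappa[TRANSIT]))
    return m


def _start_values(steps: pd.DataFrame, rng: np.random.Generator, jitter: bool) -> HMMModel:
    s = steps["step_km"].to_numpy(dtype=float)
    s = s[np.isfinite(s) & (s > 0)]
    q30, q70 = np.quantile(s, [0.3, 0.7])
    f = (lambda: rng.uniform(0.6, 1.6)) if jitter else (lambda: 1.0)
    return HMMModel(
        step_mean=np.array([q30 * f(), q70 * f()]),
        step_sd=np.array([max(q30, 1e-3) * f(), max(q70 * 0.5, 1e-3) * f()]),
        angle_mean=np.array([0.0, 0.0]),
        angle_kappa=np.array([0.5 * f(), 4.0 * f()]),
        transition=np.array([[0.9, 0.1], [0.2, 0.8]]) if not jitter else
        _random_transition(rng),
    )


def _random_transition(rng: np.random.Generator) -> np.ndarray:
    a = rng.uniform(0.03, 0.4)
    b = rng.uniform(0.05, 0.6)
    return np.array([[1 - a, a], [b, 1 - b]])


def fit_hmm(steps: pd.DataFrame, n_restarts: int = 10, seed: int = 0,
            pooled: bool = True):
    """Maximum-likelihood fit of the 2-state model.

    With ``pooled=True`` (the default, matching a joint fit across all
    tracked animals) one parameter set is shared across animals, each animal
    an independent chain.  ``n_restarts`` optimisations start from jittered
    data-quantile values; the best converged optimum wins.  Returns
    ``(model, report)`` with the label convention applied.
    """
    if not pooled:
        raise NotImplementedError("per-animal fitting: call fit_hmm per animal's steps")
    n_ok = int(np.isfinite(steps["step_km"].to_numpy(dtype=float)).sum())
    if n_ok < 50:
        raise ValueError(f"need >= 50 step intervals to fit, got {n_ok}")
    rng = np.random.default_rng(seed)
    best = None
    failures = []
    for r in range(max(1, int(n_restarts))):
        start = _start_values(steps, rng, jitter=r > 0)
        try:
            res = minimize(lambda th: hmm_negloglik(_unpack(th), steps),
                           _pack(start), method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-7,
                                    "adaptive": True})
        except (ValueError, FloatingPointError) as e:
            failures.append(str(e))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite optimum")
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all HMM restarts failed: " + "; ".join(failures[:5]))
    model = normalize_labels(_unpack(best.x))
    report = {"negloglik": float(best.fun), "converged": bool(best.success),
              "n_intervals": n_ok, "n_restarts": max(1, int(n_restarts)),
              "n_failed_restarts": len(failures)}
    log.info("HMM fit: -lnL=%.2f, step means %.2f/%.2f km, kappas %.2f/%.2f",
             best.fun, *model.step_mean, *model.angle_kappa)
    return model, report


def activity_budgets(decoded: pd.DataFrame) -> pd.DataFrame:
    """Per-animal ARS time budgets from a Viterbi-decoded step table.

    Returns one row per animal with ``ars_fraction`` and ``transit_fraction``
    (summing to 1); frame ``attrs`` carry the across-animal mean and median
    ARS percentage.
    """
    if "state" not in decoded.columns:
        raise ValueError("decoded table must carry a 'state' column (run viterbi)")
    rows = []
    key = "animal_id" if "animal_id" in decoded.columns else None
    groups = decoded.groupby(key, sort=True) if key else [("all", decoded)]
    for aid, grp in groups:
        st = grp["state"].to_numpy(dtype=float)
        st = st[np.isfinite(st)]
        if len(st) == 0:
            continue
        ars = float(np.mean(st == ARS))
        rows.append({"animal_id": aid, "n_intervals": len(st),
                     "ars_fraction": ars, "transit_fraction": 1.0 - ars})
    table = pd.DataFrame(rows)
    if len(table):
        table.attrs["ars_mean_percent"] = float(table["ars_fraction"].mean() * 100.0)
        table.attrs["ars_median_percent"] = float(table["ars_fraction"].median() * 100.0)
    return table
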