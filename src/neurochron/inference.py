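"""Tercile partitioning and mixed-effects models linking dopamine to timing.

Three model families mirror the analysis chain:

* ``fit_trial_logistic`` — random-intercept logistic regression of the
  single-trial 'long' judgement on standardized stimulus duration and the
  standardized phasic dopamine summary (cluster-window mean). A negative
  dopamine coefficient means higher phasic dopamine -> more 'short'
  judgements (temporal underestimation).
* ``fit_tercile_model`` — the same logistic model with the within-
  participant dopamine tercile coded -1/0/+1 as an ordered numeric
  predictor.
* ``fit_tonic_outcome`` — linear mixed model (random intercepts) of a
  per-tonic-window psychometric outcome (precision = -log Weber fraction,
  or accuracy = bisection point) on the standardized tonic dopamine level.

The logistic mixed models integrate the random intercept by adaptive
Gauss-Hermite quadrature centred on the per-participant Laplace mode; with
a single participant they reduce to ordinary logistic regression. The
linear mixed model is fitted with statsmodels MixedLM. p-values use the
normal reference on z = beta/se (small-sample caveat: 6 participants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

from .decomposition import TonicSeries, WindowSummary
from .psychophysics import PsychometricFit

__all__ = [
    "TercilePartition",
    "MixedModelFit",
    "partition_terciles",
    "fit_trial_logistic",
    "fit_tercile_model",
    "fit_tonic_outcome",
]

TERCILE_LABELS = ("low", "medium", "high")


@dataclass
class TercilePartition:
    """Within-participant rank terciles of a per-trial dopamine summary."""

    labels: np.ndarray  # 'low' | 'medium' | 'high' per trial
    codes: np.ndarray  # -1 | 0 | +1 per trial
    participants: np.ndarray

    def counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().reindex(list(TERCILE_LABELS), fill_value=0)


@dataclass
class MixedModelFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    re_var: float
    n_obs: int
    converged: bool
    loglik: float = np.nan
    n_params: int = 0

    def coef(self, name: str) -> tuple[float, float, float, float]:
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i]), float(self.z[i]), float(self.p[i])


def partition_terciles(summary: WindowSummary | np.ndarray, participants) -> TercilePartition:
    """Rank-based within-participant split into low/medium/high terciles.

    Group sizes differ by at most one, with the larger groups at the low
    end when the trial count is not divisible by 3; ties are broken by
    trial order (stable sort), so the partition is invariant to strictly
    monotone transforms of the summary values.
    """
    values = summary.values if isinstance(summary, WindowSummary) else np.asarray(summary, float)
    participants = np.asarray(participants)
    if len(values) != len(participants):
        raise ValueError("summary and participants must align")
    labels = np.empty(len(values), dtype=object)
    codes = np.zeros(len(values), dtype=int)
    for p in pd.unique(participants):
        idx = np.flatnonzero(participants == p)
        if idx.size < 3:
            raise ValueError(f"participant {p!r} has fewer than 3 trials")
        v = values[idx]
        if np.ptp(v) == 0:
            warnings.warn(f"participant {p!r}: all-equal summaries; stable split by trial order",
                          stacklevel=2)
        order = np.argsort(v, kind="stable")
        n = idx.size
        q, r = divmod(n, 3)
        sizes = [q + (1 if k < r else 0) for k in range(3)]
        start = 0
        for k, sz in enumerate(sizes):
            sel = idx[order[start : start + sz]]
            labels[sel] = TERCILE_LABELS[k]
            codes[sel] = k - 1
            start += sz
    return TercilePartition(labels=labels, codes=codes, participants=participants)


def _zstd(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std()
    if sd < 1e-12:
        raise ValueError(f"zero variance in predictor {what!r}")
    return (x - x.mean()) / sd


class _MixedLogit:
    """Random-intercept logistic likelihood via adaptive Gauss-Hermite."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray, n_nodes: int = 15):
        self.X = X
        self.y = y.astype(float)
        self.group_idx = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
        self.nodes, self.weights = hermegauss(n_nodes)  # exp(-x^2/2) weight

    def _group_loglik(self, eta: np.ndarray, y: np.ndarray, tau: float) -> float:
        # mode of f(b) = sum loglik(eta + b) - b^2/(2 tau^2) by Newton
        b = 0.0
        for _ in range(50):
            p = expit(eta + b)
            g = np.sum(y - p) - b / tau**2
            h = -np.sum(p * (1 - p)) - 1 / tau**2
            step = g / h
            b -= step
            if abs(step) < 1e-10:
                break
        p = expit(eta + b)
        h = np.sum(p * (1 - p)) + 1 / tau**2  # positive curvature at mode
        scale = 1.0 / np.sqrt(h)
        bk = b + scale * self.nodes
        etab = eta[None, :] + bk[:, None]
        ll = np.sum(y * etab - np.log1p(np.exp(np.clip(etab, None, 500))), axis=1)
        # integrand under N(0, tau^2) prior, adaptive GH with Hermite_e weights
        logf = ll - bk**2 / (2 * tau**2) + self.nodes**2 / 2.0
        return float(
            logsumexp(logf, b=self.weights) + np.log(scale) - 0.5 * np.log(2 * np.pi * tau**2)
        )

    def nll(self, params: np.ndarray) -> float:
        beta, log_tau = params[:-1], params[-1]
        tau = np.exp(log_tau)
        eta = self.X @ beta
        return -sum(
            self._group_loglik(eta[idx], self.y[idx], tau) for idx in self.group_idx
        )


def _fit_mixed_logit(X: np.ndarray, y: np.ndarray, groups: np.ndarray, names: list[str]) -> MixedModelFit:
    groups = np.asarray(groups)
    n_groups = pd.unique(groups).size
    if n_groups == 1:
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # perfect separation
            warnings.warn("logistic fit failed to converge (separation?)", stacklevel=3)
            return MixedModelFit(names, np.full(X.shape[1], np.nan), np.full(X.shape[1], np.nan),
                                 np.full(X.shape[1], np.nan), np.full(X.shape[1], np.nan),
                                 0.0, len(y), False)
        beta = np.asarray(res.params, float)
        se = np.asarray(res.bse, float)
        z = beta / se
        return MixedModelFit(names, beta, se, z, 2 * norm.sf(np.abs(z)), 0.0, len(y),
                             converged, float(res.llf), X.shape[1])

    ml = _MixedLogit(X, y, groups)
    start = np.concatenate([np.zeros(X.shape[1]), [np.log(0.5)]])
    res = minimize(ml.nll, start, method="L-BFGS-B",
                   bounds=[(None, None)] * X.shape[1] + [(-8.0, 3.0)])
    params = res.x
    H = approx_hess(params, ml.nll)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        ok = bool(
            res.success and np.all(np.isfinite(se_all[:-1])) and np.all(se_all[:-1] > 0)
        )
    except np.linalg.LinAlgError:
        se_all = np.full(params.size, np.nan)
        ok = False
    beta = params[:-1]
    se = se_all[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    return MixedModelFit(names, beta, se, z, 2 * norm.sf(np.abs(z)),
                         float(np.exp(2 * params[-1])), len(y), ok,
                         -float(res.fun), params.size)


def _design(trials: pd.DataFrame, extra: np.ndarray, extra_name: str,
            standardize_extra: bool) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = (trials["response"].to_numpy() == "long").astype(float)
    dur = _zstd(trials["duration_s"].to_numpy(float), "duration")
    x = _zstd(extra, extra_name) if standardize_extra else extra.astype(float)
    X = np.column_stack([np.ones(len(y)), dur, x])
    return X, y, ["intercept", "duration", extra_name]


def fit_trial_logistic(
    trials: pd.DataFrame,
    summary: WindowSummary | np.ndarray,
    participants,
) -> MixedModelFit:
    """Single-trial judgement model: long ~ duration + dopamine summary.

    Response coded long=1, so a negative dopamine coefficient means the
    likelihood of 'short' judgements increases with the cluster-window
    dopamine level.
    """
    values = summary.values if isinstance(summary, WindowSummary) else np.asarray(summary, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite dopamine summaries")
    X, y, names = _design(trials, values, "dopamine", standardize_extra=True)
    return _fit_mixed_logit(X, y, np.asarray(participants), names)


def fit_tercile_model(
    trials: pd.DataFrame,
    partition: TercilePartition,
    participants=None,
) -> MixedModelFit:
    """Tercile PF-shift model: long ~ duration + tercile code (-1/0/+1)."""
    participants = partition.participants if participants is None else np.asarray(participants)
    X, y, names = _design(trials, partition.codes.astype(float), "tercile",
                          standardize_extra=False)
    return _fit_mixed_logit(X, y, participants, names)


def fit_tonic_outcome(
    tonic_levels: np.ndarray,
    fits_per_window: list[PsychometricFit],
    participants,
    outcome: str = "precision",
) -> MixedModelFit:
    """Tonic model: per-window PF outcome ~ standardized tonic dopamine.

    ``outcome='precision'`` regresses -log(Weber fraction) (increasing =
    better precision, so a positive coefficient matches 'higher tonic
    dopamine -> improved precision'); ``outcome='accuracy'`` regresses the
    bisection point. Both outcome and predictor are z-scored, so the
    reported coefficient is standardized. Participant random intercepts
    via statsmodels MixedLM; single-participant input reduces to OLS.
    """
    if outcome not in ("precision", "accuracy"):
        raise ValueError("outcome must be 'precision' or 'accuracy'")
    tonic = np.asarray(tonic_levels, dtype=float)
    participants = np.asarray(participants)
    if not (len(tonic) == len(fits_per_window) == len(participants)):
        raise ValueError("tonic levels, fits and participants must align")
    counts = pd.Series(participants).value_counts()
    too_few = counts[counts < 2]
    if len(too_few):
        raise ValueError(f"participants with <2 tonic windows: {list(too_few.index)}")
    good = np.array([f.converged for f in fits_per_window])
    if not good.all():
        warnings.warn(
            f"excluding {int((~good).sum())} non-converged PF window fit(s)", stacklevel=2
        )
        tonic = tonic[good]
        participants = participants[good]
        fits_per_window = [f for f, g in zip(fits_per_window, good) if g]
        counts = pd.Series(participants).value_counts()
        ok_p = counts[counts >= 2].index
        keep = np.isin(participants, ok_p)
        tonic, participants = tonic[keep], participants[keep]
        fits_per_window = [f for f, kk in zip(fits_per_window, keep) if kk]
        if len(fits_per_window) < 4:
            raise ValueError("too few converged PF window fits for the tonic model")
    if outcome == "precision":
        yvals = np.array([-np.log(f.weber) for f in fits_per_window])
    else:
        yvals = np.array([f.bp for f in fits_per_window])
    x = _zstd(tonic, "tonic")
    yz = _zstd(yvals, outcome)
    names = ["intercept", "tonic"]
    if pd.unique(participants).size == 1:
        X = np.column_stack([np.ones(len(yz)), x])
        res = sm.OLS(yz, X).fit()
        beta, se = np.asarray(res.params), np.asarray(res.bse)
        z = beta / se
        return MixedModelFit(names, beta, se, z, 2 * norm.sf(np.abs(z)), 0.0, len(yz),
                             True, float(res.llf), 3)
    X = np.column_stack([np.ones(len(yz)), x])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(yz, X, groups=participants)
            res = md.fit(reml=False, method="lbfgs")
        beta = np.asarray(res.fe_params, float)
        se = np.asarray(res.bse_fe, float)
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError("non-finite fixed-effect SEs")
        z = beta / se
        return MixedModelFit(names, beta, se, z, 2 * norm.sf(np.abs(z)),
                             float(np.asarray(res.cov_re)[0, 0]), len(yz),
                             bool(res.converged), float(res.llf), len(beta) + 2)
    except np.linalg.LinAlgError:
        # degenerate random-effects covariance: fall back to fixed participant
        # intercepts (within-participant estimator of the tonic slope)
        warnings.warn("mixed model degenerate; fixed-intercept fallback", stacklevel=2)
        dummies = pd.get_dummies(pd.Series(participants), drop_first=False).to_numpy(float)
        Xf = np.column_stack([dummies, x])
        res = sm.OLS(yz, Xf).fit()
        beta = np.array([np.nan, res.params[-1]])
        se = np.array([np.nan, res.bse[-1]])
        z = beta / se
        return MixedModelFit(names, beta, se, z, 2 * norm.sf(np.abs(z)), 0.0, len(yz),
                             False, float(res.llf), Xf.shape[1] + 1)
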