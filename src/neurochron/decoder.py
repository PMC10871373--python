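"""Elastic-net concentration decoding from voltammetric sweep features.

Two independent penalized linear regressions (dopamine, serotonin) share a
single (l1_ratio, lambda) hyperparameter pair selected by k-fold
cross-validation on the joint (summed) mean squared error. Features are
standardized with constants estimated from training folds only during
selection and from the full calibration set at the final refit.

The penalty follows the scikit-learn ``ElasticNet`` parameterization:

    (1/2n)*||y - Xb||^2 + lambda*(l1*||b||_1 + (1-l1)/2*||b||^2)

so at ``l1_ratio = 0`` the solution is ridge with matrix penalty
``n*lambda`` on standardized features, i.e. ``(X'X + n*lambda*I)^-1 X'y``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.model_selection import KFold

from .synthetic import CalibrationSet, SessionRecording

__all__ = ["DecoderModel", "ConcentrationSeries", "fit_decoder", "decode"]

DEFAULT_L1_GRID = (0.1, 0.5, 0.9)
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-6, -1, 6))


@dataclass
class ConcentrationSeries:
    """Decoded dopamine/serotonin concentration estimates over time (uM)."""

    timestamps: np.ndarray
    da: np.ndarray
    sert: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.timestamps) == len(self.da) == len(self.sert)):
            raise ValueError("timestamps, da and sert must have equal length")


@dataclass
class DecoderModel:
    """Trained per-analyte linear decoders plus standardization constants."""

    coef_da: np.ndarray
    coef_5ht: np.ndarray
    intercept_da: float
    intercept_5ht: float
    l1_ratio: float
    penalty_lambda: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    feature_mask: np.ndarray
    cv_score_da: float
    cv_score_5ht: float

    @property
    def n_features(self) -> int:
        return self.feature_mask.size

    def to_json(self) -> str:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DecoderModel":
        d = json.loads(text)
        for k in ("coef_da", "coef_5ht", "feature_means", "feature_scales"):
            d[k] = np.asarray(d[k], dtype=float)
        d["feature_mask"] = np.asarray(d["feature_mask"], dtype=bool)
        return cls(**d)


def _make_estimator(l1_ratio: float, lam: float, n: int):
    if l1_ratio == 0.0:
        return Ridge(alpha=n * lam)
    return ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=20_000, tol=1e-7)


def fit_decoder(
    cal: CalibrationSet,
    l1_grid=DEFAULT_L1_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 10,
    seed: int = 0,
    full_output: bool = False,
):
    """Select (l1_ratio, lambda) by joint k-fold CV MSE and refit on all data.

    With ``full_output=True`` also returns the CV table mapping
    (l1_ratio, lambda) -> {'mse', 'r2_da', 'r2_5ht'}.
    """
    l1_grid = list(l1_grid)
    lambda_grid = list(lambda_grid)
    if not l1_grid or not lambda_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    X = np.asarray(cal.sweeps, dtype=float)
    n, p = X.shape
    if n < n_folds:
        raise ValueError(f"{n} samples is fewer than {n_folds} folds")

    scales_all = X.std(axis=0)
    mask = scales_all > 1e-12
    if not mask.all():
        warnings.warn(
            f"dropping {int((~mask).sum())} all-constant feature(s) from the decoder",
            stacklevel=2,
        )
    Xm = X[:, mask]
    ys = {"da": np.asarray(cal.labels_da, float), "5ht": np.asarray(cal.labels_5ht, float)}

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xm))
    results: dict[tuple[float, float], dict[str, float]] = {}
    for l1 in l1_grid:
        for lam in lambda_grid:
            sse = {"da": 0.0, "5ht": 0.0}
            sst = {"da": 0.0, "5ht": 0.0}
            n_test_total = 0
            for tr, te in splits:
                mu = Xm[tr].mean(axis=0)
                sd = Xm[tr].std(axis=0)
                sd[sd < 1e-12] = 1.0
                Xtr, Xte = (Xm[tr] - mu) / sd, (Xm[te] - mu) / sd
                n_test_total += len(te)
                for a, y in ys.items():
                    est = _make_estimator(l1, lam, len(tr))
                    est.fit(Xtr, y[tr])
                    resid = y[te] - est.predict(Xte)
                    sse[a] += float(resid @ resid)
                    sst[a] += float(((y[te] - y[tr].mean()) ** 2).sum())
            results[(l1, lam)] = {
                "mse": (sse["da"] + sse["5ht"]) / n_test_total,
                "r2_da": 1.0 - sse["da"] / max(sst["da"], 1e-300),
                "r2_5ht": 1.0 - sse["5ht"] / max(sst["5ht"], 1e-300),
            }
    best = min(results, key=lambda k: results[k]["mse"])
    l1_best, lam_best = best

    mu = Xm.mean(axis=0)
    sd = Xm.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (Xm - mu) / sd
    coefs, intercepts = {}, {}
    for a, y in ys.items():
        est = _make_estimator(l1_best, lam_best, n)
        est.fit(Xs, y)
        coefs[a] = np.asarray(est.coef_, dtype=float)
        intercepts[a] = float(est.intercept_)

    means_full = np.zeros(p)
    scales_full = np.ones(p)
    means_full[mask] = mu
    scales_full[mask] = sd
    coef_da = np.zeros(p)
    coef_5ht = np.zeros(p)
    coef_da[mask] = coefs["da"]
    coef_5ht[mask] = coefs["5ht"]
    model = DecoderModel(
        coef_da=coef_da,
        coef_5ht=coef_5ht,
        intercept_da=intercepts["da"],
        intercept_5ht=intercepts["5ht"],
        l1_ratio=float(l1_best),
        penalty_lambda=float(lam_best),
        feature_means=means_full,
        feature_scales=scales_full,
        feature_mask=mask,
        cv_score_da=float(results[best]["r2_da"]),
        cv_score_5ht=float(results[best]["r2_5ht"]),
    )
    return (model, results) if full_output else model


def decode(model: DecoderModel, rec: SessionRecording | np.ndarray) -> ConcentrationSeries:
    """Apply the trained decoder to session sweeps, timepoint by timepoint.

    Estimates are affine in the sweep features and may be negative
    (downstream analyses use relative changes); no clipping is applied.
    """
    if isinstance(rec, SessionRecording):
        if rec.sweeps is None:
            raise ValueError("recording has no sweep features to decode")
        sweeps, timestamps = rec.sweeps, rec.timestamps
    else:
        sweeps = np.asarray(rec, dtype=float)
        timestamps = np.arange(len(sweeps), dtype=float)
    if sweeps.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {sweeps.shape[1]} does not match model ({model.n_features})"
        )
    bad = np.flatnonzero(~np.isfinite(sweeps).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite sweep features at timepoint index {int(bad[0])}")
    Z = (sweeps - model.feature_means) / model.feature_scales
    da = model.intercept_da + Z @ model.coef_da
    sert = model.intercept_5ht + Z @ model.coef_5ht
    return ConcentrationSeries(timestamps=np.asarray(timestamps, float), da=da, sert=sert)
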