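"""End-to-end orchestration: simulate -> decode -> decompose -> infer.

A ``RunConfig`` fully determines a cohort run: the synthetic cohort
(default 6 patients, 300 trials each, mirroring the study design), the
decoder calibration and hyperparameter search, the tonic/phasic
decomposition, and the inferential stages (psychometrics, cluster
permutation test, mixed models, Bayesian prevalence). Reruns with the same
config and seed reproduce every stochastic output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, cluster, decomposition, inference, psychophysics
from .decoder import DEFAULT_L1_GRID, DEFAULT_LAMBDA_GRID, decode, fit_decoder
from .synthetic import (
    NeurochemParams,
    ObserverParams,
    TaskConfig,
    generate_calibration_set,
    generate_session,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "pf_by_tonic_window"]

STAGES = ("simulate", "decode", "decompose", "psychometrics", "cluster", "infer", "prevalence")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Serializable configuration of one cohort analysis run."""

    seed: int = 0
    n_participants: int = 6
    task: dict = field(default_factory=dict)
    observer: dict = field(default_factory=lambda: {"phasic_coupling": 0.08, "tonic_coupling": 0.3})
    neuro: dict = field(default_factory=dict)
    n_features: int = 32
    calibration_samples: int = 500
    conc_grid: list = field(default_factory=lambda: [0.0, 0.5, 1.0, 2.0])
    l1_grid: list = field(default_factory=lambda: list(DEFAULT_L1_GRID))
    lambda_grid: list = field(default_factory=lambda: [float(x) for x in DEFAULT_LAMBDA_GRID])
    n_folds: int = 10
    tonic_window: float = 240.0
    cluster_window: list = field(default_factory=lambda: list(decomposition.CLUSTER_WINDOW))
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    prevalence_alpha: float = 0.05
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        self.stages = {s: self.stages.get(s, True) for s in STAGES}

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def task_config(self) -> TaskConfig:
        return TaskConfig(**self.task)

    def observer_params(self) -> ObserverParams:
        return ObserverParams(**self.observer)

    def neuro_params(self) -> NeurochemParams:
        from .synthetic import default_templates

        t_da, t_5ht = default_templates(self.n_features)
        return NeurochemParams(template_da=t_da, template_5ht=t_5ht, **self.neuro)


def derive_seeds(master: int, n: int, label: str) -> np.ndarray:
    """Deterministic per-component integer seeds (< 2**31) from a master seed."""
    tag = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence([int(master), tag])
    return (ss.generate_state(n, dtype=np.uint32) % (2**31)).astype(np.int64)


def pf_by_tonic_window(
    trials: pd.DataFrame,
    tonic: decomposition.TonicSeries,
    min_trials: int = 10,
    **fit_kwargs,
):
    """Fit one PF per tonic window from the trials whose onset falls inside it.

    Returns (tonic_da_levels, fits) for windows with enough trials and both
    response categories present.
    """
    onsets = trials["onset_s"].to_numpy(float)
    levels, fits = [], []
    half = tonic.window_length / 2.0
    for c, level in zip(tonic.window_centers, tonic.tonic_da):
        m = (onsets >= c - half) & (onsets < c + half)
        sub = trials[m]
        if m.sum() < min_trials or sub["response"].nunique() < 2:
            continue
        fit = psychophysics.fit_pf(psychophysics.ResponseSet.from_trials(sub), **fit_kwargs)
        levels.append(level)
        fits.append(fit)
    return np.asarray(levels), fits


def _fit_to_dict(f) -> dict:
    return {
        "bp": f.bp, "sigma": f.sigma, "jnd": f.jnd, "weber": f.weber,
        "lapse": f.lapse, "loglik": f.loglik, "converged": f.converged,
        "n_trials": f.n_trials, "label": None if f.label is None else str(f.label),
    }


def _model_to_dict(m) -> dict:
    return {
        "names": m.names,
        "beta": [float(b) for b in m.beta],
        "se": [float(s) for s in m.se],
        "z": [float(z) for z in m.z],
        "p": [float(p) for p in m.p],
        "re_var": float(m.re_var),
        "n_obs": m.n_obs,
        "converged": m.converged,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the enabled stages in dependency order and return the report."""
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {s: bool(config.stages[s]) for s in STAGES},
    }
    task = config.task_config()
    observer = config.observer_params()
    neuro = config.neuro_params()

    def require(stage: str, needed: str):
        if not config.stages[needed]:
            raise PipelineError(f"stage '{stage}' requires disabled stage '{needed}'")

    sessions = None
    if config.stages["simulate"]:
        seeds = derive_seeds(config.seed, config.n_participants, "session")
        sessions = [
            generate_session(task, observer, neuro, seed=int(s)) for s in seeds
        ]
        report["simulate"] = {
            "n_participants": config.n_participants,
            "n_trials": [len(s.trials) for s in sessions],
            "session_seeds": [int(s) for s in seeds],
        }

    series = None
    if config.stages["decode"]:
        require("decode", "simulate")
        cal_seed = int(derive_seeds(config.seed, 1, "calibration")[0])
        cal = generate_calibration_set(
            neuro, n_samples=config.calibration_samples, conc_grid=config.conc_grid,
            seed=cal_seed,
        )
        model = fit_decoder(
            cal, l1_grid=config.l1_grid, lambda_grid=config.lambda_grid,
            n_folds=config.n_folds, seed=cal_seed,
        )
        series = [decode(model, s) for s in sessions]
        report["decode"] = {
            "l1_ratio": model.l1_ratio,
            "penalty_lambda": model.penalty_lambda,
            "cv_r2_da": model.cv_score_da,
            "cv_r2_5ht": model.cv_score_5ht,
        }

    tonic_list = epochs_list = summaries = None
    if config.stages["decompose"]:
        require("decompose", "decode")
        tonic_list = [decomposition.compute_tonic(s, config.tonic_window) for s in series]
        epochs_list = [
            decomposition.extract_epochs(cs, s.trials)
            for cs, s in zip(series, sessions)
        ]
        w0, w1 = config.cluster_window
        summaries = [decomposition.window_mean(e, w0, w1, analyte="da") for e in epochs_list]
        report["decompose"] = {
            "tonic_window_s": config.tonic_window,
            "n_tonic_windows": [len(t.window_centers) for t in tonic_list],
            "n_epochs": [e.n_trials for e in epochs_list],
            "n_dropped": [e.n_dropped for e in epochs_list],
        }

    if config.stages["psychometrics"]:
        require("psychometrics", "simulate")
        fits = [
            psychophysics.fit_pf(psychophysics.ResponseSet.from_trials(s.trials))
            for s in sessions
        ]
        report["psychometrics"] = {"participant_fits": [_fit_to_dict(f) for f in fits]}

    if config.stages["cluster"]:
        require("cluster", "decompose")
        epochs_by_p, labels_by_p = [], []
        for s, e in zip(sessions, epochs_list):
            resp = s.trials["response"].to_numpy()[e.trial_index]
            epochs_by_p.append(e.da)
            labels_by_p.append((resp == "short").astype(int))
        cres = cluster.cluster_permutation_test(
            epochs_by_p, labels_by_p, epochs_list[0].epoch_times,
            n_perm=config.n_perm, cluster_alpha=config.cluster_alpha,
            seed=int(derive_seeds(config.seed, 1, "cluster")[0]),
        )
        report["cluster"] = {
            "n_perm": cres.n_perm,
            "clusters": [dataclasses.asdict(c) for c in cres.clusters],
            "min_p": cres.min_p,
        }

    if config.stages["infer"]:
        require("infer", "decompose")
        trials_all = pd.concat(
            [s.trials.iloc[e.trial_index] for s, e in zip(sessions, epochs_list)],
            ignore_index=True,
        )
        pids = np.concatenate(
            [np.full(e.n_trials, i) for i, e in enumerate(epochs_list)]
        )
        values = np.concatenate([w.values for w in summaries])
        trial_model = inference.fit_trial_logistic(trials_all, values, pids)
        partition = inference.partition_terciles(values, pids)
        tercile_model = inference.fit_tercile_model(trials_all, partition)
        tercile_fits = [
            [
                _fit_to_dict(f)
                for f in psychophysics.indices_by_group(
                    psychophysics.ResponseSet.from_trials(trials_all[pids == i]),
                    labels=partition.labels[pids == i],
                )
            ]
            for i in range(len(sessions))
        ]
        levels_all, fits_all, pid_w = [], [], []
        for i, (s, t) in enumerate(zip(sessions, tonic_list)):
            lv, ft = pf_by_tonic_window(s.trials, t)
            levels_all.append(lv)
            fits_all.extend(ft)
            pid_w.append(np.full(len(lv), i))
        levels_all = np.concatenate(levels_all)
        pid_w = np.concatenate(pid_w)
        tonic_precision = inference.fit_tonic_outcome(levels_all, fits_all, pid_w, "precision")
        tonic_accuracy = inference.fit_tonic_outcome(levels_all, fits_all, pid_w, "accuracy")
        report["infer"] = {
            "trial_logistic": _model_to_dict(trial_model),
            "tercile_model": _model_to_dict(tercile_model),
            "tercile_fits": tercile_fits,
            "tonic_precision": _model_to_dict(tonic_precision),
            "tonic_accuracy": _model_to_dict(tonic_accuracy),
            "n_tonic_outcome_rows": int(len(fits_all)),
        }

    if config.stages["prevalence"]:
        require("prevalence", "infer")
        k = 0
        for i in range(len(sessions)):
            m = pids == i
            fit_i = inference.fit_trial_logistic(
                trials_all[m].reset_index(drop=True), values[m], pids[m]
            )
            if fit_i.converged and fit_i.coef("dopamine")[3] < config.prevalence_alpha:
                k += 1
        prev = bayes.prevalence_posterior(k, len(sessions), alpha=config.prevalence_alpha)
        report["prevalence"] = {
            "k": prev.k, "n": prev.n, "alpha": prev.alpha,
            "gamma_map": prev.gamma_map, "hpdi_low": prev.hpdi_low,
            "hpdi_high": prev.hpdi_high, "hpdi_level": prev.hpdi_level,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.to_yaml())
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        if sessions is not None:
            for i, s in enumerate(sessions):
                s.trials.to_csv(out / f"trials_p{i}.csv", index=False)
    return report
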