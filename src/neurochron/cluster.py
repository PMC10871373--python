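"""Cluster-based permutation contrast of response-conditioned epochs.

Per participant and epoch timepoint, a Welch t statistic contrasts the two
response groups across trials; participant statistics are combined by
Stouffer's method on sign-preserving probit-transformed one-sided p-values,
yielding a z series over timepoints. Clusters are maximal runs of
timepoints with |z| above the two-sided cluster-forming threshold; the
cluster mass is the sum of |z| in the run. Family-wise error over
timepoints is controlled by comparing each observed mass against the null
distribution of the maximum cluster mass under within-participant label
permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from scipy.stats import t as t_dist

__all__ = ["ClusterResult", "timepoint_statistic", "cluster_permutation_test"]

_Z_CAP = 37.0  # |z| beyond double-precision probit resolution


@dataclass
class Cluster:
    t_start: float
    t_end: float
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    stat_series: np.ndarray
    epoch_times: np.ndarray
    clusters: list[Cluster]
    n_perm: int
    cluster_alpha: float
    seed: int
    null_masses: np.ndarray

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def _welch_z(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch t over columns, mapped to z via the probit of the
    one-sided Student p (sign-preserving)."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    z = np.zeros_like(t)
    ok = np.isfinite(t) & np.isfinite(df) & (df > 0)
    # z = Phi^-1(P(T <= t)) computed from the upper tail for stability
    z[ok] = norm.isf(t_dist.sf(t[ok], df[ok]))
    z[~np.isfinite(z) & (t > 0)] = _Z_CAP
    z[~np.isfinite(z) & (t < 0)] = -_Z_CAP
    z[~ok & np.isnan(t)] = 0.0  # zero variance, equal means
    z[~ok & (t == np.inf)] = _Z_CAP
    z[~ok & (t == -np.inf)] = -_Z_CAP
    return np.nan_to_num(z, nan=0.0, posinf=_Z_CAP, neginf=-_Z_CAP)


def _usable(labels_by_p: list[np.ndarray], participants: list) -> list[int]:
    keep = []
    for i, lab in enumerate(labels_by_p):
        if np.unique(lab).size == 2:
            keep.append(i)
        else:
            warnings.warn(
                f"participant {participants[i]!r} has a single response label; excluded",
                stacklevel=3,
            )
    if not keep:
        raise ValueError("no participant with both response labels")
    return keep


def timepoint_statistic(
    epochs_by_participant: list[np.ndarray],
    labels_by_participant: list[np.ndarray],
    participants: list | None = None,
) -> np.ndarray:
    """Stouffer-combined Welch z per timepoint.

    ``epochs_by_participant[i]`` is an (n_trials_i x n_timepoints) epoch
    matrix; ``labels_by_participant[i]`` the binary trial labels (1 vs 0
    contrast, z > 0 where group 1 exceeds group 0). Participants with only
    one label present are excluded with a warning.
    """
    participants = participants or list(range(len(epochs_by_participant)))
    labels = [np.asarray(l).astype(int) for l in labels_by_participant]
    keep = _usable(labels, participants)
    zs = [
        _welch_z(e[l == 1], e[l == 0])
        for e, l in ((epochs_by_participant[i], labels[i]) for i in keep)
    ]
    return np.sum(zs, axis=0) / np.sqrt(len(zs))


def _clusters_from_z(z: np.ndarray, thresh: float) -> list[tuple[int, int, float]]:
    """Maximal runs of |z| > thresh as (i_start, i_end inclusive, mass)."""
    supra = np.abs(z) > thresh
    out = []
    i = 0
    n = len(z)
    while i < n:
        if supra[i]:
            j = i
            while j + 1 < n and supra[j + 1]:
                j += 1
            out.append((i, j, float(np.abs(z[i : j + 1]).sum())))
            i = j + 1
        else:
            i += 1
    return out


def _perm_welch_z(e: np.ndarray, perm_labels: np.ndarray) -> np.ndarray:
    """Welch z for many label permutations at once.

    ``perm_labels`` is (n_perm x n_trials) binary. Returns (n_perm x T).
    """
    n1 = perm_labels.sum(axis=1, keepdims=True).astype(float)
    n0 = perm_labels.shape[1] - n1
    e2 = e**2
    s1 = perm_labels @ e
    s1_sq = perm_labels @ e2
    s0 = e.sum(axis=0) - s1
    s0_sq = e2.sum(axis=0) - s1_sq
    m1, m0 = s1 / n1, s0 / n0
    v1 = (s1_sq - n1 * m1**2) / (n1 - 1)
    v0 = (s0_sq - n0 * m0**2) / (n0 - 1)
    v1 = np.clip(v1, 0.0, None)
    v0 = np.clip(v0, 0.0, None)
    se2 = v1 / n1 + v0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v0**2 / (n0**2 * (n0 - 1)))
    z = np.zeros_like(t)
    ok = np.isfinite(t) & np.isfinite(df) & (df > 0)
    z[ok] = norm.isf(t_dist.sf(t[ok], df[ok]))
    return np.nan_to_num(z, nan=0.0, posinf=_Z_CAP, neginf=-_Z_CAP)


def cluster_permutation_test(
    epochs_by_participant: list[np.ndarray],
    labels_by_participant: list[np.ndarray],
    epoch_times: np.ndarray,
    participants: list | None = None,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Two-sided max-cluster-mass permutation test.

    Observed clusters are runs where |z| exceeds the two-sided
    ``Phi^-1(1 - cluster_alpha/2)`` threshold; each cluster's p-value is
    ``(1 + #{null max masses >= mass}) / (1 + n_perm)`` with the null built
    by permuting response labels independently within each participant.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    participants = participants or list(range(len(epochs_by_participant)))
    labels = [np.asarray(l).astype(int) for l in labels_by_participant]
    for lab in labels:
        if np.unique(lab).size < 2 and len(labels) == 1:
            raise ValueError("all labels identical")
    keep = _usable(labels, participants)
    epochs = [np.asarray(epochs_by_participant[i], float) for i in keep]
    labels = [labels[i] for i in keep]

    z_obs = np.sum(
        [_welch_z(e[l == 1], e[l == 0]) for e, l in zip(epochs, labels)], axis=0
    ) / np.sqrt(len(epochs))
    thresh = norm.ppf(1.0 - cluster_alpha / 2.0)
    runs = _clusters_from_z(z_obs, thresh)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z_null = np.zeros((n_perm, len(epoch_times)))
    for e, l in zip(epochs, labels):
        perm_labels = np.tile(l, (n_perm, 1))
        perm_labels = rng.permuted(perm_labels, axis=1)
        z_null += _perm_welch_z(e, perm_labels)
    z_null /= np.sqrt(len(epochs))

    null_max = np.empty(n_perm)
    for k in range(n_perm):
        row_runs = _clusters_from_z(z_null[k], thresh)
        null_max[k] = max((m for _, _, m in row_runs), default=0.0)

    clusters = [
        Cluster(
            t_start=float(epoch_times[i0]),
            t_end=float(epoch_times[i1]),
            mass=mass,
            p_value=float((1 + np.sum(null_max >= mass)) / (1 + n_perm)),
        )
        for i0, i1, mass in runs
    ]
    return ClusterResult(
        stat_series=z_obs,
        epoch_times=np.asarray(epoch_times, float),
        clusters=clusters,
        n_perm=n_perm,
        cluster_alpha=cluster_alpha,
        seed=seed,
        null_masses=null_max,
    )
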