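"""Feature-stability analysis: how cluster bounds move when one subject is
excluded from feature extraction, and whether that movement predicts
classification accuracy.

For cluster i with common bounds (all subjects) and individual bounds
(one subject excluded), the percent changes are

    delta_f_i = (|f1_ind - f1_com| + |f2_ind - f2_com|) / (2 (f2_com - f1_com)) * 100
    delta_t_i = (|t1_ind - t1_com| + |t2_ind - t2_com|) / (2 (t2_com - t1_com)) * 100

— symmetric in which bound moved, scale-covariant, and zero exactly when
the intervals coincide.  A cluster can be absent from a leave-one-out run;
the record then carries ``present=False`` and no deltas (never imputed).

Accuracy is regressed on the per-cluster deltas by ordinary least squares
(accuracy is the response; the deltas are the predictors), on complete
cases only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusterstats import Cluster, ClusterSettings, cluster_permutation_test
from .montage import NeighborGraph


def _interval_delta(common: tuple[float, float], individual: tuple[float, float]) -> float:
    c1, c2 = map(float, common)
    i1, i2 = map(float, individual)
    width = c2 - c1
    if width <= 0:
        raise ValueError(f"common interval [{c1}, {c2}] has non-positive width")
    return (abs(i1 - c1) + abs(i2 - c2)) / (2.0 * width) * 100.0


def delta_f(common: tuple[float, float], individual: tuple[float, float]) -> float:
    """Percent change of a cluster's frequency bounds (see module docstring)."""
    return _interval_delta(common, individual)


def delta_t(common: tuple[float, float], individual: tuple[float, float]) -> float:
    """Percent change of a cluster's time bounds (see module docstring)."""
    return _interval_delta(common, individual)


def _box_overlap(a_f, a_t, b_f, b_t) -> float:
    """Area of the time-frequency box intersection."""
    df = min(a_f[1], b_f[1]) - max(a_f[0], b_f[0])
    dt = min(a_t[1], b_t[1]) - max(a_t[0], b_t[0])
    return max(0.0, df) * max(0.0, dt)


def match_clusters(common: list[Cluster], candidates: list[Cluster]) -> list[Cluster | None]:
    """For each common cluster, the same-polarity candidate with maximal
    time-frequency box overlap (None when no overlapping candidate exists).

    A candidate is consumed by at most one common cluster (greedy by
    overlap, largest first).
    """
    assigned: list[Cluster | None] = [None] * len(common)
    taken: set[int] = set()
    pairs = []
    for i, com in enumerate(common):
        for j, cand in enumerate(candidates):
            if cand.polarity != com.polarity:
                continue
            ov = _box_overlap(com.f_bounds, com.t_bounds, cand.f_bounds, cand.t_bounds)
            if ov > 0:
                pairs.append((ov, i, j))
    for ov, i, j in sorted(pairs, reverse=True):
        if assigned[i] is None and j not in taken:
            assigned[i] = candidates[j]
            taken.add(j)
    return assigned


@dataclass
class StabilityRecord:
    """Bounds and deltas of one (excluded subject, cluster) pair."""

    excluded_subject: int
    cluster_index: int
    present: bool
    f_bounds_ind: tuple[float, float] | None = None
    t_bounds_ind: tuple[float, float] | None = None
    delta_f: float | None = None
    delta_t: float | None = None


def loso_cluster_bounds(
    ersp_ha: np.ndarray,
    ersp_la: np.ndarray,
    common_clusters: list[Cluster],
    graph: NeighborGraph,
    freqs: np.ndarray,
    times: np.ndarray,
    channels: tuple[str, ...] | None = None,
    settings: ClusterSettings | None = None,
    seed: int = 0,
    subject_ids: list[int] | None = None,
    significant_only: bool = True,
) -> list[StabilityRecord]:
    """Re-extract clusters with each subject excluded in turn.

    Reruns the identical cluster pipeline (same settings, same seed
    policy) on the remaining subjects, matches the resulting clusters to
    the common ones by box overlap, and records individual bounds and
    delta metrics.  ``common_clusters`` must carry extracted bounds.
    """
    settings = settings or ClusterSettings()
    n = ersp_ha.shape[0]
    if n < 4:
        raise ValueError("need >= 4 subjects (>= 3 remaining after exclusion)")
    ids = list(subject_ids) if subject_ids is not None else list(range(n))
    records: list[StabilityRecord] = []
    for k in range(n):
        keep = np.arange(n) != k
        obs, _ = cluster_permutation_test(
            ersp_ha[keep], ersp_la[keep], graph, freqs, times,
            channels=channels, settings=settings, seed=seed)
        if significant_only:
            obs = [c for c in obs if c.significant]
        matched = match_clusters(common_clusters, obs)
        for ci, m in enumerate(matched):
            if m is None:
                records.append(StabilityRecord(ids[k], ci, present=False))
            else:
                com = common_clusters[ci]
                records.append(StabilityRecord(
                    ids[k], ci, present=True,
                    f_bounds_ind=m.f_bounds, t_bounds_ind=m.t_bounds,
                    delta_f=delta_f(com.f_bounds, m.f_bounds),
                    delta_t=delta_t(com.t_bounds, m.t_bounds)))
    return records


def records_to_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "excluded_subject": r.excluded_subject,
            "cluster_index": r.cluster_index,
            "present": r.present,
            "f1_ind": None if r.f_bounds_ind is None else r.f_bounds_ind[0],
            "f2_ind": None if r.f_bounds_ind is None else r.f_bounds_ind[1],
            "t1_ind": None if r.t_bounds_ind is None else r.t_bounds_ind[0],
            "t2_ind": None if r.t_bounds_ind is None else r.t_bounds_ind[1],
            "delta_f": r.delta_f,
            "delta_t": r.delta_t,
        })
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    """OLS summary: accuracy ~ deltas (complete cases)."""

    coefficients: dict[str, float]
    standardized_betas: dict[str, float]
    r_squared: float
    f_statistic: float
    f_pvalue: float
    coef_pvalues: dict[str, float]
    n_cases: int

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "standardized_betas": self.standardized_betas,
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "coef_pvalues": self.coef_pvalues,
            "n_cases": self.n_cases,
        }


def accuracy_regression(accuracies: pd.Series | dict, deltas: pd.DataFrame,
                        ) -> RegressionResult:
    """OLS of per-subject accuracy on per-subject delta predictors.

    ``deltas`` is indexed by subject with one column per predictor (e.g.
    delta_t per cluster); rows with any missing value are dropped
    (subjects lacking a cluster), as are their accuracies.  Raises when
    fewer complete cases remain than predictors + 1 or when a predictor
    has zero variance.
    """
    import statsmodels.api as sm

    acc = pd.Series(accuracies)
    df = deltas.copy()
    df = df.loc[df.index.intersection(acc.index)].dropna()
    y = acc.loc[df.index].astype(float)
    if len(df) < df.shape[1] + 2:
        raise ValueError(f"only {len(df)} complete cases for {df.shape[1]} predictors")
    if np.any(df.std(ddof=1) == 0):
        raise ValueError("zero-variance predictor")
    X = sm.add_constant(df.astype(float))
    fit = sm.OLS(y, X).fit()
    sy = y.std(ddof=1)
    betas = {c: float(fit.params[c] * df[c].std(ddof=1) / sy) for c in df.columns}
    return RegressionResult(
        coefficients={c: float(v) for c, v in fit.params.items()},
        standardized_betas=betas,
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        coef_pvalues={c: float(v) for c, v in fit.pvalues.items()},
        n_cases=int(fit.nobs),
    )
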