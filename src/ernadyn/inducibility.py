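"""Virus-inducibility scoring of expression time courses.

Two indices drive the inducible call:

* amplitude index ``AI = log2[ max_{t <= 24 h} (e(t)+eps) / (e(0)+eps) ]`` —
  the maximum log fold increase within the first 24 hours (the 0 h point is
  included in the max, so AI >= 0);
* continuity index ``CI`` — the lag-1 (one-step-delayed) Pearson
  autocorrelation of the series, which rejects profiles dominated by
  uncorrelated noise.

A locus is called inducible when AI > 1 and CI > 0.2 (strict inequalities).
Responsive profiles are grouped into inducible-early / inducible-late /
repressed classes with a deterministic PAM (k-medoids) clustering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import DEFAULT_PSEUDOCOUNT, ExpressionMatrix, TimeGrid, log_fold_change

AI_THRESHOLD = 1.0
CI_THRESHOLD = 0.2
AI_TIME_MAX = 24.0

CLUSTER_NAMES = ("inducible_early", "inducible_late", "repressed")


@dataclass
class InducibilityScore:
    locus: str
    ai: float
    ci: float
    inducible: bool
    cluster: str = "none"


def amplitude_index(
    series,
    timegrid: TimeGrid,
    t_max: float = AI_TIME_MAX,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Maximum log2 fold increase over time points at or before ``t_max``."""
    e = np.asarray(series, dtype=float)
    t = np.asarray(timegrid.hours, dtype=float)
    if e.shape[0] != t.shape[0]:
        raise ValueError("series and time grid length mismatch")
    if np.all(np.isnan(e)):
        raise ValueError("all-missing series")
    mask = t <= t_max
    if mask.sum() < 2:
        raise ValueError("need at least two time points at or before t_max")
    ratios = (e[mask] + pseudocount) / (e[0] + pseudocount)
    return float(np.log2(np.nanmax(ratios)))


def continuity_index(series) -> float:
    """Lag-1 Pearson autocorrelation; 0 when either lagged vector is constant."""
    e = np.asarray(series, dtype=float)
    if e.shape[0] < 3:
        raise ValueError("continuity index needs at least 3 points")
    a, b = e[:-1], e[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def score_inducibility(
    m: ExpressionMatrix,
    ai_thr: float = AI_THRESHOLD,
    ci_thr: float = CI_THRESHOLD,
    t_max: float = AI_TIME_MAX,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """AI, CI and the inducible flag for every locus of an RPKM matrix."""
    e = m.values.values
    t = np.asarray(m.timegrid.hours)
    mask = t <= t_max
    ratios = (e[:, mask] + pseudocount) / (e[:, [0]] + pseudocount)
    ai = np.log2(ratios.max(axis=1))
    ci = np.array([continuity_index(row) for row in e])
    return pd.DataFrame(
        {
            "AI": ai,
            "CI": ci,
            "inducible": call_inducible(ai, ci, ai_thr, ci_thr),
        },
        index=m.values.index,
    )


def call_inducible(ai, ci, ai_thr: float = AI_THRESHOLD, ci_thr: float = CI_THRESHOLD):
    """Strict AI/CI thresholding."""
    return (np.asarray(ai) > ai_thr) & (np.asarray(ci) > ci_thr)


# -- PAM (k-medoids) clustering ---------------------------------------------

def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        # gain of adding candidate j: sum of reductions in nearest-medoid cost
        gains = np.maximum(current[:, None] - d, 0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return sorted(medoids)


def _pam_swap(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    n, k = d.shape[0], len(medoids)

    def cost(meds):
        return float(d[:, meds].min(axis=1).sum())

    best = cost(medoids)
    while True:
        best_swap, best_cost = None, best
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                c = cost(medoids[:mi] + [h] + medoids[mi + 1 :])
                if c < best_cost - 1e-12:
                    best_swap, best_cost = (mi, h), c
        if best_swap is None:
            return sorted(medoids), best
        mi, h = best_swap
        medoids = sorted(medoids[:mi] + [h] + medoids[mi + 1 :])
        best = best_cost


def pam_medoids(
    d: np.ndarray, k: int, n_restarts: int = 0, seed: int = 0
) -> tuple[list[int], float]:
    """PAM: greedy BUILD initialisation, then steepest-descent SWAP.

    Each SWAP pass evaluates every (medoid, non-medoid) exchange and applies
    the single best cost-reducing one; ties break on the smallest (slot,
    candidate) indices via the stable scan order, so the default run is
    fully deterministic. ``n_restarts`` extra runs from random initial
    medoid sets (seeded) guard against local optima on small inputs.
    Returns medoid indices and total cost (sum of distances to the nearest
    medoid).
    """
    n = d.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles n={n}")
    medoids, best = _pam_swap(d, _pam_build(d, k))
    if n_restarts:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            init = sorted(int(i) for i in rng.choice(n, size=k, replace=False))
            m, c = _pam_swap(d, init)
            if c < best - 1e-12:
                medoids, best = m, c
    return medoids, best


def pam_cluster_profiles(
    profiles: pd.DataFrame,
    timegrid: TimeGrid,
    k: int = 3,
) -> pd.Series:
    """Cluster responsive log-fold-change profiles into the three temporal
    classes with PAM under Euclidean distance.

    Cluster labels are assigned from the medoid shape: a medoid whose
    dominant change is negative is ``repressed``; otherwise the peak time
    decides ``inducible_early`` (<= 24 h) vs ``inducible_late``.
    """
    X = profiles.values
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    medoids, _ = pam_medoids(d, k)
    assign = np.argmin(d[:, medoids], axis=1)
    t = np.asarray(timegrid.hours)
    names = []
    for m in medoids:
        prof = X[m]
        if abs(prof.min()) > abs(prof.max()):
            names.append("repressed")
        elif t[int(np.argmax(prof))] <= AI_TIME_MAX:
            names.append("inducible_early")
        else:
            names.append("inducible_late")
    # disambiguate duplicated shape labels deterministically
    seen: dict[str, int] = {}
    final = []
    for nm in names:
        seen[nm] = seen.get(nm, 0) + 1
        final.append(nm if seen[nm] == 1 else f"{nm}_{seen[nm]}")
    return pd.Series([final[a] for a in assign], index=profiles.index, name="cluster")


def select_responsive(
    m: ExpressionMatrix,
    ci_thr: float = CI_THRESHOLD,
    min_abs_lfc: float = 1.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Responsive-locus preselection for clustering: lag-1 autocorrelation
    above ``ci_thr`` (noise control) and maximum absolute log2 fold change
    above ``min_abs_lfc`` anywhere in the course."""
    lfc = log_fold_change(m, pseudocount=pseudocount)
    ci = np.array([continuity_index(row) for row in m.values.values])
    keep = (ci > ci_thr) & (lfc.abs().max(axis=1).values > min_abs_lfc)
    return lfc.loc[keep]
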