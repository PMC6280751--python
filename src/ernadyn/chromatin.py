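"""3C qPCR interaction quantification and eRNA-knockdown effect analysis.

Interaction frequencies follow the crosslinking-qPCR convention
``frequency = 2^(dCt_sample - dCt_control)`` with the BAC-library control
in the exponent; note this printed sign convention runs opposite to the
usual qPCR algebra, where a larger Ct means less product — supply dCt
values on this convention, or enable ``negate_exponent`` for standard
2^-ddCt behaviour. Replicate frequencies are combined by geometric mean
(equivalently, replicate dCt differences are averaged before
exponentiation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KDRecord:
    sirna: str
    enhancer: str
    gene: str
    efold: float  # eRNA fold vs scrambled-siRNA control
    mfold: float  # mRNA fold vs control

    def __post_init__(self):
        if self.efold <= 0 or self.mfold <= 0:
            raise ValueError("fold changes must be positive")


EFOLD_THRESHOLD = 0.7


def interaction_frequency(
    dct_sample, dct_control, negate_exponent: bool = False
) -> float:
    """2^(dCt_sample - dCt_control), averaging replicate dCt values first.

    Scalar inputs give the single-measurement frequency; array inputs are
    treated as replicates (mean dCt difference, i.e. geometric-mean
    frequency). ``negate_exponent`` flips to the standard 2^-ddCt form.
    """
    s = np.atleast_1d(np.asarray(dct_sample, dtype=float))
    c = np.atleast_1d(np.asarray(dct_control, dtype=float))
    if not (np.isfinite(s).all() and np.isfinite(c).all()):
        raise ValueError("dCt values must be finite")
    delta = s.mean() - c.mean()
    if negate_exponent:
        delta = -delta
    return float(2.0 ** delta)


def frequency_trajectory(
    ct_table: pd.DataFrame, pair: str, negate_exponent: bool = False
) -> pd.Series:
    """Per-time-point interaction frequencies for one pair from a Ct table
    with columns pair_id, time_h, library ('sample'/'control_BAC'),
    replicate, ct."""
    sub = ct_table[ct_table.pair_id == pair]
    out = {}
    for t, g in sub.groupby("time_h"):
        s = g[g.library == "sample"].ct.values
        c = g[g.library == "control_BAC"].ct.values
        if len(s) == 0 or len(c) == 0:
            raise ValueError(f"pair {pair} at {t} h lacks a sample or control library")
        out[float(t)] = interaction_frequency(s, c, negate_exponent)
    return pd.Series(out).sort_index()


def interaction_fold_change(
    freqs: pd.Series, peak: float = 12.0, baseline: float = 0.0
) -> float:
    """log2 frequency ratio at the interaction peak (12 h) vs baseline (0 h)."""
    for t in (peak, baseline):
        if t not in freqs.index:
            raise ValueError(f"time point {t} h missing from trajectory")
    if freqs[baseline] <= 0:
        raise ValueError("zero baseline frequency")
    return float(np.log2(freqs[peak] / freqs[baseline]))


def ks_compare(group_a, group_b, alternative: str = "two-sided"):
    """Two-sample Kolmogorov-Smirnov test: D = sup|ECDF_a - ECDF_b|.

    Uses the exact null distribution when n_a * n_b <= 100, the asymptotic
    one otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    method = "exact" if len(a) * len(b) <= 100 else "asymp"
    res = stats.ks_2samp(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def kd_effect(
    records: list[KDRecord],
    efold_thr: float = EFOLD_THRESHOLD,
    dead_zone: float = 0.0,
) -> pd.DataFrame:
    """Per-EP-pair knockdown classification restricted to effective siRNAs.

    Records with eFold >= ``efold_thr`` are excluded as ineffective
    knockdowns. Effective records are aggregated per (enhancer, gene) by the
    best (lowest) eFold and classified by mRNA fold: < 1-dead_zone
    repressed, > 1+dead_zone activated, otherwise unchanged.
    """
    rows = []
    best: dict[tuple[str, str], KDRecord] = {}
    for r in records:
        if r.efold >= efold_thr:
            continue
        key = (r.enhancer, r.gene)
        if key not in best or r.efold < best[key].efold:
            best[key] = r
    for (enh, gene), r in sorted(best.items()):
        if r.mfold < 1.0 - dead_zone:
            cls = "repressed"
        elif r.mfold > 1.0 + dead_zone:
            cls = "activated"
        else:
            cls = "unchanged"
        rows.append(
            {
                "enhancer": enh,
                "gene": gene,
                "sirna": r.sirna,
                "efold": r.efold,
                "mfold": r.mfold,
                "effect": cls,
            }
        )
    return pd.DataFrame(rows, columns=["enhancer", "gene", "sirna", "efold", "mfold", "effect"])


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"pair_id", "time_h", "library", "replicate", "ct"}
    if not need <= set(df.columns):
        raise ValueError(f"Ct table missing columns {sorted(need - set(df.columns))}")
    if (df.ct <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def read_kd_table(path) -> list[KDRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        KDRecord(r.sirna_id, r.enhancer_id, r.gene_id, float(r.efold), float(r.mfold))
        for r in df.itertuples()
    ]
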