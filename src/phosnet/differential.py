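"""Differential phosphosite abundance from spectral counts.

Counts for each quantification unit are modelled as Poisson with per-sample
library-size offsets.  The test contrasts a common rate against
condition-specific rates via a likelihood-ratio statistic (chi-square, 1 df)
and controls the FDR with Benjamini--Hochberg.  Fold changes are reported on
the natural-log scale, treatment (HFD) relative to reference (LFD), with a
small pseudo-count guarding zero totals; a site is called regulated when it
changes at least ``fold_min``-fold at FDR <= ``fdr_max`` (defaults: 2-fold,
10% FDR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, ParameterError
from .quant import SiteCountMatrix

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DifferentialSite:
    """Per-unit differential result: ln fold change, LRT p, BH q, call."""

    unit_key: str
    log_fold_change: float
    statistic: float
    p_value: float
    fdr: float
    direction: str  # up / down / unchanged


def _poisson_lrt(y_t: float, y_r: float, l_t: float, l_r: float) -> float:
    """2*(ll1 - ll0) for condition-specific vs common Poisson rates.

    Offsets l_t, l_r are condition library totals; zero-count terms
    contribute nothing (x log x -> 0).
    """
    y = y_t + y_r
    l_tot = l_t + l_r
    if y == 0:
        return 0.0

    def xlogx(x: float, rate: float) -> float:
        return x * math.log(x / rate) if x > 0 else 0.0

    mu0 = y / l_tot
    ll_diff = xlogx(y_t, mu0 * l_t) + xlogx(y_r, mu0 * l_r)
    return max(0.0, 2.0 * ll_diff)


def test_differential(
    matrix: SiteCountMatrix,
    design: Mapping[str, str] | None = None,
    pseudo_count: float = 0.5,
    treatment: str = "HFD",
    reference: str = "LFD",
    fold_min: float = 2.0,
    fdr_max: float = 0.10,
) -> list[DifferentialSite]:
    """Likelihood-ratio test of differential abundance per unit.

    ``design`` maps sample id to condition (defaults to the conditions
    recorded in the matrix).  The log fold change is
    ``ln[(Y_t + pc) / N_t] - ln[(Y_r + pc) / N_r]`` where ``Y_c`` is the
    unit's count total in condition ``c`` and ``N_c`` the condition's
    library total.  BH ties are broken by unit key order so results are
    deterministic.
    """
    if pseudo_count <= 0:
        raise ParameterError("pseudo_count must be positive")
    design = dict(design) if design is not None else dict(matrix.conditions)
    conditions = set(design.values())
    if conditions != {treatment, reference}:
        raise DesignError(
            f"design must contain exactly conditions {{{treatment}, {reference}}}, "
            f"got {sorted(conditions)}"
        )
    t_samples = [s for s in matrix.samples if design.get(s) == treatment]
    r_samples = [s for s in matrix.samples if design.get(s) == reference]
    if not t_samples or not r_samples:
        raise DesignError("each condition needs at least one sample in the matrix")

    counts = matrix.counts
    y_t = counts[t_samples].sum(axis=1).to_numpy(dtype=float)
    y_r = counts[r_samples].sum(axis=1).to_numpy(dtype=float)
    n_t = float(counts[t_samples].to_numpy().sum())
    n_r = float(counts[r_samples].to_numpy().sum())
    if n_t == 0 or n_r == 0:
        raise DesignError("a condition has zero total counts; cannot form offsets")

    lfc = np.log((y_t + pseudo_count) / n_t) - np.log((y_r + pseudo_count) / n_r)
    stats_v = np.array(
        [_poisson_lrt(a, b, n_t, n_r) for a, b in zip(y_t, y_r)]
    )
    pvals = stats.chi2.sf(stats_v, df=1)
    # all-zero units carry no evidence: p = 1, logFC = 0 by convention
    zero = (y_t + y_r) == 0
    pvals[zero] = 1.0
    lfc[zero] = 0.0
    stats_v[zero] = 0.0

    order = pd.DataFrame(
        {"unit_key": counts.index, "p": pvals}
    ).sort_values(["p", "unit_key"], kind="mergesort")
    q_sorted = multipletests(order["p"].to_numpy(), method="fdr_bh")[1]
    qvals = pd.Series(q_sorted, index=order["unit_key"]).reindex(counts.index).to_numpy()

    results = []
    for key, l, s, p, q in zip(counts.index, lfc, stats_v, pvals, qvals):
        if q <= fdr_max and l >= math.log(fold_min):
            direction = "up"
        elif q <= fdr_max and l <= -math.log(fold_min):
            direction = "down"
        else:
            direction = "unchanged"
        results.append(
            DifferentialSite(
                unit_key=str(key),
                log_fold_change=float(l),
                statistic=float(s),
                p_value=float(p),
                fdr=float(q),
                direction=direction,
            )
        )
    return results


def classify_regulated(
    results: Sequence[DifferentialSite],
    fold_min: float = 2.0,
    fdr_max: float = 0.10,
) -> tuple[set[str], set[str]]:
    """Split results into up/down sets at ``fold_min``-fold, FDR ``fdr_max``."""
    if fold_min < 1:
        raise ParameterError("fold_min must be >= 1")
    if not 0.0 <= fdr_max <= 1.0:
        raise ParameterError("fdr_max must lie in [0, 1]")
    threshold = math.log(fold_min)
    up = {
        r.unit_key
        for r in results
        if r.fdr <= fdr_max and r.log_fold_change >= threshold
    }
    down = {
        r.unit_key
        for r in results
        if r.fdr <= fdr_max and r.log_fold_change <= -threshold
    }
    return up, down


def log_to_fold(log_fold_change: float) -> float:
    """Linear fold-change magnitude under the natural-log convention."""
    return math.exp(abs(log_fold_change))


def results_to_frame(results: Sequence[DifferentialSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_key": [r.unit_key for r in results],
            "log_fold_change": [r.log_fold_change for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "direction": [r.direction for r in results],
        }
    )
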