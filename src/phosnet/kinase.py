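"""Kinase-activity inference from direction-classified phosphosites.

Kinase--substrate predictions are first filtered (NetworKIN score > 2 or
NetPhorest probability > 0.1; restriction to kinases detected in the
phosphoproteome).  Each kinase is then tested for enrichment of its
substrates among the up- and down-regulated site groups with a
hypergeometric upper tail over the detected-phosphopeptide background.
Kinases significant in exactly one group are assigned the corresponding
condition (up -> HFD, down -> LFD); kinases significant in both are
disambiguated by a KSEA z-score on their substrates' mean log2 fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, ParameterError

NETWORKIN_SCORE_MIN = 2.0
NETPHOREST_PROB_MIN = 0.1


@dataclass(frozen=True)
class KinaseResult:
    """Enrichment of one kinase's substrates in one direction group."""

    kinase: str
    source: str
    group: str  # up / down
    k: int  # kinase substrates in the group
    K: int  # kinase substrates in the background
    n: int  # group size within the background
    N: int  # background size
    p_value: float
    significant: bool
    ksea_z: float | None = None
    assigned_condition: str | None = None  # HFD / LFD / ambiguous / None


def filter_ksrs(
    ksrs: pd.DataFrame,
    detected_kinases: Iterable[str],
    score_min: float = NETWORKIN_SCORE_MIN,
    prob_min: float = NETPHOREST_PROB_MIN,
) -> pd.DataFrame:
    """Score-filter NetworKIN rows and restrict to detected kinases.

    NetworKIN-source rows survive iff score > ``score_min`` OR probability
    > ``prob_min`` (both strict).  iGPS rows carry no scores (pre-filtered
    upstream at 10% FPR) and pass unconditionally.
    """
    detected = set(detected_kinases)
    is_nwk = ksrs["source"] == "networkin"
    score_ok = ksrs["networkin_score"].astype(float) > score_min
    prob_ok = ksrs["netphorest_probability"].astype(float) > prob_min
    keep = (~is_nwk) | score_ok.fillna(False) | prob_ok.fillna(False)
    out = ksrs[keep]
    return out[out["kinase"].isin(detected)].reset_index(drop=True)


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); returns 1 when k = 0."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ParameterError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_kinases(
    ksrs: pd.DataFrame,
    up_units: set[str],
    down_units: set[str],
    background_units: set[str],
    alpha: float = 1e-4,
    merge_sources: bool = False,
) -> list[KinaseResult]:
    """Hypergeometric enrichment per kinase and direction group.

    ``ksrs`` must carry ``kinase``, ``substrate`` (unit identifiers drawn
    from the same namespace as the unit sets) and ``source`` columns.
    Enrichment is computed separately per prediction source unless
    ``merge_sources``.  A kinase significant (p < alpha, strict) in exactly
    one group is assigned HFD (up) or LFD (down); significant in both is
    marked ``ambiguous`` pending KSEA.
    """
    if not background_units:
        raise ParameterError("background_units must be non-empty")
    if not up_units <= background_units or not down_units <= background_units:
        raise ParameterError("up/down units must be subsets of the background")
    N = len(background_units)
    groups = {"up": up_units, "down": down_units}

    key_cols = ["kinase"] if merge_sources else ["kinase", "source"]
    results: list[KinaseResult] = []
    for key, sub in ksrs.groupby(key_cols, sort=True):
        kinase = key[0] if isinstance(key, tuple) else key
        source = "merged" if merge_sources else key[1]
        substrates = set(sub["substrate"]) & background_units
        K = len(substrates)
        per_group: dict[str, KinaseResult] = {}
        for group, units in groups.items():
            k = len(substrates & units)
            n = len(units)
            p = hypergeometric_upper_tail(k, K, n, N)
            per_group[group] = KinaseResult(
                kinase=str(kinase),
                source=str(source),
                group=group,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=p,
                significant=p < alpha,
            )
        sig = [g for g in ("up", "down") if per_group[g].significant]
        if len(sig) == 1:
            assigned = "HFD" if sig[0] == "up" else "LFD"
        elif len(sig) == 2:
            assigned = "ambiguous"
        else:
            assigned = None
        for g in ("up", "down"):
            results.append(replace(per_group[g], assigned_condition=assigned))
    return results


def ksea_score(
    substrate_log2fc: Sequence[float], all_log2fc: Sequence[float]
) -> float:
    """KSEA z: mean substrate log2 fold change vs the global distribution.

    ``z = (mean(substrates) - mean(all)) * sqrt(m) / sd(all)`` with ``m``
    the substrate count and ``sd`` the population standard deviation of the
    full distribution.  Natural-log fold changes must be divided by ln 2
    before calling.
    """
    subs = np.asarray(substrate_log2fc, dtype=float)
    full = np.asarray(all_log2fc, dtype=float)
    if subs.size == 0:
        raise ParameterError("substrate fold-change list must be non-empty")
    sd = float(full.std(ddof=0))
    if sd == 0.0:
        raise ParameterError("global fold-change sd is zero; KSEA z undefined")
    return float((subs.mean() - full.mean()) * math.sqrt(subs.size) / sd)


def assign_activity(
    results: Sequence[KinaseResult], ksea_zs: Mapping[str, float]
) -> list[KinaseResult]:
    """Resolve ``ambiguous`` kinases by KSEA sign (z > 0 -> HFD, < 0 -> LFD)."""
    out: list[KinaseResult] = []
    for r in results:
        if r.assigned_condition == "ambiguous":
            if r.kinase not in ksea_zs:
                raise ConsistencyError(
                    f"no KSEA z supplied for ambiguous kinase {r.kinase}"
                )
            z = float(ksea_zs[r.kinase])
            if z > 0:
                assigned = "HFD"
            elif z < 0:
                assigned = "LFD"
            else:
                assigned = "ambiguous"
            out.append(replace(r, ksea_z=z, assigned_condition=assigned))
        else:
            out.append(r)
    return out


def kinase_results_to_frame(results: Sequence[KinaseResult]) -> pd.DataFrame:
    """Summary table shaped like the published kinase list.

    One row per significant kinase x group with its enrichment p, assigned
    condition, and prediction source.
    """
    rows = [
        {
            "kinase": r.kinase,
            "group": r.group,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p_value": r.p_value,
            "active_in": r.assigned_condition,
            "source": r.source,
            "ksea_z": r.ksea_z,
        }
        for r in results
        if r.significant
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "kinase",
            "group",
            "k",
            "K",
            "n",
            "N",
            "p_value",
            "active_in",
            "source",
            "ksea_z",
        ],
    )
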