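"""Observation-unit and lake-level aggregation of metric EQRs.

An OU x substrate score is the arithmetic mean of the selected metrics'
EQRs; when both mineral and macrophyte scores exist for an OU, the lower
one is kept (worst-case rule).  The lake index is a riparian-zone-weighted
average: OU scores are averaged within each riparian zone type, and the
per-type means are combined with the perimeter fractions Pc_type,

    IBDL = sum_type mean(Score_OU | type) * Pc_type,

with weights renormalized over the types that actually have scored OUs so
the index stays a convex combination (the dropped weight is reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_tables import RIPARIAN_TYPES

__all__ = ["OUScore", "LakeScore", "ou_substrate_score", "combine_substrates",
           "lake_ibdl", "score_lakes"]


@dataclass(frozen=True)
class OUScore:
    ou_id: str
    lake_id: str
    riparian_type: int
    score_mineral: float | None
    score_macrophyte: float | None
    score: float | None
    n_metrics_mineral: int = 0
    n_metrics_macrophyte: int = 0


@dataclass(frozen=True)
class LakeScore:
    lake_id: str
    ibdl: float | None
    per_type_means: dict = field(default_factory=dict)
    pc_type: dict = field(default_factory=dict)
    dropped_weight: float = 0.0
    n_ou_scored: int = 0
    n_ou_total: int = 0


def ou_substrate_score(metric_eqrs) -> float | None:
    """Mean of the available selected-metric EQRs; None when none computable."""
    values = pd.Series(list(metric_eqrs), dtype=float).dropna()
    if values.empty:
        return None
    return float(values.mean())


def combine_substrates(score_mineral: float | None,
                       score_macrophyte: float | None) -> float | None:
    """Final OU score: the minimum of the available substrate scores."""
    present = [s for s in (score_mineral, score_macrophyte) if s is not None]
    if not present:
        return None
    return min(present)


def lake_ibdl(ou_scores, pc_type: Mapping[int, float]) -> LakeScore:
    """Riparian-weighted lake score from scored OUs.

    ``ou_scores`` is an iterable of :class:`OUScore` (or any objects with
    ``score`` and ``riparian_type``) belonging to one lake; ``pc_type`` maps
    riparian type (1-4) to its perimeter fraction (summing to 1).  Types
    carrying weight but no scored OU are dropped and the remaining weights
    renormalized; a lake with no scored OU is returned unscored.
    """
    ou_scores = list(ou_scores)
    weights = {int(t): float(pc_type.get(t, pc_type.get(str(t), 0.0))) for t in RIPARIAN_TYPES}
    total = sum(weights.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"pc_type weights must sum to 1, got {total}")
    lake_id = ou_scores[0].lake_id if ou_scores else ""
    per_type = {}
    for t in RIPARIAN_TYPES:
        vals = [o.score for o in ou_scores if o.riparian_type == t and o.score is not None]
        if vals:
            # sort before averaging so the result is bit-identical under
            # any OU ordering
            per_type[t] = float(np.mean(np.sort(vals)))
    n_scored = sum(1 for o in ou_scores if o.score is not None)
    if not per_type:
        return LakeScore(lake_id=lake_id, ibdl=None, pc_type=weights,
                         dropped_weight=1.0, n_ou_scored=0, n_ou_total=len(ou_scores))
    represented = sum(weights[t] for t in per_type)
    dropped = 1.0 - represented
    if represented <= 0:
        # all scored OUs sit in zero-weight types: fall back to equal weights
        eff = {t: 1.0 / len(per_type) for t in per_type}
    else:
        eff = {t: weights[t] / represented for t in per_type}
    ibdl = float(sum(per_type[t] * eff[t] for t in per_type))
    return LakeScore(lake_id=lake_id, ibdl=ibdl, per_type_means=per_type,
                     pc_type=weights, dropped_weight=float(max(0.0, dropped)),
                     n_ou_scored=n_scored, n_ou_total=len(ou_scores))


def score_lakes(sample_eqr: pd.DataFrame, sample_meta: pd.DataFrame,
                lake_meta: pd.DataFrame):
    """Aggregate per-sample mean EQRs into OU and lake tables.

    ``sample_eqr`` is a samples x selected-variables table of EQR values.
    Returns ``(ou_df, lake_df)`` report DataFrames.
    """
    meta = sample_meta.set_index("sample_id")
    mean_eqr = sample_eqr.mean(axis=1, skipna=True)
    n_metrics = sample_eqr.notna().sum(axis=1)

    ou_rows = []
    grouping = meta.loc[sample_eqr.index].groupby(["lake_id", "ou_id"], sort=True)
    for (lake_id, ou_id), sub in grouping:
        scores = {}
        counts = {}
        for substrate in ("mineral", "macrophyte"):
            sids = sub.index[sub["substrate"] == substrate]
            vals = mean_eqr.loc[sids].dropna()
            scores[substrate] = float(vals.mean()) if not vals.empty else None
            counts[substrate] = int(n_metrics.loc[sids].max()) if len(sids) else 0
        final = combine_substrates(scores["mineral"], scores["macrophyte"])
        ou_rows.append(OUScore(
            ou_id=str(ou_id), lake_id=str(lake_id),
            riparian_type=int(sub["riparian_type"].iloc[0]),
            score_mineral=scores["mineral"], score_macrophyte=scores["macrophyte"],
            score=final, n_metrics_mineral=counts["mineral"],
            n_metrics_macrophyte=counts["macrophyte"],
        ))

    ou_df = pd.DataFrame([{
        "lake_id": o.lake_id, "ou_id": o.ou_id, "riparian_type": o.riparian_type,
        "score_mineral": o.score_mineral, "score_macrophyte": o.score_macrophyte,
        "score": o.score,
    } for o in ou_rows])

    lake_rows = []
    lakes = lake_meta.set_index("lake_id")
    for lake_id in sorted({o.lake_id for o in ou_rows}):
        if lake_id not in lakes.index:
            continue
        pc = {t: float(lakes.at[lake_id, f"pc_type_{t}"]) for t in RIPARIAN_TYPES}
        ls = lake_ibdl([o for o in ou_rows if o.lake_id == lake_id], pc)
        row = {"lake_id": lake_id, "ibdl": ls.ibdl, "n_ou_scored": ls.n_ou_scored,
               "n_ou_total": ls.n_ou_total, "dropped_weight": ls.dropped_weight}
        for t in RIPARIAN_TYPES:
            row[f"mean_score_type_{t}"] = ls.per_type_means.get(t)
        lake_rows.append(row)
    lake_df = pd.DataFrame(lake_rows)
    return ou_df, lake_df
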