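"""Calibration and scoring pipelines.

Calibration runs the three-step index construction on a calibration
dataset: (1) identify pressure-specific alert taxa with TITAN per
environmental variable, (2) build per-variable alert-richness metrics and
transform them through SES -> normalization -> EQR against reference
lakes, keeping only metrics whose Pearson correlation with their gradient
exceeds the threshold, and (3) freeze everything needed for deployment
into an :class:`~ibdl.io_tables.IndexModel` artifact.  Scoring applies a
calibrated model to new data without needing environmental measurements.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .io_tables import (CalibrationError, CountMatrix, IndexModel, VARIABLES,
                        validate_samples)
from . import titan
from . import metrics as mx
from . import aggregation as agg

__all__ = ["CalibrationSettings", "CalibrationResult", "ScoreResult",
           "calibrate", "score", "broadcast_env", "settings_hash"]


@dataclass(frozen=True)
class CalibrationSettings:
    """Thresholds and sizes of a calibration run (all spec'd defaults)."""

    seed: int = 0
    min_occurrence: int = 3
    minsplit: int = titan.DEFAULT_MINSPLIT
    n_perm: int = titan.DEFAULT_N_PERM
    n_boot: int = titan.DEFAULT_N_BOOT
    purity_min: float = titan.DEFAULT_PURITY_MIN
    reliability_min: float = titan.DEFAULT_RELIABILITY_MIN
    r_threshold: float = mx.PEARSON_R_THRESHOLD
    alert_rule: str = titan.DEFAULT_ALERT_RULE
    variables: tuple = VARIABLES
    reference_stat: str = "mean"
    validity_policy: str = "strict"


@dataclass
class CalibrationResult:
    model: IndexModel
    reports: dict = field(default_factory=dict)  # name -> DataFrame


@dataclass
class ScoreResult:
    sample_metrics: pd.DataFrame
    ou_scores: pd.DataFrame
    lake_scores: pd.DataFrame
    validity: pd.DataFrame
    warnings: list = field(default_factory=list)


def settings_hash(settings: CalibrationSettings) -> str:
    payload = json.dumps(asdict(settings), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Environmental broadcast
# ---------------------------------------------------------------------------

def broadcast_env(env: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Lake-scale environmental values broadcast to samples.

    Matching prefers the sample's own year, then the year before, then the
    year after; rows with a missing year act as wildcards.  Returns a
    samples x variables DataFrame (NaN where nothing matches).
    """
    years = pd.to_numeric(samples["date"].astype(str).str[:4], errors="coerce")
    lookup: dict = {}
    for row in env.itertuples(index=False):
        y = None if pd.isna(row.year) else int(row.year)
        lookup.setdefault((row.lake_id, row.variable), {})[y] = row.value
    variables = sorted(env["variable"].unique())
    data = np.full((len(samples), len(variables)), np.nan)
    for i, (lake, year) in enumerate(zip(samples["lake_id"], years)):
        y = None if pd.isna(year) else int(year)
        for j, var in enumerate(variables):
            d = lookup.get((lake, var))
            if not d:
                continue
            for candidate in ((y, y - 1, y + 1, None) if y is not None else (None,)):
                if candidate in d:
                    data[i, j] = d[candidate]
                    break
            else:
                if None in d:
                    data[i, j] = d[None]
    return pd.DataFrame(data, index=samples["sample_id"].to_numpy(), columns=variables)


def _sample_groups(samples: pd.DataFrame, lakes: pd.DataFrame) -> pd.DataFrame:
    """substrate / metatype per sample (index: sample_id)."""
    meta = samples.merge(lakes[["lake_id", "metatype"]], on="lake_id", how="left")
    meta["metatype"] = meta["metatype"].fillna("unknown")
    return meta.set_index("sample_id")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(counts: CountMatrix, samples: pd.DataFrame, lakes: pd.DataFrame,
              env: pd.DataFrame,
              settings: CalibrationSettings = CalibrationSettings()) -> CalibrationResult:
    """Run the full index calibration; raises CalibrationError when no
    variable survives or the reference pool is empty."""
    validity = validate_samples(counts, samples, policy=settings.validity_policy)
    valid_ids = validity.loc[validity["valid"], "sample_id"].tolist()
    if not valid_ids:
        raise CalibrationError("no valid samples after count-compliance screening")
    matrix = counts.subset_samples(valid_ids)
    samples_v = samples[samples["sample_id"].isin(valid_ids)].reset_index(drop=True)

    idx_taxa = titan.index_taxa(matrix, settings.min_occurrence)
    if not idx_taxa:
        raise CalibrationError("no index taxa pass the occurrence threshold")
    rel = matrix.relative_abundance()[idx_taxa]
    env_b = broadcast_env(env, samples_v)

    # --- TITAN per variable -------------------------------------------
    titan_tables = []
    alert_sets: dict = {}
    alert_pairs: dict = {}
    community: dict = {}
    var_status: dict = {}
    for var in settings.variables:
        if var not in env_b.columns:
            var_status[var] = "no_env"
            continue
        try:
            vres = titan.run_titan(
                rel, env_b[var], variable=var, seed=settings.seed,
                n_perm=settings.n_perm, n_boot=settings.n_boot,
                minsplit=settings.minsplit, purity_min=settings.purity_min,
                reliability_min=settings.reliability_min,
                alert_rule=settings.alert_rule,
            )
        except CalibrationError:
            var_status[var] = "no_env"
            continue
        titan_tables.append(titan.results_table(vres))
        if vres.alert.taxa:
            alert_sets[var] = vres.alert.codes()
            alert_pairs[var] = vres.alert.taxa
            community[var] = ({"plus": vres.community.cp_sumz_plus,
                               "minus": vres.community.cp_sumz_minus}
                              if vres.community else {"plus": None, "minus": None})
            var_status[var] = "candidate"
        else:
            var_status[var] = "no_signal"

    if not alert_sets:
        raise CalibrationError("no variable produced a non-empty alert-taxa set")

    # --- metric chain --------------------------------------------------
    groups = _sample_groups(samples_v, lakes)
    raw = mx.raw_metric_table(matrix, idx_taxa, alert_sets)
    substrate = groups.loc[raw.index, "substrate"]
    metatype = groups.loc[raw.index, "metatype"]
    ref_flags = mx.identify_reference_lakes(lakes)
    sample_lakes = groups.loc[raw.index, "lake_id"]

    gstats: dict = {}
    bounds: dict = {}
    refvals: dict = {}
    ses_df = pd.DataFrame(index=raw.index)
    sesnor_df = pd.DataFrame(index=raw.index)
    eqr_df = pd.DataFrame(index=raw.index)
    eqr_uncapped_df = pd.DataFrame(index=raw.index)
    for var in list(alert_sets):
        try:
            gs = mx.group_stats(raw[var], substrate, metatype)
        except CalibrationError:
            var_status[var] = "degenerate"
            for d in (alert_sets, alert_pairs, community):
                d.pop(var)
            continue
        key = (substrate + "|" + metatype)
        means = key.map({k: v[0] for k, v in gs.items()})
        sds = key.map({k: v[1] for k, v in gs.items()})
        s = (raw[var] - means) / sds
        lo, hi = float(np.nanmin(s)), float(np.nanmax(s))
        if not hi > lo:
            var_status[var] = "degenerate"
            for d in (alert_sets, alert_pairs, community):
                d.pop(var)
            continue
        sn = (s - lo) / (hi - lo)
        ref = mx.reference_value(sn, sample_lakes, ref_flags, stat=settings.reference_stat)
        if not ref > 0:
            raise CalibrationError(f"reference SESnor is 0 for {var!r}")
        gstats[var] = gs
        bounds[var] = (lo, hi)
        refvals[var] = ref
        ses_df[var] = s
        sesnor_df[var] = sn
        eqr_uncapped_df[var] = sn / ref
        eqr_df[var] = np.minimum(1.0, sn / ref)

    if not gstats:
        raise CalibrationError("all candidate variables degenerate")

    # --- selection (raw metric vs gradient, OU scale) -------------------
    ou_key = groups.loc[raw.index, "lake_id"] + "/" + groups.loc[raw.index, "ou_id"]
    metric_ou = raw[list(gstats)].groupby(ou_key).mean()
    env_ou = env_b.groupby(ou_key).mean()
    selection = mx.select_metrics(metric_ou, env_ou, settings.r_threshold)
    selected = tuple(sorted(selection.loc[selection["status"] == "selected", "variable"]))
    for _, row in selection.iterrows():
        var_status[row["variable"]] = row["status"]

    # --- substrate effect (report only) ---------------------------------
    sub_rows = []
    ou_of = groups.loc[raw.index, "lake_id"] + "/" + groups.loc[raw.index, "ou_id"]
    for var in list(gstats):
        wide = pd.DataFrame({
            "ou": ou_of, "substrate": substrate, "eqr": eqr_df[var],
        }).pivot_table(index="ou", columns="substrate", values="eqr", aggfunc="mean")
        emin = wide["mineral"] if "mineral" in wide else pd.Series(dtype=float)
        emac = wide["macrophyte"] if "macrophyte" in wide else pd.Series(dtype=float)
        stat, p, n = mx.substrate_effect_test(emin, emac)
        sub_rows.append({"variable": var, "statistic": stat, "p_value": p, "n_pairs": n})
    substrate_report = pd.DataFrame(sub_rows)

    provenance = {
        "seed": settings.seed,
        "settings": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(settings).items()},
        "config_hash": settings_hash(settings),
        "version": __version__,
    }
    model = IndexModel(
        index_taxa=tuple(idx_taxa),
        alert_taxa=alert_pairs,
        community_thresholds=community,
        group_stats=gstats,
        norm_bounds=bounds,
        reference_values=refvals,
        selected_metrics=selected,
        provenance=provenance,
    )
    model.validate()

    sel_info = selection.set_index("variable")
    status_report = pd.DataFrame([
        {
            "variable": var,
            "status": var_status.get(var, "no_env"),
            "pearson_r": sel_info["pearson_r"].get(var, np.nan),
            "n_pairs": int(sel_info["n_pairs"].get(var, 0)),
            "n_alert_taxa": len(alert_pairs.get(var, ())),
        }
        for var in settings.variables
    ])

    metric_long = pd.concat(
        {
            "raw": raw[list(gstats)], "ses": ses_df, "sesnor": sesnor_df,
            "eqr": eqr_df, "eqr_uncapped": eqr_uncapped_df,
        },
        axis=1,
    )
    metric_long.columns = [f"{stage}_{var}" for stage, var in metric_long.columns]
    metric_long.insert(0, "group", (substrate + "|" + metatype))
    metric_long.index.name = "sample_id"

    reports = {
        "titan": (pd.concat(titan_tables, ignore_index=True)
                  if titan_tables else pd.DataFrame()),
        "metrics": metric_long.reset_index(),
        "selection": status_report,
        "substrate_tests": substrate_report,
        "validity": validity,
    }
    return CalibrationResult(model=model, reports=reports)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score(model: IndexModel, counts: CountMatrix, samples: pd.DataFrame,
          lakes: pd.DataFrame, validity_policy: str = "strict") -> ScoreResult:
    """Score new data with a calibrated model (no env data needed)."""
    model.validate()
    warnings: list = []
    validity = validate_samples(counts, samples, policy=validity_policy)
    valid_ids = validity.loc[validity["valid"], "sample_id"].tolist()
    if not valid_ids:
        raise CalibrationError("no valid samples to score")
    matrix = counts.subset_samples(valid_ids)
    samples_v = samples[samples["sample_id"].isin(valid_ids)].reset_index(drop=True)

    unknown = sorted(set(matrix.taxon_codes) - set(model.index_taxa))
    if unknown:
        warnings.append(
            f"{len(unknown)} taxa absent from the model were ignored: "
            + ", ".join(unknown[:10]) + ("..." if len(unknown) > 10 else "")
        )

    groups = _sample_groups(samples_v, lakes)
    use_vars = list(model.selected_metrics)
    alert_sets = {v: [c for c, _ in model.alert_taxa[v]] for v in use_vars}
    raw = mx.raw_metric_table(matrix, model.index_taxa, alert_sets)

    substrate = groups.loc[raw.index, "substrate"]
    metatype = groups.loc[raw.index, "metatype"]
    eqr_df = pd.DataFrame(index=raw.index)
    rows_fallback = 0
    for var in use_vars:
        gs = model.group_stats[var]
        keys = substrate + "|" + metatype
        fallback = substrate + "|*"
        known = keys.isin(gs)
        use_keys = keys.where(known, fallback)
        rows_fallback += int((~known & use_keys.isin(gs)).sum())
        means = use_keys.map({k: v[0] for k, v in gs.items()})
        sds = use_keys.map({k: v[1] for k, v in gs.items()})
        s = (raw[var] - means) / sds
        sn = ((s - model.norm_bounds[var][0])
              / (model.norm_bounds[var][1] - model.norm_bounds[var][0])).clip(0.0, 1.0)
        eqr_df[var] = np.minimum(1.0, sn / model.reference_values[var])
    if rows_fallback:
        warnings.append(f"{rows_fallback} sample-metric values used substrate-pooled "
                        "group statistics (unseen substrate x metatype group)")

    ou_df, lake_df = agg.score_lakes(eqr_df, samples_v, lakes)
    unscored = lake_df["ibdl"].isna().sum() if len(lake_df) else 0
    if unscored:
        warnings.append(f"{unscored} lakes could not be scored")

    sample_metrics = eqr_df.copy()
    sample_metrics.insert(0, "group", substrate + "|" + metatype)
    sample_metrics.index.name = "sample_id"
    return ScoreResult(sample_metrics=sample_metrics.reset_index(),
                       ou_scores=ou_df, lake_scores=lake_df,
                       validity=validity, warnings=warnings)
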