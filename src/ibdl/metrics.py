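"""Per-variable metrics: alert-taxon richness, SES, normalization and EQR.

The raw metric for a pressure variable is one minus the fraction of alert
taxa among the index taxa present in a sample:

    Metric = 1 - Alert_taxa / Index_taxa

(both counted as presences, count > 0).  Raw values are standardized per
sample group (substrate type x lake alkalinity metatype),

    SES = (Metric - M_group) / sd_group,

rescaled to the calibration range,

    SESnor = (SES - Min) / (Max - Min),

and finally expressed as an ecological quality ratio against the
expectation under reference conditions,

    EQR = SESnor / SESnor_ref,

capped at 1 so index scores live in [0, 1].  Reference lakes are those with
< 0.4 % artificial land use and < 20 % agriculture in the catchment.
Metric variables are screened by the strength of their Pearson correlation
with their own gradient (|r| > 0.6 kept), and a paired Wilcoxon signed-rank
test reports (without gating) whether substrate type shifts the EQR at the
observation-unit scale.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CalibrationError, CountMatrix

__all__ = [
    "REFERENCE_MAX_ARTIFICIAL_PCT",
    "REFERENCE_MAX_AGRICULTURE_PCT",
    "PEARSON_R_THRESHOLD",
    "raw_metric",
    "raw_metric_table",
    "ses",
    "ses_normalize",
    "eqr",
    "group_stats",
    "identify_reference_lakes",
    "reference_value",
    "select_metrics",
    "substrate_effect_test",
]

REFERENCE_MAX_ARTIFICIAL_PCT = 0.4
REFERENCE_MAX_AGRICULTURE_PCT = 20.0
PEARSON_R_THRESHOLD = 0.6
MIN_WILCOXON_PAIRS = 6


# ---------------------------------------------------------------------------
# Raw metric (alert-taxon richness ratio)
# ---------------------------------------------------------------------------

def raw_metric(present_taxa: Iterable, alert_codes: Iterable, index_taxa: Iterable) -> float:
    """1 - (#alert taxa present / #index taxa present); NaN when no index
    taxon is present (metric undefined for the sample)."""
    index = set(index_taxa)
    present = set(present_taxa) & index
    if not present:
        return float("nan")
    alert_present = present & set(alert_codes)
    return 1.0 - len(alert_present) / len(present)


def raw_metric_table(matrix: CountMatrix, index_taxa: Iterable,
                     alert_sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """Raw metric per sample for every variable with an alert set.

    Returns a samples x variables DataFrame; NaN marks samples where no
    index taxon is present (flagged, excluded downstream).
    """
    index = [t for t in matrix.taxon_codes if t in set(index_taxa)]
    presence = matrix.counts[index] > 0
    n_present = presence.sum(axis=1).to_numpy(dtype=float)
    out = {}
    for var, alert in alert_sets.items():
        codes = [c for c in alert if c in presence.columns]
        n_alert = presence[codes].sum(axis=1).to_numpy(dtype=float) if codes else np.zeros(len(presence))
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = 1.0 - n_alert / n_present
        raw[n_present == 0] = np.nan
        out[var] = raw
    return pd.DataFrame(out, index=matrix.counts.index)


# ---------------------------------------------------------------------------
# SES / normalization / EQR
# ---------------------------------------------------------------------------

def ses(raw: float, m_group: float, sd_group: float) -> float:
    """Standardized effect size: (raw - group mean) / group sd."""
    if not sd_group > 0:
        raise CalibrationError("sd_group must be > 0")
    return (raw - m_group) / sd_group


def ses_normalize(value: float, bounds, clamp: bool = False) -> float:
    """Rescale an SES value by the calibration extremes ``bounds=(Min, Max)``.

    ``clamp=True`` (used when scoring out-of-calibration samples) truncates
    the result to [0, 1].
    """
    lo, hi = bounds
    if not hi > lo:
        raise CalibrationError("normalization requires Max > Min")
    out = (value - lo) / (hi - lo)
    if clamp:
        out = min(1.0, max(0.0, out))
    return out


def eqr(sesnor: float, reference: float, cap: bool = True) -> float:
    """Ecological quality ratio: observed / reference SESnor, capped at 1."""
    if not reference > 0:
        raise CalibrationError("reference SESnor must be > 0")
    value = sesnor / reference
    return min(1.0, value) if cap else value


def group_stats(raw: pd.Series, substrate: pd.Series, metatype: pd.Series) -> dict:
    """Mean/sd of the raw metric per substrate x metatype group, plus
    substrate-pooled fallbacks keyed ``"<substrate>|*"``.

    Groups with fewer than 2 values or zero spread are rejected: the SES
    transform is undefined there.
    """
    df = pd.DataFrame({"raw": raw, "substrate": substrate, "metatype": metatype}).dropna()
    out = {}
    for keys, sub in list(df.groupby(["substrate", "metatype"], sort=True)) + \
                     list(df.groupby(["substrate"], sort=True)):
        if isinstance(keys, tuple) and len(keys) == 2:
            key = f"{keys[0]}|{keys[1]}"
        else:
            key = f"{keys[0] if isinstance(keys, tuple) else keys}|*"
        mean = float(sub["raw"].mean())
        sd = float(sub["raw"].std(ddof=1)) if len(sub) > 1 else 0.0
        if not sd > 0:
            raise CalibrationError(f"group {key!r} has no spread (sd = 0, n = {len(sub)})")
        out[key] = (mean, sd)
    return out


# ---------------------------------------------------------------------------
# Reference conditions
# ---------------------------------------------------------------------------

def identify_reference_lakes(lake_meta: pd.DataFrame) -> pd.Series:
    """Reference flag per lake: < 0.4 % artificial land use AND < 20 %
    agriculture in the catchment (strict inequalities).  Lakes with missing
    land-use data are excluded from the reference pool."""
    art = pd.to_numeric(lake_meta["pct_artificial_landuse"], errors="coerce")
    agr = pd.to_numeric(lake_meta["pct_agriculture"], errors="coerce")
    flags = (art < REFERENCE_MAX_ARTIFICIAL_PCT) & (agr < REFERENCE_MAX_AGRICULTURE_PCT)
    flags &= art.notna() & agr.notna()
    return pd.Series(flags.to_numpy(), index=lake_meta["lake_id"].to_numpy(), name="reference")


def reference_value(sesnor: pd.Series, sample_lakes: pd.Series,
                    reference_flags: pd.Series, stat: str = "mean") -> float:
    """Expected SESnor under reference conditions.

    ``sesnor`` holds per-sample normalized values, ``sample_lakes`` maps the
    same index to lake ids.  The expectation is the mean (default; median
    selectable) over all valid samples of reference lakes.
    """
    ref_lakes = set(reference_flags.index[reference_flags])
    mask = sample_lakes.isin(ref_lakes) & sesnor.notna()
    values = sesnor[mask]
    if values.empty:
        raise CalibrationError("empty reference pool")
    if stat == "mean":
        return float(values.mean())
    if stat == "median":
        return float(values.median())
    raise ValueError(f"unknown reference statistic {stat!r}")


# ---------------------------------------------------------------------------
# Metric selection and substrate effect
# ---------------------------------------------------------------------------

def select_metrics(metric_ou: pd.DataFrame, env_ou: pd.DataFrame,
                   r_threshold: float = PEARSON_R_THRESHOLD) -> pd.DataFrame:
    """Pearson screen of candidate metrics against their own gradients.

    ``metric_ou`` and ``env_ou`` are OU x variables tables (pairwise-complete
    rows are used per variable).  Variables with |r| > ``r_threshold`` are
    kept; fewer than 3 complete pairs skips the variable.  Returns a report
    with one row per variable: r, n pairs and status.
    """
    rows = []
    for var in metric_ou.columns:
        if var not in env_ou.columns:
            rows.append((var, np.nan, 0, "skipped"))
            continue
        pair = pd.DataFrame({"m": metric_ou[var], "e": env_ou[var]}).dropna()
        if len(pair) < 3 or pair["m"].nunique() < 2 or pair["e"].nunique() < 2:
            rows.append((var, np.nan, len(pair), "skipped"))
            continue
        r = float(stats.pearsonr(pair["m"], pair["e"]).statistic)
        status = "selected" if abs(r) > r_threshold else "dropped"
        rows.append((var, r, len(pair), status))
    return pd.DataFrame(rows, columns=["variable", "pearson_r", "n_pairs", "status"])


def substrate_effect_test(eqr_mineral: pd.Series, eqr_macrophyte: pd.Series):
    """Paired Wilcoxon signed-rank test of a substrate effect on OU EQRs.

    The two series are aligned on their index (observation units); only OUs
    with both substrates enter.  Returns ``(statistic, p_value, n_pairs)``;
    with fewer than 6 pairs the test is not computable and p is NaN.
    Identical pairs give statistic 0 and p = 1.
    """
    pairs = pd.DataFrame({"min": eqr_mineral, "mac": eqr_macrophyte}).dropna()
    n = len(pairs)
    if n < MIN_WILCOXON_PAIRS:
        return (np.nan, np.nan, n)
    diff = pairs["min"].to_numpy() - pairs["mac"].to_numpy()
    if np.allclose(diff, 0.0):
        return (0.0, 1.0, n)
    res = stats.wilcoxon(pairs["min"], pairs["mac"])
    return (float(res.statistic), float(res.pvalue), n)
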