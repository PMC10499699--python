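"""Threshold Indicator Taxa ANalysis (TITAN) along a single gradient.

TITAN (Baker & King 2010) combines change-point scanning with indicator
species analysis (IndVal; Dufrene & Legendre 1997).  For every taxon the
scan tries each admissible binary partition of the samples along one
environmental variable; the partition maximizing the larger of the two
side-specific IndVal scores is the taxon's change point, and the side that
attains the maximum gives the response direction ("plus" = increaser along
the gradient, "minus" = decreaser).  The observed maximum IndVal is
standardized into a z-score against permutations of the gradient labels,
and bootstrap resampling yields *purity* (direction consistency) and
*reliability* (fraction of replicates with permutation p <= 0.05).  Taxa
passing both screens are classified Z+ or Z-; summed z profiles over the
classified taxa locate the community-level shift thresholds, from which the
pressure-specific *alert taxa* are extracted.

Implementation notes
--------------------
All scans run in a "boundary" representation: a row of abundances is
aligned to the sorted order of its gradient vector, so every admissible
partition is a cut between consecutive positions, and group sums, occurrence
frequencies and IndVal scores for all cuts come from two cumulative sums.
Permutation and bootstrap replicates are plain extra rows in the same
batched computation, which keeps the whole analysis vectorized.

Randomness is organized as one master seed with per-(variable, taxon)
substreams derived by stable hashing of the taxon code, so results do not
depend on taxon ordering.  The draw order within a taxon never consults the
gradient values, which makes results exactly symmetric under gradient
negation (direction flips, z unchanged).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_tables import CalibrationError, CountMatrix

__all__ = [
    "TitanTaxonResult",
    "TitanCommunityResult",
    "AlertTaxaSet",
    "TitanVariableResult",
    "index_taxa",
    "compute_indval",
    "candidate_partitions",
    "taxon_change_point",
    "bootstrap_taxon",
    "classify_taxa",
    "community_change_points",
    "alert_taxa",
    "run_titan",
    "results_table",
]

DEFAULT_N_PERM = 250
DEFAULT_N_BOOT = 500
DEFAULT_MINSPLIT = 5
DEFAULT_PURITY_MIN = 0.95
DEFAULT_RELIABILITY_MIN = 0.95
#: per-replicate permutation p-value threshold entering reliability
RELIABILITY_ALPHA = 0.05
_MAX_REDRAWS = 10


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class TitanTaxonResult:
    """Per-taxon TITAN outcome for one environmental variable."""

    taxon_code: str
    change_point: float
    direction: str            # "plus" | "minus"
    indval_max: float         # observed maximum IndVal, in [0, 100]
    z: float                  # permutation-standardized maximum IndVal
    p_value: float
    purity: float
    reliability: float
    cp_quantiles: tuple       # bootstrap 5/50/95% change points
    group: str = "indifferent"  # "Zplus" | "Zminus" | "indifferent"
    excluded: bool = False    # taxon absent from all samples of this run
    n_boot_skipped: int = 0
    thresholds: np.ndarray = field(default=None, repr=False, compare=False)
    z_profile_plus: np.ndarray = field(default=None, repr=False, compare=False)
    z_profile_minus: np.ndarray = field(default=None, repr=False, compare=False)


@dataclass
class TitanCommunityResult:
    """Community-level sum(z) shift thresholds for one variable."""

    cp_sumz_plus: float | None
    cp_sumz_minus: float | None
    thresholds: np.ndarray = field(repr=False, compare=False, default=None)
    sumz_plus: np.ndarray = field(repr=False, compare=False, default=None)
    sumz_minus: np.ndarray = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class AlertTaxaSet:
    """Alert taxa for one variable: sorted ((taxon_code, direction), ...)."""

    variable: str
    taxa: tuple

    def codes(self) -> tuple:
        return tuple(code for code, _ in self.taxa)


@dataclass
class TitanVariableResult:
    """Everything TITAN produced for one environmental variable."""

    variable: str
    results: list
    community: TitanCommunityResult | None
    alert: AlertTaxaSet
    n_samples: int


# ---------------------------------------------------------------------------
# Index taxa
# ---------------------------------------------------------------------------

def index_taxa(matrices, min_occurrence: int = 3) -> list:
    """Taxa present (count > 0) in at least ``min_occurrence`` samples.

    ``matrices`` may be a single :class:`CountMatrix` or an iterable of them
    (occurrences are pooled).  The returned list is sorted by taxon code.
    """
    if isinstance(matrices, CountMatrix):
        matrices = [matrices]
    matrices = list(matrices)
    if not matrices:
        raise ValueError("empty calibration set")
    occ = None
    for m in matrices:
        o = m.occurrence()
        occ = o if occ is None else occ.add(o, fill_value=0)
    return sorted(occ.index[occ >= min_occurrence])


# ---------------------------------------------------------------------------
# IndVal and the boundary scan
# ---------------------------------------------------------------------------

def compute_indval(abundance, high_side, minsplit: int = 1):
    """Two-group IndVal scores for every taxon under a fixed partition.

    For each taxon and side g: specificity A_g = (mean abundance in g) /
    (sum of the two group mean abundances), fidelity B_g = occurrence
    frequency in g, and IndVal_g = 100 * A_g * B_g.  Taxa absent everywhere
    score 0 on both sides.

    Parameters
    ----------
    abundance : array-like or DataFrame, shape (n_samples, n_taxa)
    high_side : boolean array, True for samples above the threshold
    minsplit : smallest group size the caller allows

    Returns ``(indval_low, indval_high)`` as arrays (or Series when a
    DataFrame was given).
    """
    values = np.asarray(abundance, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    high = np.asarray(high_side, dtype=bool)
    n_high = int(high.sum())
    n_low = int((~high).sum())
    if n_low < minsplit or n_high < minsplit:
        raise ValueError(f"partition sides ({n_low}, {n_high}) smaller than minsplit={minsplit}")
    mean_low = values[~high].mean(axis=0)
    mean_high = values[high].mean(axis=0)
    den = mean_low + mean_high
    with np.errstate(invalid="ignore", divide="ignore"):
        a_low = np.where(den > 0, mean_low / den, 0.0)
        a_high = np.where(den > 0, mean_high / den, 0.0)
    b_low = (values[~high] > 0).mean(axis=0)
    b_high = (values[high] > 0).mean(axis=0)
    iv_low = 100.0 * a_low * b_low
    iv_high = 100.0 * a_high * b_high
    if isinstance(abundance, pd.DataFrame):
        return (pd.Series(iv_low, index=abundance.columns),
                pd.Series(iv_high, index=abundance.columns))
    return iv_low, iv_high


def _valid_boundaries(env_sorted: np.ndarray, minsplit: int) -> np.ndarray:
    """Admissible cuts of a sorted gradient: boundary b splits positions
    [0..b] vs [b+1..n-1]; ties never split and both sides need >= minsplit."""
    n = env_sorted.shape[-1]
    k = np.arange(1, n)
    distinct = env_sorted[..., 1:] > env_sorted[..., :-1]
    return distinct & (k >= minsplit) & (n - k >= minsplit)


def candidate_partitions(env, minsplit: int = DEFAULT_MINSPLIT) -> np.ndarray:
    """Threshold values (midpoints between distinct sorted gradient values)
    whose induced partitions have both sides >= minsplit."""
    env = np.asarray(env, dtype=float)
    if env.size < 2 * minsplit:
        raise ValueError(f"need at least {2 * minsplit} samples, got {env.size}")
    es = np.sort(env, kind="stable")
    vb = _valid_boundaries(es, minsplit)
    mids = 0.5 * (es[:-1] + es[1:])
    return mids[vb]


def _profiles(A: np.ndarray):
    """IndVal profiles over all cuts for rows aligned to sorted-gradient order.

    A: (B, n).  Returns (iv_low, iv_high), each (B, n-1); column b is the
    cut after position b (low group size b + 1).
    """
    n = A.shape[1]
    cs = np.cumsum(A, axis=1)
    tot = cs[:, -1:]
    csl = cs[:, :-1]
    k = np.arange(1, n, dtype=float)
    mean_low = csl / k
    mean_high = (tot - csl) / (n - k)
    den = mean_low + mean_high
    with np.errstate(invalid="ignore", divide="ignore"):
        a_low = np.where(den > 0, mean_low / den, 0.0)
        a_high = np.where(den > 0, mean_high / den, 0.0)
    occ = np.cumsum(A > 0, axis=1)
    occl = occ[:, :-1]
    occt = occ[:, -1:]
    b_low = occl / k
    b_high = (occt - occl) / (n - k)
    return 100.0 * a_low * b_low, 100.0 * a_high * b_high


def _scan_rows_numpy(A: np.ndarray, VB: np.ndarray):
    """Reference numpy implementation of the block scan."""
    iv_low, iv_high = _profiles(A)
    stat = np.maximum(iv_low, iv_high)
    stat = np.where(VB, stat, -np.inf)
    argb = stat.argmax(axis=1)
    rows = np.arange(A.shape[0])
    max_stat = stat[rows, argb]
    is_plus = iv_high[rows, argb] >= iv_low[rows, argb]
    return max_stat, argb, is_plus


try:  # optional compiled kernel; the numpy path is the reference
    from numba import njit as _njit

    @_njit(cache=False)
    def _scan_kernel(A, VB):  # pragma: no cover - exercised via _scan_rows
        B, n = A.shape
        max_stat = np.empty(B)
        argb = np.zeros(B, np.int64)
        plus = np.zeros(B, np.bool_)
        for r in range(B):
            tot = 0.0
            occt = 0.0
            for i in range(n):
                v = A[r, i]
                tot += v
                if v > 0:
                    occt += 1.0
            cs = 0.0
            occ = 0.0
            best = -np.inf
            bj = 0
            bp = True
            for j in range(n - 1):
                v = A[r, j]
                cs += v
                if v > 0:
                    occ += 1.0
                if not VB[r, j]:
                    continue
                k = j + 1.0
                mean_low = cs / k
                mean_high = (tot - cs) / (n - k)
                den = mean_low + mean_high
                if den > 0:
                    a_low = mean_low / den
                    a_high = mean_high / den
                else:
                    a_low = 0.0
                    a_high = 0.0
                iv_low = 100.0 * a_low * (occ / k)
                iv_high = 100.0 * a_high * ((occt - occ) / (n - k))
                s = iv_low if iv_low >= iv_high else iv_high
                if s > best:
                    best = s
                    bj = j
                    bp = iv_high >= iv_low
            max_stat[r] = best
            argb[r] = bj
            plus[r] = bp
        return max_stat, argb, plus

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _scan_rows(A: np.ndarray, VB: np.ndarray):
    """Max-IndVal scan for a block of rows.

    A: (B, n) abundance rows aligned to each row's sorted-gradient order.
    VB: (B, n-1) admissible-cut masks.
    Returns (max_stat, arg_boundary, is_plus); ties go to the lowest cut
    and, within a cut, to the "plus" side only on exact IndVal equality.
    """
    if _HAVE_NUMBA:
        return _scan_kernel(np.ascontiguousarray(A, dtype=np.float64),
                            np.ascontiguousarray(VB, dtype=np.bool_))
    return _scan_rows_numpy(A, VB)


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def taxon_rng(seed: int, taxon_code: str, variable: str = "") -> np.random.Generator:
    """Per-(variable, taxon) substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _stable_hash(variable), _stable_hash(taxon_code)])
    )


# ---------------------------------------------------------------------------
# Per-taxon analysis
# ---------------------------------------------------------------------------

def _perm_rows(rng: np.random.Generator, a: np.ndarray, n_perm: int,
               order: np.ndarray) -> np.ndarray:
    """Rows for permuted gradient labels, aligned to the sorted grid.

    Sample i is paired with abundance a[pi(i)] and the pairs are laid out in
    sorted-gradient order; drawing pi over sample indices (never consulting
    the gradient values) makes the scan exactly symmetric under gradient
    negation, where every row and cut mask simply reverses.
    """
    n = a.size
    idx = np.tile(np.arange(n), (n_perm, 1))
    rng.permuted(idx, axis=1, out=idx)
    return a[idx[:, order]]


def _analyze_taxon(code, a, env, n_perm, n_boot, rng, minsplit,
                   boot_block: int = 50) -> TitanTaxonResult:
    a = np.asarray(a, dtype=float)
    env = np.asarray(env, dtype=float)
    n = a.size
    order = np.argsort(env, kind="stable")
    es = env[order]
    vb = _valid_boundaries(es, minsplit)
    if not vb.any():
        raise CalibrationError(
            "no candidate partitions (gradient degenerate or too few samples)"
        )
    mids = 0.5 * (es[:-1] + es[1:])

    if not (a > 0).any():
        return TitanTaxonResult(code, np.nan, "plus", 0.0, 0.0, 1.0, 0.0, 0.0,
                                (np.nan, np.nan, np.nan), excluded=True,
                                thresholds=mids[vb].copy(),
                                z_profile_plus=np.zeros(int(vb.sum())),
                                z_profile_minus=np.zeros(int(vb.sum())))

    # Observed scan (keep profiles for the community sum(z) step).
    iv_low0, iv_high0 = _profiles(a[order][None, :])
    stat0 = np.where(vb, np.maximum(iv_low0[0], iv_high0[0]), -np.inf)
    argb = int(stat0.argmax())
    obs_max = float(stat0[argb])
    is_plus = bool(iv_high0[0, argb] >= iv_low0[0, argb])
    direction = "plus" if is_plus else "minus"
    change_point = float(mids[argb])

    # Permutation null of the max-IndVal statistic.
    perm_max, _, _ = _scan_rows(_perm_rows(rng, a, n_perm, order),
                                np.tile(vb, (n_perm, 1)))
    mu = float(perm_max.mean())
    sd = float(perm_max.std(ddof=1))
    z = (obs_max - mu) / sd if sd > 0 else 0.0
    p_value = (1.0 + np.sum(perm_max >= obs_max - 1e-12)) / (n_perm + 1.0)

    # Direction-specific z profiles over admissible cuts (scalar normalization
    # by the permutation mean/sd of the max statistic).
    if sd > 0:
        z_plus = (iv_high0[0, :][vb] - mu) / sd
        z_minus = (iv_low0[0, :][vb] - mu) / sd
    else:
        z_plus = np.zeros(int(vb.sum()))
        z_minus = np.zeros(int(vb.sum()))

    # Bootstrap: resample samples with replacement; each replicate gets its
    # own scan and its own permutation p-value.
    purity = reliability = np.nan
    cp_q = (np.nan, np.nan, np.nan)
    n_skipped = 0
    if n_boot > 0:
        boot_dirs = []
        boot_ps = []
        boot_cps = []
        pending = []  # (obs_row, perm_rows, vb_r, mids_r)
        def _flush():
            if not pending:
                return
            rows = np.concatenate([np.concatenate([p[0][None, :], p[1]]) for p in pending])
            masks = np.concatenate([np.tile(p[2], (1 + n_perm, 1)) for p in pending])
            mx, ab, pl = _scan_rows(rows, masks)
            for i, (_, _, _, mids_r) in enumerate(pending):
                lo = i * (1 + n_perm)
                obs_r = mx[lo]
                boot_dirs.append("plus" if pl[lo] else "minus")
                boot_cps.append(mids_r[ab[lo]])
                pm = mx[lo + 1: lo + 1 + n_perm]
                boot_ps.append((1.0 + np.sum(pm >= obs_r - 1e-12)) / (n_perm + 1.0))
            pending.clear()

        for _ in range(n_boot):
            accepted = False
            for _attempt in range(_MAX_REDRAWS):
                idx = rng.integers(0, n, n)
                er = env[idx]
                o = np.argsort(er, kind="stable")
                ero = er[o]
                vbr = _valid_boundaries(ero, minsplit)
                if vbr.any():
                    accepted = True
                    break
            if not accepted:
                n_skipped += 1
                continue
            ar = a[idx]
            pending.append((ar[o], _perm_rows(rng, ar, n_perm, o),
                            vbr, 0.5 * (ero[:-1] + ero[1:])))
            if len(pending) >= boot_block:
                _flush()
        _flush()
        if boot_dirs:
            boot_dirs = np.asarray(boot_dirs)
            purity = float(np.mean(boot_dirs == direction))
            reliability = float(np.mean(np.asarray(boot_ps) <= RELIABILITY_ALPHA))
            cp_q = tuple(np.percentile(np.asarray(boot_cps), [5, 50, 95]))
        else:
            purity = reliability = 0.0

    return TitanTaxonResult(
        taxon_code=code,
        change_point=change_point,
        direction=direction,
        indval_max=obs_max,
        z=z,
        p_value=p_value,
        purity=purity,
        reliability=reliability,
        cp_quantiles=cp_q,
        n_boot_skipped=n_skipped,
        thresholds=mids[vb].copy(),
        z_profile_plus=z_plus,
        z_profile_minus=z_minus,
    )


def taxon_change_point(abundance_col, env, n_perm: int = DEFAULT_N_PERM,
                       rng: np.random.Generator | None = None,
                       minsplit: int = DEFAULT_MINSPLIT):
    """Change point, direction, permutation z and max IndVal for one taxon.

    Deterministic given ``rng`` (pass a seeded Generator).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if rng is None:
        rng = np.random.default_rng()
    res = _analyze_taxon("", abundance_col, env, n_perm, 0, rng, minsplit)
    if res.excluded:
        raise ValueError("taxon absent from all samples; result undefined")
    return res.change_point, res.direction, res.z, res.indval_max


def bootstrap_taxon(abundance_col, env, n_boot: int = DEFAULT_N_BOOT,
                    rng: np.random.Generator | None = None,
                    n_perm: int = DEFAULT_N_PERM,
                    minsplit: int = DEFAULT_MINSPLIT):
    """Bootstrap purity, reliability and 5/50/95% change-point quantiles."""
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if rng is None:
        rng = np.random.default_rng()
    res = _analyze_taxon("", abundance_col, env, n_perm, n_boot, rng, minsplit)
    if res.excluded:
        raise ValueError("taxon absent from all samples; result undefined")
    return res.purity, res.reliability, res.cp_quantiles


# ---------------------------------------------------------------------------
# Classification, community thresholds, alert taxa
# ---------------------------------------------------------------------------

def classify_taxa(results: Iterable[TitanTaxonResult],
                  purity_min: float = DEFAULT_PURITY_MIN,
                  reliability_min: float = DEFAULT_RELIABILITY_MIN):
    """Label results Zplus/Zminus/indifferent (inclusive >= thresholds)."""
    if not 0 < purity_min <= 1 or not 0 < reliability_min <= 1:
        raise ValueError("purity_min and reliability_min must lie in (0, 1]")
    out = list(results)
    for r in out:
        if (not r.excluded and np.isfinite(r.purity) and np.isfinite(r.reliability)
                and r.purity >= purity_min and r.reliability >= reliability_min
                and r.z != 0.0):
            r.group = "Zplus" if r.direction == "plus" else "Zminus"
        else:
            r.group = "indifferent"
    return out


def community_change_points(results: Sequence[TitanTaxonResult],
                            env=None) -> TitanCommunityResult:
    """Community shift thresholds from summed z profiles.

    For each admissible cut, the z profiles of all Z+ (resp. Z-) taxa are
    summed; the community threshold per direction is the cut maximizing the
    profile, ties broken toward the lower gradient value.  A direction with
    no classified taxa gets ``None``.
    """
    classified = [r for r in results if r.group in ("Zplus", "Zminus")]
    if not classified:
        raise CalibrationError("no responders: no taxa classified Zplus or Zminus")
    thresholds = classified[0].thresholds
    for r in classified[1:]:
        if r.thresholds.shape != thresholds.shape or not np.allclose(r.thresholds, thresholds):
            raise ValueError("results come from different gradients")

    def _side(group: str, attr: str):
        members = [r for r in classified if r.group == group]
        if not members:
            return None, None
        profile = np.sum([getattr(r, attr) for r in members], axis=0)
        return float(thresholds[int(profile.argmax())]), profile

    cp_plus, sumz_plus = _side("Zplus", "z_profile_plus")
    cp_minus, sumz_minus = _side("Zminus", "z_profile_minus")
    return TitanCommunityResult(cp_sumz_plus=cp_plus, cp_sumz_minus=cp_minus,
                                thresholds=thresholds, sumz_plus=sumz_plus,
                                sumz_minus=sumz_minus)


#: Alert-rule strategies: which side of the community threshold a taxon's
#: change point must fall on, per direction.  "le" keeps taxa whose shift
#: occurs at or before the community shift.
ALERT_RULES = {
    "le_le": {"minus": "le", "plus": "le"},
    "le_ge": {"minus": "le", "plus": "ge"},
    "ge_le": {"minus": "ge", "plus": "le"},
    "ge_ge": {"minus": "ge", "plus": "ge"},
}
DEFAULT_ALERT_RULE = "le_le"


def alert_taxa(results: Sequence[TitanTaxonResult],
               community: TitanCommunityResult | None,
               variable: str = "",
               rule: str = DEFAULT_ALERT_RULE) -> AlertTaxaSet:
    """Extract alert taxa: classified taxa on the early side of the community
    shift threshold (default rule; other sign conventions selectable)."""
    sides = ALERT_RULES[rule]
    picked = []
    if community is not None:
        for r in results:
            if r.group == "Zplus" and community.cp_sumz_plus is not None:
                ok = (r.change_point <= community.cp_sumz_plus if sides["plus"] == "le"
                      else r.change_point >= community.cp_sumz_plus)
                if ok:
                    picked.append((r.taxon_code, "plus"))
            elif r.group == "Zminus" and community.cp_sumz_minus is not None:
                ok = (r.change_point <= community.cp_sumz_minus if sides["minus"] == "le"
                      else r.change_point >= community.cp_sumz_minus)
                if ok:
                    picked.append((r.taxon_code, "minus"))
    return AlertTaxaSet(variable=variable, taxa=tuple(sorted(picked)))


# ---------------------------------------------------------------------------
# Per-variable driver
# ---------------------------------------------------------------------------

def run_titan(abundance: pd.DataFrame, env: pd.Series, *, variable: str = "",
              seed: int = 0, n_perm: int = DEFAULT_N_PERM,
              n_boot: int = DEFAULT_N_BOOT, minsplit: int = DEFAULT_MINSPLIT,
              purity_min: float = DEFAULT_PURITY_MIN,
              reliability_min: float = DEFAULT_RELIABILITY_MIN,
              alert_rule: str = DEFAULT_ALERT_RULE) -> TitanVariableResult:
    """Full TITAN for one variable: per-taxon scans, classification,
    community thresholds and the alert-taxa set.

    ``abundance`` holds relative abundances (samples x index taxa); ``env``
    the gradient, aligned on the same index.  Samples with a missing
    gradient value are dropped from this run only.
    """
    env = env.reindex(abundance.index)
    keep = env.notna().to_numpy()
    env_v = env.to_numpy(dtype=float)[keep]
    abund = abundance.loc[keep]
    if env_v.size < 2 * minsplit:
        raise CalibrationError(
            f"variable {variable!r}: only {env_v.size} samples with gradient values"
        )
    results = []
    for code in abund.columns:
        rng = taxon_rng(seed, str(code), variable)
        results.append(_analyze_taxon(str(code), abund[code].to_numpy(dtype=float),
                                      env_v, n_perm, n_boot, rng, minsplit))
    classify_taxa(results, purity_min, reliability_min)
    try:
        community = community_change_points(results)
    except CalibrationError:
        community = None
    alerts = alert_taxa(results, community, variable=variable, rule=alert_rule)
    return TitanVariableResult(variable=variable, results=results,
                               community=community, alert=alerts,
                               n_samples=int(env_v.size))


def results_table(var_result: TitanVariableResult) -> pd.DataFrame:
    """Tabular TITAN report: one row per taxon plus community summary rows."""
    rows = []
    for r in var_result.results:
        rows.append({
            "variable": var_result.variable, "taxon_code": r.taxon_code,
            "change_point": r.change_point, "direction": r.direction,
            "indval_max": r.indval_max, "z": r.z, "p_value": r.p_value,
            "purity": r.purity, "reliability": r.reliability,
            "cp_05": r.cp_quantiles[0], "cp_50": r.cp_quantiles[1],
            "cp_95": r.cp_quantiles[2], "group": r.group,
            "excluded": r.excluded, "n_boot_skipped": r.n_boot_skipped,
        })
    df = pd.DataFrame(rows).sort_values("taxon_code", kind="stable").reset_index(drop=True)
    if var_result.community is not None:
        comm = var_result.community
        for direction, cp in (("plus", comm.cp_sumz_plus), ("minus", comm.cp_sumz_minus)):
            if cp is not None:
                df.loc[len(df)] = {
                    "variable": var_result.variable,
                    "taxon_code": f"<community sum(z) {direction}>",
                    "change_point": cp, "direction": direction,
                }
    return df
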