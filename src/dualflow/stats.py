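"""Agreement statistics between modalities: Bland-Altman bias and limits of
agreement, Spearman rank correlation, paired t-test, and myocardial flow
reserve, plus the table join that pairs PET and MRI estimates by
subject/condition/region with exclusion bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .segments import TERRITORIES


class StatsError(ValueError):
    """Invalid statistical input (length, constancy, non-positive rest flow)."""


@dataclass(frozen=True)
class AgreementReport:
    """Bias, limits of agreement and correlation for one paired comparison."""

    n: int
    bias: float
    loa_low: float
    loa_high: float
    spearman_r: float
    spearman_p: float
    t_stat: float
    t_p: float
    excluded_count: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def mfr(rest_F: float, stress_F: float) -> float:
    """Myocardial flow reserve: stress flow over rest flow (per subject/region)."""
    if rest_F <= 0:
        raise StatsError("rest MBF must be positive to form a flow reserve")
    return float(stress_F) / float(rest_F)


def bland_altman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Mean difference (bias) and 1.96-SD limits of agreement for x - y.

    SD uses the n-1 denominator; exclusions must be removed beforehand.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise StatsError("need two equal-length vectors with at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p from the t-approximation with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise StatsError("need two equal-length vectors with at least 2 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Two-sided paired t-test; returns (t, p, df) with df = n - 1.

    A zero-variance nonzero difference yields an infinite statistic with
    p = 0 (flagged by the inf) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise StatsError("need two equal-length vectors with at least 2 pairs")
    d = x - y
    n = d.size
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, n - 1
        return math.copysign(math.inf, mean), 0.0, n - 1
    t = mean / (sd / math.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return float(t), p, n - 1


def mfr_table(fit_table: pd.DataFrame) -> pd.DataFrame:
    """Per subject/region flow reserve from a rest+stress fit table.

    Rows where either condition is missing or not ``ok`` are kept with
    ``ok = False`` and NaN MFR so exclusions remain countable.
    """
    rows = []
    for (sub, region), grp in fit_table.groupby(["subject", "region"]):
        rest = grp[grp.condition == "rest"]
        stress = grp[grp.condition == "stress"]
        ok = (len(rest) == 1 and len(stress) == 1
              and bool(rest.ok.iloc[0]) and bool(stress.ok.iloc[0])
              and rest.mbf.iloc[0] > 0)
        value = (mfr(rest.mbf.iloc[0], stress.mbf.iloc[0]) if ok else np.nan)
        rows.append({"subject": sub, "region": region, "mfr": value, "ok": ok})
    return pd.DataFrame(rows)


def _select_level(table: pd.DataFrame, level: str) -> pd.DataFrame:
    if level == "global":
        return table[table.region == "global"]
    if level == "territory":
        return table[table.region.isin(TERRITORIES)]
    if level == "segment":
        return table[table.region.str.startswith("seg")]
    raise StatsError(f"unknown level {level!r}")


def compare_modalities(pet_table: pd.DataFrame, mri_table: pd.DataFrame,
                       level: str = "global", condition: str = "pooled",
                       value_col: str = "mbf"
                       ) -> tuple[AgreementReport, pd.DataFrame]:
    """Pair PET and MRI estimates and compute the agreement report.

    Joins on subject x condition x region at the requested level
    (global/territory/segment); ``condition`` restricts to rest or stress,
    or pools both (each condition contributing an independent pair).  Pairs
    where either fit is excluded (``ok`` False or NaN value) are dropped and
    counted in ``excluded_count``.  Returns the report and the underlying
    paired table (columns pet, mri) for plotting.
    """
    pet = _select_level(pet_table, level)
    mri = _select_level(mri_table, level)
    if condition in ("rest", "stress"):
        pet = pet[pet.condition == condition]
        mri = mri[mri.condition == condition]
    elif condition != "pooled":
        raise StatsError(f"unknown condition {condition!r}")
    keys = ["subject", "condition", "region"]
    merged = pet.merge(mri, on=keys, suffixes=("_pet", "_mri"), how="inner")
    if merged.empty:
        raise StatsError(
            f"no overlapping (subject, condition, region) keys at level "
            f"{level!r}, condition {condition!r}")
    ok = (merged.ok_pet.fillna(False) & merged.ok_mri.fillna(False)
          & merged[f"{value_col}_pet"].notna()
          & merged[f"{value_col}_mri"].notna())
    excluded = int((~ok).sum())
    kept = merged[ok]
    x = kept[f"{value_col}_mri"].to_numpy(dtype=float)
    y = kept[f"{value_col}_pet"].to_numpy(dtype=float)
    bias, lo, hi = bland_altman(x, y)
    r, rp = spearman(x, y)
    t, tp, _ = paired_t(x, y)
    report = AgreementReport(n=int(x.size), bias=bias, loa_low=lo, loa_high=hi,
                             spearman_r=r, spearman_p=rp, t_stat=t, t_p=tp,
                             excluded_count=excluded)
    paired = kept[keys].copy()
    paired["mri"] = x
    paired["pet"] = y
    return report, paired


def compare_mfr(pet_table: pd.DataFrame, mri_table: pd.DataFrame,
                level: str = "global") -> tuple[AgreementReport, pd.DataFrame]:
    """Agreement report for flow reserve (stress/rest) between modalities."""
    pet_mfr = mfr_table(_select_level(pet_table, level))
    mri_mfr = mfr_table(_select_level(mri_table, level))
    pet_mfr = pet_mfr.rename(columns={"mfr": "mbf"})
    pet_mfr["condition"] = "mfr"
    mri_mfr = mri_mfr.rename(columns={"mfr": "mbf"})
    mri_mfr["condition"] = "mfr"
    return compare_modalities(pet_mfr, mri_mfr, level=level,
                              condition="pooled")
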