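"""Indirect age-sex standardization and descriptive statistics.

Expected case counts per area come from indirect standardization: pooled
reference ("country-level") rates are computed for four age-sex strata —
females 0-74, females 75+, males 0-74, males 75+ — and applied to each
area's stratum populations,

    r_s = sum_i C_is / sum_i P_is,        E_i = sum_s r_s * P_is.

The relative risk (standardized incidence ratio) of area i is then
RR_i = Y_i / E_i.  With internally computed rates the standardization is
calibrated: sum_i E_i equals the total case count exactly.

Also implemented here: aggregation of RR over exposure quartiles
(sum Y / sum E per quartile group), stage-by-group percentage tables with
half-away-from-zero one-decimal rounding, and the physicians-per-10,000
density transform.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = [
    "STRATA",
    "validate_strata",
    "stratum_rates",
    "expected_counts",
    "relative_risk",
    "quartile_aggregate",
    "stage_proportions",
    "physician_density",
    "standardize_study",
    "round_half_away",
]

#: The four age-sex strata: females 0-74, females 75+, males 0-74, males 75+.
STRATA: tuple[str, ...] = ("F0_74", "F75p", "M0_74", "M75p")


def round_half_away(x, ndigits: int = 1):
    """Round half away from zero (0.05 -> 0.1, -0.05 -> -0.1)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def validate_strata(strata: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format strata table (area_id, stratum, population, cases)."""
    required = {"area_id", "stratum", "population", "cases"}
    missing = required - set(strata.columns)
    if missing:
        raise InputError(f"strata table missing columns: {sorted(missing)}")
    unknown = set(strata["stratum"]) - set(STRATA)
    if unknown:
        raise InputError(f"unknown strata: {sorted(unknown)}; expected {STRATA}")
    if (strata["population"] < 0).any():
        raise InputError("negative population in strata table")
    if (strata["cases"] < 0).any():
        raise InputError("negative case count in strata table")
    bad = (strata["population"] == 0) & (strata["cases"] > 0)
    if bad.any():
        areas = strata.loc[bad, "area_id"].tolist()
        raise InputError(f"cases with zero population in areas {areas}")
    return strata


def _wide(strata: pd.DataFrame, value: str) -> pd.DataFrame:
    """Pivot to areas x strata (strata present in the table), preserving
    first-appearance area order."""
    order = strata["area_id"].drop_duplicates().tolist()
    present = [s for s in STRATA if s in set(strata["stratum"])]
    wide = strata.pivot_table(
        index="area_id", columns="stratum", values=value, aggfunc="sum", fill_value=0.0
    ).reindex(index=order, columns=present, fill_value=0.0)
    return wide


def stratum_rates(strata: pd.DataFrame) -> pd.Series:
    """Pooled reference rate per stratum, r_s = total cases / total population."""
    validate_strata(strata)
    pop = _wide(strata, "population").sum(axis=0)
    cases = _wide(strata, "cases").sum(axis=0)
    zero = pop[pop <= 0]
    if len(zero):
        raise InputError(f"zero total population in strata {zero.index.tolist()}")
    rates = cases / pop
    rates.name = "rate"
    return rates


def expected_counts(strata: pd.DataFrame, rates: pd.Series | None = None) -> pd.Series:
    """Indirectly standardized expected counts E_i = sum_s r_s * P_is.

    ``rates=None`` uses internal (pooled) rates, in which case
    sum_i E_i equals the total observed cases exactly (calibration).
    """
    validate_strata(strata)
    if rates is None:
        rates = stratum_rates(strata)
    pop = _wide(strata, "population")
    rates = pd.Series(rates).reindex(pop.columns)
    if rates.isna().any():
        raise InputError(f"rates must cover the strata present: {list(pop.columns)}")
    if (rates < 0).any():
        raise InputError("negative stratum rate")
    e = pop.mul(rates, axis=1).sum(axis=1)
    e.name = "expected"
    return e


def relative_risk(y, e) -> np.ndarray:
    """Standardized incidence ratio RR_i = Y_i / E_i (requires E_i > 0)."""
    y = np.asarray(y, dtype=float)
    e = np.asarray(e, dtype=float)
    bad = np.flatnonzero(e <= 0)
    if bad.size:
        raise InputError(f"non-positive expected counts at positions {bad.tolist()}")
    return y / e


def quartile_aggregate(
    areas: pd.DataFrame,
    by: str = "exposure",
    y: str = "y_late",
    expected: str = "expected",
) -> pd.DataFrame:
    """Aggregate relative risk over quartiles of an exposure column.

    Quartile cut points are sample quantiles (linear interpolation); areas
    exactly on a cut point join the lower group.  Per group the aggregate
    relative risk is (sum Y) / (sum E), so the whole-sample aggregate is
    preserved regardless of grouping.
    """
    for col in (by, y, expected):
        if col not in areas.columns:
            raise InputError(f"areas table missing column {col!r}")
    if len(areas) < 4:
        raise InputError(f"need at least 4 areas, got {len(areas)}")
    x = areas[by].to_numpy(dtype=float)
    qs = np.quantile(x, [0.25, 0.5, 0.75])
    if np.all(x == x[0]):
        warnings.warn(
            "all exposures identical; returning a single aggregate group",
            stacklevel=2,
        )
        group = np.ones(len(areas), dtype=int)
    else:
        group = 1 + (x > qs[0]).astype(int) + (x > qs[1]).astype(int) + (x > qs[2]).astype(int)
    df = areas.assign(_q=group)
    rows = []
    for g, sub in df.groupby("_q", sort=True):
        sy = float(sub[y].sum())
        se = float(sub[expected].sum())
        rows.append(
            {
                "quartile": int(g),
                "n_areas": len(sub),
                "sum_observed": sy,
                "sum_expected": se,
                "rr": sy / se,
                "mean_exposure": float(sub[by].mean()),
            }
        )
    return pd.DataFrame(rows)


def stage_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Percentage of early/late stage per group column, one-decimal rounding.

    ``table`` has rows indexed 'early' and 'late' (an optional 'all' row is
    validated against their sum) and one column per patient group.
    """
    idx = set(table.index)
    if not {"early", "late"} <= idx:
        raise InputError("stage table needs rows 'early' and 'late'")
    early = table.loc["early"].astype(float)
    late = table.loc["late"].astype(float)
    total = early + late
    if "all" in idx:
        declared = table.loc["all"].astype(float)
        if not np.allclose(declared.to_numpy(), total.to_numpy()):
            raise InputError("'all' row does not equal early + late")
    zero = total[total <= 0]
    if len(zero):
        raise InputError(f"zero group total in columns {zero.index.tolist()}")
    out = pd.DataFrame(
        {
            "early": pd.Series(round_half_away(100.0 * early / total, 1), index=total.index),
            "late": pd.Series(round_half_away(100.0 * late / total, 1), index=total.index),
        }
    ).T
    out.index.name = "stage"
    return out


def physician_density(count: float, population: float, per: float = 10_000.0) -> float:
    """Physicians per ``per`` inhabitants (default per 10,000)."""
    if population <= 0:
        raise InputError(f"population must be positive, got {population}")
    if count < 0:
        raise InputError(f"physician count must be nonnegative, got {count}")
    return per * count / population


def standardize_study(strata: pd.DataFrame) -> pd.DataFrame:
    """Area table (observed, expected, RR) from a strata table alone.

    Observed counts are the per-area stratum case sums; expected counts use
    internally pooled stratum rates, so the output is calibrated
    (sum expected = sum observed).
    """
    validate_strata(strata)
    cases = _wide(strata, "cases").sum(axis=1)
    e = expected_counts(strata)
    rr = relative_risk(cases.to_numpy(), e.to_numpy())
    return pd.DataFrame(
        {
            "area_id": e.index,
            "y_late": cases.to_numpy(),
            "expected": e.to_numpy(),
            "rr": rr,
        }
    )
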