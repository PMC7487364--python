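"""Cohort summaries, anisotropy testing and the swelling helper.

The inflation cohort table (one row per specimen: thickness, burst pressure,
identified Ogden/NeoHookean parameters, rupture stress) carries two distinct
missing-value codes — ``failed`` (the experiment failed outright) and
``not_in_aoi`` (rupture happened outside the reconstructed area of interest)
— which are preserved on output and excluded from summaries.
"""

from __future__ import annotations

import re
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MISSING_CODES",
    "load_inflation_cohort",
    "summarize_cohort",
    "anisotropy_test",
    "volumetric_swelling",
    "agrees_with_printed",
]

MISSING_CODES = ("failed", "not_in_aoi")
_META_COLUMNS = ("pig", "side")


def load_inflation_cohort(path=None) -> pd.DataFrame:
    """Load a cohort table; defaults to the packaged inflation-test table.

    Value columns keep their missing-value codes as strings; use
    :func:`summarize_cohort` (or ``numeric_cohort``) for arithmetic.
    """
    if path is None:
        src = resources.files("duramech").joinpath(
            "data/inflation_cohort.csv")
        with resources.as_file(src) as p:
            return pd.read_csv(p, dtype=str)
    return pd.read_csv(path, dtype=str)


def numeric_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Value columns coerced to float with missing codes as NaN."""
    out = {}
    for col in table.columns:
        if col in _META_COLUMNS:
            continue
        s = table[col].astype(str).str.strip()
        s = s.where(~s.isin(MISSING_CODES))
        out[col] = pd.to_numeric(s, errors="raise")
    return pd.DataFrame(out, index=table.index)


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample standard deviation (n-1) per value column.

    Missing entries (either missing code) are excluded column-wise.  Columns
    with fewer than two non-missing values are reported as NaN and listed in
    the frame's ``attrs['non_summarizable']``.
    """
    num = numeric_cohort(table)
    counts = num.notna().sum()
    mean = num.mean()
    std = num.std(ddof=1)
    bad = counts[counts < 2].index.tolist()
    mean[bad] = np.nan
    std[bad] = np.nan
    out = pd.DataFrame({"mean": mean, "std": std, "n": counts})
    out.attrs["non_summarizable"] = bad
    return out


def anisotropy_test(group_a, group_b, welch: bool = False) -> float:
    """Two-tailed two-sample t-test p-value between parameter groups.

    Pooled-variance Student's t by default; set ``welch=True`` for Welch's
    unequal-variance form.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.array_equal(a, b):
        return 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def volumetric_swelling(linear_strain: float,
                        convention: str = "small_strain") -> float:
    """Percent volumetric expansion from an isotropic linear strain.

    ``small_strain`` uses 3 eps (the engineering convention in which a 2%
    thermal strain is a 6% volume change); ``exact`` uses (1+eps)^3 - 1.
    """
    if linear_strain <= -1:
        raise ValueError("linear strain must exceed -1")
    if convention == "small_strain":
        return 300.0 * linear_strain
    if convention == "exact":
        return 100.0 * ((1.0 + linear_strain) ** 3 - 1.0)
    raise ValueError("convention must be small_strain|exact")


def agrees_with_printed(value: float, printed: str) -> bool:
    """Whether ``value`` rounds to the printed figure within half an ulp.

    ``printed`` is a decimal string exactly as tabulated ("375", "8.19",
    "0.005"); agreement means |value - printed| <= 0.5 of the last printed
    digit, i.e. the comparison is at printed precision, not machine
    precision.
    """
    printed = printed.strip()
    if not re.fullmatch(r"-?\d+(\.\d+)?", printed):
        raise ValueError(f"not a plain decimal: {printed!r}")
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    tol = 0.5 * 10.0 ** (-decimals)
    return abs(value - float(printed)) <= tol + 1e-12
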