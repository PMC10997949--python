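"""Correlation and summary statistics for tap-water endpoint analysis.

Implements the product-moment correlation, simple ordinary-least-squares
regression, a two-sided permutation test on |r|, and grouped mean +/- SD
summaries from first principles.  Pairs with an undefined value (NaN) are
dropped listwise and the exclusion count is carried on the result.

The permutation p-value uses the add-one estimator
p = (1 + #{|r*| >= |r_obs|}) / (B + 1), which is never exactly zero and is
exact-level for any B when the null of exchangeability holds.  No
multiple-comparison correction is applied; callers receive raw p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError


@dataclass(frozen=True)
class AssociationResult:
    """One variable pair's full association summary."""

    x_name: str
    y_name: str
    n: int
    n_dropped: int
    pearson_r: float
    r2: float
    slope: float
    intercept: float
    p_perm: float | None
    permutations: int | None
    seed: int | None

    def as_dict(self) -> dict:
        return dict(vars(self))


@dataclass(frozen=True)
class GroupSummary:
    """Per-group n, mean and sample SD (n-1 denominator; None when n < 2)."""

    label: str
    n: int
    mean: float
    sd: float | None

    def formatted(self, decimals: int = 2) -> str:
        if self.sd is None:
            return f"{self.mean:.{decimals}f} (n=1)"
        return f"{self.mean:.{decimals}f} ± {self.sd:.{decimals}f}"


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError(
            f"x and y must be 1-D and equal length, got {x.shape} vs {y.shape}"
        )
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DegenerateInputError(f"need >= 3 complete pairs, have {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    return x, y, n_dropped


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN pairs are dropped listwise."""
    x, y, _ = _clean_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def linfit(x, y) -> tuple[float, float, float]:
    """Simple OLS fit y = slope*x + intercept; returns (slope, intercept, r2).

    For this one-predictor fit r2 equals pearson_r**2 identically.
    """
    x, y, _ = _clean_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r2 = (sxy * sxy) / (sxx * syy)
    return slope, intercept, r2


def permutation_p(x, y, B: int = 999, seed: int | None = None) -> float:
    """Two-sided permutation p-value for the Pearson correlation.

    Permutes y against x B times (seeded, reproducible) and reports
    (1 + #{|r*| >= |r_obs|}) / (B + 1).
    """
    if B < 99:
        raise ValueError(f"need at least 99 permutations, got {B}")
    x, y, _ = _clean_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    r_obs = abs(float(xc @ yc) / denom)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(yc, (B, 1)), axis=1)
    r_star = np.abs(perms @ xc) / denom
    exceed = int(np.count_nonzero(r_star >= r_obs))
    return (1 + exceed) / (B + 1)


def associate(
    x,
    y,
    x_name: str = "x",
    y_name: str = "y",
    B: int | None = 999,
    seed: int | None = None,
) -> AssociationResult:
    """Full association summary for one variable pair.

    Reports both r and r2 (never guessing which scale a reader wants), the
    OLS line, and — when ``B`` is not None — the seeded permutation p-value.
    """
    xv, yv, n_dropped = _clean_pair(x, y)
    r = pearson_r(xv, yv)
    slope, intercept, r2 = linfit(xv, yv)
    p = permutation_p(xv, yv, B=B, seed=seed) if B is not None else None
    return AssociationResult(
        x_name=x_name,
        y_name=y_name,
        n=len(xv),
        n_dropped=n_dropped,
        pearson_r=r,
        r2=r2,
        slope=slope,
        intercept=intercept,
        p_perm=p,
        permutations=B,
        seed=seed,
    )


def group_summary(
    table: pd.DataFrame, group_field: str, value_field: str
) -> list[GroupSummary]:
    """Per-group n / mean / sample SD of one numeric column.

    Groups of size one carry ``sd=None`` (undefined), matching the
    mean +/- SD presentation convention of water-quality summary tables.
    """
    if len(table) == 0:
        raise DegenerateInputError("empty table")
    for f in (group_field, value_field):
        if f not in table.columns:
            raise DegenerateInputError(f"unknown field {f!r}")
    out = []
    for label, sub in table.groupby(group_field, sort=True):
        vals = sub[value_field].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
        out.append(
            GroupSummary(label=str(label), n=len(vals),
                         mean=float(np.mean(vals)), sd=sd)
        )
    return out
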