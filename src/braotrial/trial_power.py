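"""Effect-size projection and minimum sample sizes for a two-arm trial.

A neuroprotective drug of efficacy e in [0, 1] is assumed to scale the
natural GCL loss: treated mean %change = (1 - e) * placebo mean, so a fully
effective drug abolishes all loss.  Cohen's d at trial day t is

    d = e * |%change(t)| / sigma

with sigma the residual SD of the decay regression (its Sy.x).  The minimum
patients per group is the smallest integer n giving power >= the target for
a two-sided two-sample t-test at level alpha, computed from the noncentral-t
distribution with noncentrality d * sqrt(n/2) and 2n - 2 degrees of freedom.

The published planning table did not print its sigma; ``calibrate_sigma``
back-fits it by least squares over the printed cells.  Back-calculation
shows the published grid is only reproducible when the intermediate
quantities are rounded the way planning tables print them — predicted
%change to a whole percent and d to two decimals — so the reconstruction
helpers apply that convention (exposed as parameters, off by default in the
generic grid builder).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .decay_model import DecayFit, predict, published_decay_fit
from .published import (
    PUBLISHED_ALPHA,
    PUBLISHED_DURATIONS,
    PUBLISHED_EFFICACIES,
    PUBLISHED_POWER,
    PUBLISHED_SAMPLE_SIZES,
)

# Convention that reproduces the published planning table (see module docs).
TABLE_CHANGE_DECIMALS = 0
TABLE_D_DECIMALS = 2


@dataclass(frozen=True)
class EfficacyScenario:
    """One hypothetical trial cell: drug efficacy fraction and duration."""

    efficacy: float
    trial_days: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError("efficacy must be in [0, 1]")
        if self.trial_days <= 0:
            raise ValueError("trial_days must be > 0")


@dataclass(frozen=True)
class SampleSizeGrid:
    """Durations x efficacies planning grid with intermediate quantities.

    ``table`` is long-form with one row per cell and columns
    ``trial_days``, ``efficacy``, ``predicted_change_placebo``,
    ``predicted_change_treated``, ``cohens_d``, ``n_per_group``.
    """

    table: pd.DataFrame
    alpha: float
    power: float
    sigma: float
    durations: tuple = field(default=())
    efficacies: tuple = field(default=())

    def n_wide(self) -> pd.DataFrame:
        """Pivot to the published layout: rows durations, columns efficacies."""
        wide = self.table.pivot(
            index="trial_days", columns="efficacy", values="n_per_group"
        )
        return wide.loc[list(self.durations), list(self.efficacies)]

    def cell(self, trial_days, efficacy) -> pd.Series:
        match = self.table[
            (self.table["trial_days"] == trial_days)
            & (self.table["efficacy"] == efficacy)
        ]
        if match.empty:
            raise KeyError((trial_days, efficacy))
        return match.iloc[0]


def power_two_sample_t(
    n: float, d: float, alpha: float = PUBLISHED_ALPHA
) -> float:
    """Power of a two-sided two-sample t-test with n per group and effect d.

    Noncentral-t exact power; n may be fractional (df = 2n - 2), which makes
    the function continuous for root finding.
    """
    if n <= 1:
        return 0.0
    df = 2.0 * n - 2.0
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    ncp = d * math.sqrt(n / 2.0)
    upper = stats.nct.sf(crit, df, ncp)
    # scipy's noncentral-t CDF is NaN for some large ncp at small df; the
    # lower-tail rejection probability is negligible (<1e-15) there.
    lower = stats.nct.cdf(-crit, df, ncp)
    if not np.isfinite(lower):
        lower = 0.0
    if not np.isfinite(upper):
        upper = 1.0 if ncp > crit else 0.0
    return float(upper + lower)


def min_n_continuous(
    d: float, alpha: float = PUBLISHED_ALPHA, power: float = PUBLISHED_POWER
) -> float:
    """Real-valued n per group solving power(n, d) = power (>= 2)."""
    if d <= 0:
        raise ValueError("d must be > 0")
    gap = lambda n: power_two_sample_t(n, d, alpha) - power
    if gap(2.0) >= 0:
        return 2.0
    hi = 4.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("sample size search did not bracket a root")
    return float(optimize.brentq(gap, 2.0, hi, xtol=1e-8))


@lru_cache(maxsize=4096)
def _sample_size_cached(d: float, alpha: float, power: float) -> int:
    n = max(2, math.ceil(min_n_continuous(d, alpha, power) - 1e-9))
    while power_two_sample_t(n, d, alpha) < power:
        n += 1
    while n > 2 and power_two_sample_t(n - 1, d, alpha) >= power:
        n -= 1
    return n


def sample_size(
    d: float, alpha: float = PUBLISHED_ALPHA, power: float = PUBLISHED_POWER
) -> int:
    """Minimum integer patients per group for power >= target (floor 2)."""
    if d <= 0:
        raise ValueError("d must be > 0")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must be in (0, 1)")
    return _sample_size_cached(float(d), float(alpha), float(power))


def treated_mean(fit: DecayFit, day: float, efficacy: float) -> float:
    """Expected %change on drug: (1 - efficacy) x the natural course."""
    if not 0.0 <= efficacy <= 1.0:
        raise ValueError("efficacy must be in [0, 1]")
    return (1.0 - efficacy) * predict(fit, day)


def cohens_d(
    fit: DecayFit, day: float, efficacy: float, sigma: float | None = None
) -> float:
    """Standardised placebo-vs-treated difference at ``day``.

    ``sigma`` defaults to the fit's residual SD (Sy.x) and must be > 0.
    """
    if sigma is None:
        sigma = fit.sy_x
    if not (sigma > 0):
        raise ValueError("sigma (residual SD) must be > 0")
    placebo = predict(fit, day)
    return abs(placebo - treated_mean(fit, day, efficacy)) / sigma


def _cell_quantities(
    fit: DecayFit,
    day: float,
    efficacy: float,
    sigma: float,
    change_decimals: int | None,
    d_decimals: int | None,
):
    placebo = predict(fit, day)
    if change_decimals is not None:
        placebo = round(placebo, change_decimals)
    treated = (1.0 - efficacy) * placebo
    d = abs(placebo - treated) / sigma
    if d_decimals is not None:
        d = round(d, d_decimals)
    return placebo, treated, d


def build_grid(
    fit: DecayFit,
    durations=PUBLISHED_DURATIONS,
    efficacies=PUBLISHED_EFFICACIES,
    alpha: float = PUBLISHED_ALPHA,
    power: float = PUBLISHED_POWER,
    sigma: float | None = None,
    change_decimals: int | None = None,
    d_decimals: int | None = None,
) -> SampleSizeGrid:
    """Full durations x efficacies grid of effect sizes and sample sizes.

    ``change_decimals`` / ``d_decimals`` optionally round the intermediate
    predicted change and Cohen's d before the power lookup, mimicking a
    planning workflow that reads them off printed tables.  Default is no
    rounding.
    """
    if not fit.converged:
        raise ValueError("grid requires a converged fit")
    durations = tuple(durations)
    efficacies = tuple(efficacies)
    if not durations or not efficacies:
        raise ValueError("durations and efficacies must be nonempty")
    if sigma is None:
        sigma = fit.sy_x
    if not (sigma > 0):
        raise ValueError("sigma (residual SD) must be > 0")

    rows = []
    for day in durations:
        for efficacy in efficacies:
            EfficacyScenario(efficacy=efficacy, trial_days=day)
            placebo, treated, d = _cell_quantities(
                fit, day, efficacy, sigma, change_decimals, d_decimals
            )
            n = sample_size(d, alpha, power) if d > 0 else math.inf
            rows.append(
                {
                    "trial_days": day,
                    "efficacy": efficacy,
                    "predicted_change_placebo": placebo,
                    "predicted_change_treated": treated,
                    "cohens_d": d,
                    "n_per_group": n,
                }
            )
    return SampleSizeGrid(
        table=pd.DataFrame(rows), alpha=alpha, power=power, sigma=float(sigma),
        durations=durations, efficacies=efficacies,
    )


def calibrate_sigma(
    fit: DecayFit | None = None,
    published_cells: dict[tuple, int] | None = None,
    exclude: tuple | None = None,
    alpha: float = PUBLISHED_ALPHA,
    power: float = PUBLISHED_POWER,
    change_decimals: int | None = TABLE_CHANGE_DECIMALS,
    d_decimals: int | None = TABLE_D_DECIMALS,
    sigma_grid: np.ndarray | None = None,
) -> float:
    """Back-fit the unprinted residual SD from the published planning table.

    Minimises the sum of squared differences between reconstructed and
    published patients-per-group over the printed cells (optionally leaving
    one out), scanning a fine sigma grid: with integer sample sizes the
    objective is piecewise constant, so the scan is exact up to the grid step
    and the mean of the minimising set is returned.
    """
    if fit is None:
        fit = published_decay_fit()
    if published_cells is None:
        published_cells = PUBLISHED_SAMPLE_SIZES
    cells = {k: v for k, v in published_cells.items() if k != exclude}
    if not cells:
        raise ValueError("no cells left to calibrate against")
    if sigma_grid is None:
        sigma_grid = np.arange(20.0, 28.0, 0.005)

    sse = np.empty(len(sigma_grid))
    for i, s in enumerate(sigma_grid):
        total = 0.0
        for (day, efficacy), n_pub in cells.items():
            _, _, d = _cell_quantities(
                fit, day, efficacy, s, change_decimals, d_decimals
            )
            n = sample_size(d, alpha, power) if d > 0 else math.inf
            total += (n - n_pub) ** 2
        sse[i] = total
    best = np.flatnonzero(sse == sse.min())
    return float(sigma_grid[best].mean())


def reconstruct_published_grid(
    exclude_for_sigma: tuple | None = None,
    alpha: float = PUBLISHED_ALPHA,
    power: float = PUBLISHED_POWER,
) -> SampleSizeGrid:
    """Rebuild the published planning table from the published decay curve.

    Sigma is calibrated from the printed cells (leave-one-out if
    ``exclude_for_sigma`` names a cell) and the printed-table rounding
    convention is applied.
    """
    sigma = calibrate_sigma(exclude=exclude_for_sigma, alpha=alpha, power=power)
    return build_grid(
        published_decay_fit(),
        alpha=alpha,
        power=power,
        sigma=sigma,
        change_decimals=TABLE_CHANGE_DECIMALS,
        d_decimals=TABLE_D_DECIMALS,
    )
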