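"""Published study constants used as calibration inputs.

The aggregate GCL time course in the source study fit a single-phase decay

    %change(t) = 46.2 * exp(-0.01 * t) - 55.7        (t in days after occlusion)

i.e. span 46.2 % (y0 = -9.5 % at day 0), plateau -55.7 %, decay constant
0.01 / day.  The published trial-planning table gives the minimum number of
patients per group for a two-arm trial (two-tailed two-sample t-test,
alpha = 0.05, power = 0.8) across trial durations and drug efficacies.
Those printed numbers are calibration data for the residual SD sigma, which
the study did not print.
"""

from __future__ import annotations

PUBLISHED_Y0 = -9.5
"""% GCL change at day 0 of the published decay fit (46.2 - 55.7)."""

PUBLISHED_PLATEAU = -55.7
"""Asymptotic % GCL change of the published decay fit."""

PUBLISHED_SPAN = 46.2
"""y0 - plateau of the published decay fit, in % change units."""

PUBLISHED_K = 0.01
"""Decay constant of the published fit, per day."""

PUBLISHED_DURATIONS = (30, 60, 90, 180)
"""Trial durations (days) of the published sample-size table rows."""

PUBLISHED_EFFICACIES = (0.2, 0.4, 0.6, 0.8, 1.0)
"""Drug efficacies (fractions) of the published sample-size table columns."""

#: Published minimum patients per group, keyed (trial_days, efficacy).
PUBLISHED_SAMPLE_SIZES: dict[tuple[int, float], int] = {
    (30, 0.2): 486, (30, 0.4): 130, (30, 0.6): 57, (30, 0.8): 33, (30, 1.0): 21,
    (60, 0.2): 253, (60, 0.4): 64, (60, 0.6): 29, (60, 0.8): 17, (60, 1.0): 11,
    (90, 0.2): 165, (90, 0.4): 44, (90, 0.6): 20, (90, 0.8): 12, (90, 1.0): 8,
    (180, 0.2): 100, (180, 0.4): 26, (180, 0.6): 12, (180, 0.8): 8, (180, 1.0): 6,
}

PUBLISHED_ALPHA = 0.05
PUBLISHED_POWER = 0.8
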