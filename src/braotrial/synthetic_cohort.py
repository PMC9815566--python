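"""Synthetic longitudinal OCT cohorts with the study's statistical structure.

The generator emulates a BRAO case series: each patient has an affected eye
and (usually) a healthy fellow eye; the affected quadrant's GCL follows the
single-phase decay curve on the %-change scale with additive Gaussian noise,
while every other (quadrant, layer) cell stays at its reference thickness.
Noise lives on the % scale — the scale the regression is fit on — and raw
micrometre thickness is back-computed from the reference value, so the
%-change pipeline recovers the generated values exactly.

Defaults mirror the study conditions: 17 patients, 1-5 scans each (about 38
scans in total), days 0-1040 after onset, decay truth y0 = -9.5 %,
plateau = -55.7 %, k = 0.01/day, and residual noise SD 24 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decay_model import single_phase_decay
from .normative import (
    DEFAULT_LAYERS,
    QUADRANTS,
    NormativeProfile,
    default_normative_profile,
)
from .thickness_io import COLUMNS, INNER_RING, write_thickness_table

# Truncated-geometric success probability for scans per patient; gives a
# mean of about 2.2 scans on the 1-5 range, matching 38 scans / 17 patients.
_SCAN_COUNT_P = 0.35

TRACKED_LAYER = "GCL"
EYE_CODES = ("OD", "OS")


class CohortParamsError(ValueError):
    """Invalid generator settings; the message names the offending field."""


@dataclass(frozen=True)
class CohortParams:
    """Settings for one synthetic cohort draw.

    ``true_y0``, ``true_plateau`` (% change, negative = thinning) and
    ``true_k`` (per day) define the ground-truth decay of the affected
    quadrant's GCL.  ``noise_sd`` is the %-scale residual scatter per scan;
    ``between_patient_sd_k`` adds patient-level heterogeneity to the decay
    rate (0 = none; truncated at k = 0).  ``scan_schedule`` is
    ``"geometric"`` (scan counts skewed toward single visits),
    ``"uniform"``, with days drawn uniformly over ``day_range``, or
    ``"early_weighted"`` (visit days concentrated early after onset).
    """

    n_patients: int = 17
    scans_per_patient_range: tuple[int, int] = (1, 5)
    day_range: tuple[int, int] = (0, 1040)
    true_y0: float = -9.5
    true_plateau: float = -55.7
    true_k: float = 0.01
    noise_sd: float = 24.0
    between_patient_sd_k: float = 0.0
    normative_profile: NormativeProfile | None = None
    affected_quadrant_policy: str = "random"
    affected_quadrant: str = "S"
    fellow_eye_missing_rate: float = 0.0
    scan_schedule: str = "geometric"
    layers: tuple[str, ...] = DEFAULT_LAYERS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise CohortParamsError("n_patients must be >= 1")
        lo, hi = self.scans_per_patient_range
        if not (1 <= lo <= hi):
            raise CohortParamsError(
                "scans_per_patient_range must satisfy 1 <= lo <= hi"
            )
        d0, d1 = self.day_range
        if not (0 <= d0 <= d1):
            raise CohortParamsError("day_range must satisfy 0 <= lo <= hi")
        if self.noise_sd < 0:
            raise CohortParamsError("noise_sd must be >= 0")
        if self.true_k < 0:
            raise CohortParamsError("true_k must be >= 0")
        if not (self.true_plateau <= self.true_y0 <= 0):
            raise CohortParamsError(
                "true_plateau <= true_y0 <= 0 required for a loss process"
            )
        if self.between_patient_sd_k < 0:
            raise CohortParamsError("between_patient_sd_k must be >= 0")
        if self.affected_quadrant_policy not in ("fixed", "random"):
            raise CohortParamsError(
                "affected_quadrant_policy must be 'fixed' or 'random'"
            )
        if self.affected_quadrant not in QUADRANTS:
            raise CohortParamsError("affected_quadrant must be one of T,S,N,I")
        if not 0.0 <= self.fellow_eye_missing_rate <= 1.0:
            raise CohortParamsError(
                "fellow_eye_missing_rate must be in [0, 1]"
            )
        if self.scan_schedule not in ("geometric", "uniform", "early_weighted"):
            raise CohortParamsError(
                "scan_schedule must be 'geometric', 'uniform' or "
                "'early_weighted'"
            )
        if TRACKED_LAYER not in self.layers:
            raise CohortParamsError(f"layers must include {TRACKED_LAYER!r}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus the ground-truth ledger."""

    records: pd.DataFrame
    truth: pd.DataFrame
    params: CohortParams

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records_path = out_dir / "thickness.csv"
        truth_path = out_dir / "truth.csv"
        write_thickness_table(self.records, records_path)
        self.truth.to_csv(truth_path, index=False)
        return records_path, truth_path


def _scan_count(rng: np.random.Generator, lo: int, hi: int,
                schedule: str) -> int:
    if lo == hi or schedule == "uniform":
        return int(rng.integers(lo, hi + 1))
    support = np.arange(lo, hi + 1)
    weights = (1.0 - _SCAN_COUNT_P) ** (support - lo)
    return int(rng.choice(support, p=weights / weights.sum()))


def _scan_days(rng: np.random.Generator, n: int, day_range: tuple[int, int],
               schedule: str) -> np.ndarray:
    lo, hi = day_range
    if hi == lo:
        return np.full(n, lo)
    days: set[int] = set()
    while len(days) < n:
        u = rng.random()
        if schedule == "early_weighted":
            u = u * u  # density ~ 1/sqrt(day): scans pile up early
        days.add(int(lo + round(u * (hi - lo))))
    return np.array(sorted(days))


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Draw one synthetic cohort; byte-identical output for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    normative = params.normative_profile or default_normative_profile(
        params.layers
    )
    lo, hi = params.scans_per_patient_range

    record_rows: list[tuple] = []
    truth_rows: list[dict] = []
    for idx in range(params.n_patients):
        patient_id = f"P{idx + 1:03d}"
        affected_eye = str(rng.choice(EYE_CODES))
        fellow_eye = "OS" if affected_eye == "OD" else "OD"
        has_fellow = rng.random() >= params.fellow_eye_missing_rate
        quadrant = (
            params.affected_quadrant
            if params.affected_quadrant_policy == "fixed"
            else str(rng.choice(QUADRANTS))
        )
        k_i = params.true_k
        if params.between_patient_sd_k > 0:
            k_i = max(0.0, k_i + rng.normal(0.0, params.between_patient_sd_k))

        # Reference thicknesses: one draw per eye, held constant over visits
        # (raw-scale visit-to-visit noise is not modelled).
        base_um = {}
        for q in QUADRANTS:
            for layer in params.layers:
                mean = normative.mean_um(q, layer)
                if has_fellow:
                    draw = rng.normal(mean, normative.sd_um(q, layer))
                    base_um[(q, layer)] = max(draw, 1.0)
                else:
                    base_um[(q, layer)] = mean

        n_scans = _scan_count(rng, lo, hi, params.scan_schedule)
        days = _scan_days(rng, n_scans, params.day_range, params.scan_schedule)
        for day in days:
            curve_pct = single_phase_decay(
                float(day), params.true_y0, params.true_plateau, k_i
            )
            applied_pct = curve_pct
            if params.noise_sd > 0:
                applied_pct += rng.normal(0.0, params.noise_sd)
            applied_pct = max(applied_pct, -100.0 + 1e-9)  # thickness > 0

            if has_fellow:
                for q in QUADRANTS:
                    for layer in params.layers:
                        record_rows.append((
                            patient_id, fellow_eye, "reference", int(day),
                            INNER_RING, q, layer, base_um[(q, layer)],
                        ))
            for q in QUADRANTS:
                for layer in params.layers:
                    um = base_um[(q, layer)]
                    if q == quadrant and layer == TRACKED_LAYER:
                        um = um * (1.0 + applied_pct / 100.0)
                    record_rows.append((
                        patient_id, affected_eye, "affected", int(day),
                        INNER_RING, q, layer, um,
                    ))
            truth_rows.append({
                "patient_id": patient_id,
                "day": int(day),
                "quadrant": quadrant,
                "layer": TRACKED_LAYER,
                "ring": INNER_RING,
                "has_fellow_eye": has_fellow,
                "true_y0": params.true_y0,
                "true_plateau": params.true_plateau,
                "true_k": k_i,
                "curve_pct_change": curve_pct,
                "applied_pct_change": applied_pct,
            })

    records = pd.DataFrame(record_rows, columns=list(COLUMNS))
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(records=records, truth=truth, params=params)


def simulate_percent_change_series(
    n_points: int,
    y0: float,
    plateau: float,
    k: float,
    noise_sd: float,
    day_range: tuple[float, float] = (0.0, 1040.0),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bare (days, %change) draws from the decay curve plus Gaussian noise.

    Days are continuous-uniform over ``day_range``.  This is the lightweight
    path for fit-recovery simulations that do not need full eye-level records.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    days = rng.uniform(day_range[0], day_range[1], size=n_points)
    pct = single_phase_decay(days, y0, plateau, k)
    if noise_sd > 0:
        pct = pct + rng.normal(0.0, noise_sd, size=n_points)
    return days, pct
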