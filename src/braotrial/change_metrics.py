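"""Percent thickness change and longitudinal series assembly.

The outcome statistic is the percent change of the affected eye relative to
its reference:

    %change = (-1) * (1 - affected / reference) * 100

Negative values mean thinning; 0 means no change; -100 means total loss.
Thickening (affected > reference) yields positive values and is retained —
the statistic admits it and measurement noise makes it inevitable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normative import NormativeProfile
from .thickness_io import INNER_RING, most_affected_quadrant, select_reference


@dataclass(frozen=True)
class PercentChangeSeries:
    """(day, %change) observations for one tracked quadrant/layer cell.

    ``data`` has columns ``patient_id``, ``day``, ``pct_change``; one row per
    OCT scan (scans are never averaged within a day — each is one regression
    observation).  ``quadrant`` is a single code in single-patient mode, or
    ``"most_affected"`` when patients track different quadrants.
    """

    data: pd.DataFrame
    layer: str
    quadrant: str
    ring: str = INNER_RING

    @property
    def days(self) -> np.ndarray:
        return self.data["day"].to_numpy(dtype=float)

    @property
    def pct_change(self) -> np.ndarray:
        return self.data["pct_change"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def percent_change(affected_um, reference_um):
    """Percent thickness change of the affected vs the reference eye.

    Accepts scalars or arrays; reference thickness must be positive and
    affected thickness nonnegative.
    """
    affected = np.asarray(affected_um, dtype=float)
    reference = np.asarray(reference_um, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference_um must be > 0")
    if np.any(affected < 0):
        raise ValueError("affected_um must be >= 0")
    result = (-1.0) * (1.0 - affected / reference) * 100.0
    return result if result.ndim else float(result)


def build_series(
    records: pd.DataFrame,
    normative: NormativeProfile | None = None,
    layer: str = "GCL",
    quadrant: str | None = None,
    ring: str = INNER_RING,
    mode: str = "aggregate",
):
    """Assemble %change series for the tracked quadrant of each patient.

    Parameters
    ----------
    records
        Validated thickness table (any number of patients).
    normative
        Fallback reference profile for patients without a fellow eye.
    quadrant
        Track this quadrant in every patient; ``None`` selects each patient's
        most affected quadrant at their earliest scan and holds it fixed.
    mode
        ``"aggregate"`` pools all patients' points into one series;
        ``"per_patient"`` returns a list with one series per patient.

    Returns
    -------
    PercentChangeSeries or list[PercentChangeSeries]
    """
    if mode not in ("aggregate", "per_patient"):
        raise ValueError(f"unknown mode {mode!r}")
    patients = records.loc[
        records["status"] == "affected", "patient_id"
    ].unique()
    if len(patients) == 0:
        raise ValueError("no affected-eye records in the table")

    per_patient: list[PercentChangeSeries] = []
    tracked_quadrants: set[str] = set()
    for patient_id in patients:
        patient = records[records["patient_id"] == patient_id]
        references = select_reference(patient, normative=normative, ring=ring)
        tracked = quadrant or most_affected_quadrant(
            patient, references, layer=layer, ring=ring
        )
        tracked_quadrants.add(tracked)
        reference_um = float(
            references.loc[
                (references["quadrant"] == tracked)
                & (references["layer"] == layer),
                "reference_um",
            ].iloc[0]
        )
        scans = patient[
            (patient["status"] == "affected")
            & (patient["ring"] == ring)
            & (patient["layer"] == layer)
            & (patient["quadrant"] == tracked)
        ].sort_values("day")
        if scans.empty:
            raise ValueError(
                f"patient {patient_id!r}: no affected scans in quadrant "
                f"{tracked!r}"
            )
        points = pd.DataFrame(
            {
                "patient_id": patient_id,
                "day": scans["day"].to_numpy(),
                "pct_change": percent_change(
                    scans["thickness_um"].to_numpy(), reference_um
                ),
            }
        )
        per_patient.append(
            PercentChangeSeries(
                data=points, layer=layer, quadrant=tracked, ring=ring
            )
        )

    if mode == "per_patient":
        return per_patient
    label = (
        tracked_quadrants.pop()
        if len(tracked_quadrants) == 1
        else "most_affected"
    )
    pooled = pd.concat([s.data for s in per_patient], ignore_index=True)
    return PercentChangeSeries(
        data=pooled, layer=layer, quadrant=label, ring=ring
    )
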