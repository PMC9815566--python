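"""Tabular thickness data model: reading, validation, reference selection.

One row of the CSV schema is one layer-thickness measurement:

    patient_id,eye,status,day,ring,quadrant,layer,thickness_um

``status`` marks the eye's role: ``affected`` (the BRAO eye), ``reference``
(the patient's healthy fellow eye) or ``normative`` (an eye from the
reference group).  ``day`` counts days since occlusion onset.  Quadrants are
the ETDRS temporal/superior/nasal/inferior sectors; ``ring`` selects the
3 mm inner or 6 mm outer ring.  Only the inner ring participates in the
default analysis; outer-ring rows are parsed and retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .normative import DEFAULT_LAYERS, QUADRANTS, NormativeProfile

EYES = ("OD", "OS")
STATUSES = ("affected", "reference", "normative")
RINGS = ("inner_3mm", "outer_6mm")
INNER_RING = "inner_3mm"

COLUMNS = (
    "patient_id", "eye", "status", "day", "ring", "quadrant", "layer",
    "thickness_um",
)

KEY_COLUMNS = ("patient_id", "eye", "day", "ring", "quadrant", "layer")


class ThicknessTableError(ValueError):
    """Malformed thickness table; the message names the offending file row."""


class ReferenceSelectionError(ValueError):
    """No usable reference thickness for a requested (quadrant, layer)."""


@dataclass(frozen=True)
class ThicknessRecord:
    """A single (patient, eye, visit-day, ring, quadrant, layer) measurement."""

    patient_id: str
    eye: str
    status: str
    day: int
    ring: str
    quadrant: str
    layer: str
    thickness_um: float


def _first_bad_row(mask: pd.Series) -> int:
    # +2: one for the header line, one for 0-based positions.
    return int(mask.idxmax()) + 2


def validate_records(
    df: pd.DataFrame, layers: Iterable[str] = DEFAULT_LAYERS
) -> pd.DataFrame:
    """Validate a thickness table in-memory; returns the validated frame.

    Raises :class:`ThicknessTableError` naming the first offending file row
    (header counted as row 1).
    """
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ThicknessTableError(f"missing column(s): {sorted(missing)}")
    df = df.reset_index(drop=True)

    checks = [
        (~df["eye"].isin(EYES), "unknown eye code"),
        (~df["status"].isin(STATUSES), "unknown status"),
        (~df["ring"].isin(RINGS), "unknown ring"),
        (~df["quadrant"].isin(QUADRANTS), "unknown quadrant code"),
        (~df["layer"].isin(tuple(layers)), "unknown layer code"),
    ]
    day = pd.to_numeric(df["day"], errors="coerce")
    checks.append((day.isna() | (day < 0) | (day != day.round()),
                   "day must be a nonnegative integer"))
    thick = pd.to_numeric(df["thickness_um"], errors="coerce")
    checks.append((thick.isna() | (thick <= 0), "thickness_um must be > 0"))
    for mask, message in checks:
        if mask.any():
            raise ThicknessTableError(f"row {_first_bad_row(mask)}: {message}")

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep="first")
    if dup.any():
        raise ThicknessTableError(
            f"row {_first_bad_row(dup)}: duplicate "
            f"(patient, eye, day, ring, quadrant, layer) key"
        )

    out = df.copy()
    out["day"] = day.astype(int)
    out["thickness_um"] = thick.astype(float)
    out["patient_id"] = out["patient_id"].astype(str)
    return out


def read_thickness_table(
    path: str | Path, layers: Iterable[str] = DEFAULT_LAYERS
) -> pd.DataFrame:
    """Read and validate a thickness CSV into a records DataFrame."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    return validate_records(df, layers=layers)


def write_thickness_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a records DataFrame in the canonical CSV schema."""
    df.loc[:, list(COLUMNS)].to_csv(path, index=False)


def select_reference(
    patient_records: pd.DataFrame,
    normative: NormativeProfile | None = None,
    ring: str = INNER_RING,
) -> pd.DataFrame:
    """Choose the reference thickness for every affected (quadrant, layer).

    The healthy fellow eye (``status == "reference"``) takes precedence; when
    the patient has none, the normative profile's quadrant/layer mean is used.
    Each cell comes from exactly one source, flagged in the ``source`` column
    (``fellow_eye`` or ``normative``).

    Returns
    -------
    DataFrame with columns ``quadrant``, ``layer``, ``reference_um``,
    ``source``.
    """
    affected = patient_records[
        (patient_records["status"] == "affected")
        & (patient_records["ring"] == ring)
    ]
    if affected.empty:
        raise ReferenceSelectionError("patient has no affected-eye records")
    fellow = patient_records[
        (patient_records["status"] == "reference")
        & (patient_records["ring"] == ring)
    ]
    # Fellow-eye thickness per cell, averaged over visits (the healthy eye is
    # treated as stable; raw-scale visit noise is not modelled).
    fellow_means = (
        fellow.groupby(["quadrant", "layer"])["thickness_um"].mean()
        if not fellow.empty
        else pd.Series(dtype=float)
    )

    rows = []
    cells = affected[["quadrant", "layer"]].drop_duplicates()
    for quadrant, layer in cells.itertuples(index=False):
        if (quadrant, layer) in fellow_means.index:
            rows.append((quadrant, layer,
                         float(fellow_means[(quadrant, layer)]), "fellow_eye"))
        elif normative is not None and normative.has(quadrant, layer):
            rows.append((quadrant, layer,
                         normative.mean_um(quadrant, layer), "normative"))
        else:
            raise ReferenceSelectionError(
                f"no fellow-eye or normative reference for "
                f"quadrant={quadrant!r}, layer={layer!r}"
            )
    return pd.DataFrame(
        rows, columns=["quadrant", "layer", "reference_um", "source"]
    )


def most_affected_quadrant(
    patient_records: pd.DataFrame,
    references: pd.DataFrame,
    layer: str = "GCL",
    ring: str = INNER_RING,
) -> str:
    """Quadrant with the largest percent loss at the patient's earliest scan.

    The quadrant is chosen once, at the earliest visit, and is meant to be
    held fixed over follow-up.  Ties break deterministically in the fixed
    order T < S < N < I.  "Most affected" is operationalised as the most
    negative percent change relative to the reference thickness.
    """
    affected = patient_records[
        (patient_records["status"] == "affected")
        & (patient_records["ring"] == ring)
        & (patient_records["layer"] == layer)
    ]
    if affected.empty:
        raise ReferenceSelectionError(
            f"no affected-eye records for layer={layer!r}, ring={ring!r}"
        )
    earliest = affected[affected["day"] == affected["day"].min()]
    ref_lookup = {
        (r.quadrant, r.layer): r.reference_um for r in references.itertuples()
    }
    best_quadrant, best_change = None, None
    for quadrant in QUADRANTS:  # fixed order doubles as the tie-break
        rows = earliest[earliest["quadrant"] == quadrant]
        if rows.empty or (quadrant, layer) not in ref_lookup:
            continue
        reference = ref_lookup[(quadrant, layer)]
        thickness = float(rows["thickness_um"].iloc[0])
        change = (-1.0) * (1.0 - thickness / reference) * 100.0
        if best_change is None or change < best_change:
            best_quadrant, best_change = quadrant, change
    if best_quadrant is None:
        raise ReferenceSelectionError(
            "no quadrant with both an affected measurement and a reference"
        )
    return best_quadrant
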