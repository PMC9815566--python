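"""Normative (non-BRAO) retinal layer thickness profile.

A normative profile supplies per-(quadrant, layer) mean and SD thicknesses
from a reference group of healthy eyes.  It is the fallback reference when a
patient has no healthy fellow eye.  The default values below are documented
placeholders with realistic magnitudes (e.g. GCL close to 50 um in the inner
3 mm ring); they are configuration plumbing, not measured study values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

QUADRANTS = ("T", "S", "N", "I")

#: Default layer vocabulary: eleven Spectralis segmentation outputs.
DEFAULT_LAYERS = (
    "RNFL", "GCL", "IPL", "INL", "OPL", "ONL",
    "PR", "RPE", "IRL", "ORL", "RET",
)

# Placeholder inner-ring means (um); quadrant offsets model the mild
# T < I/S < N asymmetry of macular thickness maps.
_BASE_MEAN_UM = {
    "RNFL": 24.0, "GCL": 50.0, "IPL": 42.0, "INL": 40.0, "OPL": 32.0,
    "ONL": 68.0, "PR": 84.0, "RPE": 15.0, "IRL": 188.0, "ORL": 152.0,
    "RET": 340.0,
}
_QUADRANT_OFFSET_UM = {"T": -2.0, "S": 1.0, "N": 2.0, "I": 0.5}


class NormativeProfileError(ValueError):
    """Raised when a profile is malformed or missing a requested cell."""


@dataclass(frozen=True)
class NormativeProfile:
    """Per-(quadrant, layer) reference thickness statistics.

    Parameters
    ----------
    values
        DataFrame with columns ``quadrant``, ``layer``, ``mean_um``, ``sd_um``;
        one row per (quadrant, layer) cell.
    source_n
        Number of reference eyes the statistics were derived from.
    """

    values: pd.DataFrame
    source_n: int = 9
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        required = {"quadrant", "layer", "mean_um", "sd_um"}
        missing = required - set(self.values.columns)
        if missing:
            raise NormativeProfileError(
                f"normative profile missing columns: {sorted(missing)}"
            )
        if (self.values["mean_um"] <= 0).any():
            raise NormativeProfileError("normative means must be > 0")
        if (self.values["sd_um"] < 0).any():
            raise NormativeProfileError("normative SDs must be >= 0")
        if self.source_n < 1:
            raise NormativeProfileError("source_n must be >= 1")
        dup = self.values.duplicated(subset=["quadrant", "layer"])
        if dup.any():
            raise NormativeProfileError("duplicate (quadrant, layer) cells")
        idx = {
            (r.quadrant, r.layer): (float(r.mean_um), float(r.sd_um))
            for r in self.values.itertuples()
        }
        object.__setattr__(self, "_index", idx)

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.values["layer"]))

    def has(self, quadrant: str, layer: str) -> bool:
        return (quadrant, layer) in self._index

    def mean_um(self, quadrant: str, layer: str) -> float:
        try:
            return self._index[(quadrant, layer)][0]
        except KeyError:
            raise NormativeProfileError(
                f"normative profile has no cell for quadrant={quadrant!r}, "
                f"layer={layer!r}"
            ) from None

    def sd_um(self, quadrant: str, layer: str) -> float:
        try:
            return self._index[(quadrant, layer)][1]
        except KeyError:
            raise NormativeProfileError(
                f"normative profile has no cell for quadrant={quadrant!r}, "
                f"layer={layer!r}"
            ) from None


def default_normative_profile(
    layers: tuple[str, ...] = DEFAULT_LAYERS, source_n: int = 9
) -> NormativeProfile:
    """Build the documented placeholder profile for the given layer set."""
    rows = []
    for layer in layers:
        base = _BASE_MEAN_UM.get(layer, 40.0)
        for quadrant in QUADRANTS:
            mean = base + _QUADRANT_OFFSET_UM[quadrant]
            rows.append(
                {
                    "quadrant": quadrant,
                    "layer": layer,
                    "mean_um": mean,
                    "sd_um": max(1.5, 0.06 * mean),
                }
            )
    return NormativeProfile(values=pd.DataFrame(rows), source_n=source_n)
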