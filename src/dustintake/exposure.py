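"""The daily-intake model and ADI risk normalization.

Daily intake via incidental ingestion of dust or soil:

    intake (ug/kg/day) = IR (mg/day) * C (ug/g) * CF (g/mg) / BW (kg)

with CF = 1e-3 converting milligrams of ingested matrix to grams so the
units close.  Risk is characterized as intake expressed as a percentage of
the compound's Acceptable Daily Intake (ADI, mg/kg/day).

Units are fixed package-wide exactly as above; anything else must be
converted at the configuration boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .distributions import LognormalSpec, combine_product_quotient
from .errors import DataError

__all__ = [
    "CONVERSION_FACTOR",
    "ADI_REGISTRY",
    "ExposureScenario",
    "intake_from_draw",
    "percent_of_adi",
]

#: mg -> g conversion closing the IR (mg/day) x C (ug/g) units.
CONVERSION_FACTOR = 1e-3

#: WHO Acceptable Daily Intakes, mg/kg body weight/day.
ADI_REGISTRY = {
    "chlorpyrifos": 0.01,
    "cypermethrin": 0.02,
}


@dataclass(frozen=True)
class ExposureScenario:
    """One compound x one route: the bound symbol table of the intake equation.

    Attributes
    ----------
    compound, route
        Labels, e.g. ``"chlorpyrifos"`` / ``"indoor_dust"``.
    ir, conc, bw
        Lognormal laws of ingestion rate (mg/day), matrix concentration
        (ug/g) and child body weight (kg).
    adi
        Acceptable daily intake in mg/kg/day (> 0); required explicitly for
        compounds outside :data:`ADI_REGISTRY`.
    cf
        Conversion factor in g/mg, fixed at 1e-3 unless overridden.
    """

    compound: str
    route: str
    ir: LognormalSpec
    conc: LognormalSpec
    bw: LognormalSpec
    adi: float
    cf: float = CONVERSION_FACTOR

    def __post_init__(self) -> None:
        if not self.adi > 0:
            raise DataError(f"ADI must be > 0, got {self.adi!r}")
        if not self.cf > 0:
            raise DataError(f"conversion factor must be > 0, got {self.cf!r}")

    @property
    def label(self) -> str:
        return f"{self.compound}_{self.route}"

    def intake_spec(self) -> LognormalSpec:
        """Closed-form lognormal law of daily intake (ug/kg/day)."""
        return combine_product_quotient(
            [self.ir, self.conc], [self.bw], scale=self.cf, unit_label="ug/kg/day"
        )

    def pct_adi_spec(self) -> LognormalSpec:
        """Closed-form lognormal law of intake as % of ADI."""
        # percent = intake * 100 / (1000 * adi); fold the constant into the scale
        return combine_product_quotient(
            [self.ir, self.conc],
            [self.bw],
            scale=self.cf * 100.0 / (1000.0 * self.adi),
            unit_label="% of ADI",
        )

    def with_adi(self, adi: float) -> "ExposureScenario":
        return replace(self, adi=adi)


def intake_from_draw(ir, conc, bw, cf: float = CONVERSION_FACTOR):
    """Daily intake in ug/kg/day for one draw (or vector of draws).

    ``ir`` in mg/day, ``conc`` in ug/g, ``bw`` in kg, ``cf`` in g/mg.
    """
    bw_arr = np.asarray(bw, dtype=float)
    if np.any(bw_arr <= 0):
        raise DataError("body weight must be > 0")
    if cf <= 0:
        raise DataError("conversion factor must be > 0")
    out = np.asarray(ir, dtype=float) * np.asarray(conc, dtype=float) * cf / bw_arr
    if np.any(out < 0):
        raise DataError("ingestion rate and concentration must be >= 0")
    return float(out) if out.ndim == 0 else out


def percent_of_adi(intake, adi: float):
    """Express intake (ug/kg/day) as percent of an ADI given in mg/kg/day."""
    if not adi > 0:
        raise DataError(f"ADI must be > 0, got {adi!r}")
    out = np.asarray(intake, dtype=float) * 100.0 / (1000.0 * adi)
    return float(out) if out.ndim == 0 else out
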