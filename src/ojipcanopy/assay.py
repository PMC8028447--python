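"""Spectrophotometric chlorophyll quantification from ethanol leaf extracts.

A leaf disk (default diameter 0.85 cm) is soaked in 95% ethanol (default
1.8 mL) and the extract's absorbance read at 470, 649 and 665 nm.  Chlorophyll
a and b concentrations (ug/mL) follow the Lichtenthaler equations for 95%
ethanol; total concentration times extract volume over disk area gives the
per-area content in ug/cm2.  The 470-nm reading serves carotenoid equations
and is carried through unused here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import AssayInconsistencyError, ValidationError

#: Lichtenthaler 95%-ethanol coefficients, ug/mL per absorbance unit,
#: as (coefficient on A665, coefficient on A649).  Configurable because
#: laboratory standard curves differ slightly between protocols.
CHL_A_COEFFS = (13.36, -5.19)
CHL_B_COEFFS = (-8.12, 27.43)


@dataclass(frozen=True)
class AbsorbanceReading:
    """One extract's absorbances plus the extraction geometry."""

    A470: float
    A649: float
    A665: float
    extract_volume_ml: float = 1.8
    disk_diameter_cm: float = 0.85

    def __post_init__(self) -> None:
        for name in ("A470", "A649", "A665"):
            a = getattr(self, name)
            if not math.isfinite(a) or a < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {a!r}")
        if self.extract_volume_ml <= 0 or self.disk_diameter_cm <= 0:
            raise ValidationError("extract volume and disk diameter must be positive")

    @property
    def disk_area_cm2(self) -> float:
        return math.pi * (self.disk_diameter_cm / 2.0) ** 2


def pigment_concentrations(
    reading: AbsorbanceReading,
    chl_a_coeffs: tuple[float, float] = CHL_A_COEFFS,
    chl_b_coeffs: tuple[float, float] = CHL_B_COEFFS,
) -> tuple[float, float]:
    """(Chl a, Chl b) concentrations in ug/mL.

    A negative concentration is physically impossible and raises
    :class:`AssayInconsistencyError` — the usual causes are swapped
    wavelengths or a failed blank.
    """
    chl_a = chl_a_coeffs[0] * reading.A665 + chl_a_coeffs[1] * reading.A649
    chl_b = chl_b_coeffs[0] * reading.A665 + chl_b_coeffs[1] * reading.A649
    if chl_a < 0 or chl_b < 0:
        raise AssayInconsistencyError(
            f"negative pigment concentration (Chl a = {chl_a:.4g}, Chl b = {chl_b:.4g} "
            "ug/mL): check wavelength assignment and blank"
        )
    return chl_a, chl_b


def chlorophyll_content(
    reading: AbsorbanceReading,
    chl_a_coeffs: tuple[float, float] = CHL_A_COEFFS,
    chl_b_coeffs: tuple[float, float] = CHL_B_COEFFS,
) -> float:
    """Total chlorophyll content per leaf area, ug/cm2."""
    chl_a, chl_b = pigment_concentrations(reading, chl_a_coeffs, chl_b_coeffs)
    return (chl_a + chl_b) * reading.extract_volume_ml / reading.disk_area_cm2


def process_assay_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append a ``chl_ug_cm2`` column to an assay table.

    Expects columns ``A470, A649, A665`` (plus any identifying metadata, which
    is passed through); optional ``extract_volume_ml`` / ``disk_diameter_cm``
    columns override the defaults row-wise.
    """
    missing = [c for c in ("A470", "A649", "A665") if c not in df.columns]
    if missing:
        raise ValidationError(f"assay table missing column(s) {missing}")
    out = df.copy()
    contents = []
    for _, row in df.iterrows():
        kwargs = {}
        if "extract_volume_ml" in df.columns:
            kwargs["extract_volume_ml"] = float(row["extract_volume_ml"])
        if "disk_diameter_cm" in df.columns:
            kwargs["disk_diameter_cm"] = float(row["disk_diameter_cm"])
        reading = AbsorbanceReading(
            A470=float(row["A470"]), A649=float(row["A649"]), A665=float(row["A665"]), **kwargs
        )
        contents.append(chlorophyll_content(reading))
    out["chl_ug_cm2"] = contents
    return out
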