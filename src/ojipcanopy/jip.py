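"""JIP-test analysis of OJIP transients.

The JIP test (Strasser's framework) reads a handful of landmarks off the fast
polyphasic fluorescence rise — F0 at 50 us (step O), F at 300 us, FJ at 2 ms
(step J), FI at 30 ms (step I), and the peak FM (= FP) — and derives from
them the PSII energy-flux panel: quantum yields (phi_Po = Fv/Fm, psi_Eo,
phi_Eo, phi_Ro), specific fluxes per Q_A-reducing reaction centre (ABS/RC,
TR0/RC, ET0/RC, DI0/RC, RE0/RC), phenomenological fluxes per excited
cross-section (ABS/CS ~ FM and friends), the RC density RC/CS, the
complementary-area statistics Sm and N, and the performance index PI_ABS.

Two formula variants are provided for the three quantities on which published
formulations disagree (RE0/RC, ET0/CS, RE0/CS): ``as_printed`` keeps the
extra yield factors of the formulation this package follows by default, while
``strasser_standard`` uses the forms most common in the JIP-test literature
(RE0/RC = M0*(1/VJ)*(1-VI), ET0/CS = phi_Eo*ABS/CS, RE0/CS = phi_Ro*ABS/CS).
All other parameters are identical between variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateTransientError, UndefinedParameterError
from .transients import T_F0, T_F300, T_FI, T_FJ, Transient, fluorescence_at

Variant = Literal["as_printed", "strasser_standard"]
VARIANTS = ("as_printed", "strasser_standard")

#: Fields of the derived panel whose formulas differ between variants.
VARIANT_DEPENDENT_FIELDS = ("RE0_RC", "ET0_CS", "RE0_CS")

#: Canonical ordering of the derived-parameter panel (used for CSV output and
#: as the feature set of the importance analysis).
JIP_PARAMETER_NAMES = (
    "VJ", "VI", "M0", "Sm", "N",
    "phi_Po", "psi_Eo", "phi_Eo", "phi_Ro",
    "ABS_RC", "TR0_RC", "ET0_RC", "DI0_RC", "RE0_RC",
    "ABS_CS", "TR0_CS", "ET0_CS", "DI0_CS", "RE0_CS",
    "RC_CS", "PI_ABS",
)


@dataclass(frozen=True)
class Landmarks:
    """Raw landmarks of one OJIP transient.

    ``area`` is the total complementary area between the induction curve and
    the horizontal F = FM, integrated from the first sample to ``t_fm``, with
    time in milliseconds (so Sm = area / (FM - F0) is in ms).
    """

    F0: float
    F300: float
    FJ: float
    FI: float
    FM: float
    t_fm: float
    area: float

    def __post_init__(self) -> None:
        if self.FM < max(self.F0, self.F300, self.FJ, self.FI):
            raise DegenerateTransientError("FM must be the maximum landmark value")
        if self.area < 0:
            raise DegenerateTransientError("complementary area must be non-negative")


@dataclass(frozen=True)
class JipParameters:
    """Full derived JIP-test panel for one transient."""

    VJ: float
    VI: float
    M0: float
    Sm: float
    N: float
    phi_Po: float
    psi_Eo: float
    phi_Eo: float
    phi_Ro: float
    ABS_RC: float
    TR0_RC: float
    ET0_RC: float
    DI0_RC: float
    RE0_RC: float
    ABS_CS: float
    TR0_CS: float
    ET0_CS: float
    DI0_CS: float
    RE0_CS: float
    RC_CS: float
    PI_ABS: float
    variant: str = "as_printed"

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in JIP_PARAMETER_NAMES}


def relative_variable_fluorescence(F_t: float, F0: float, FM: float) -> float:
    """V_t = (F_t - F0) / (FM - F0); VJ and VI are this at FJ and FI."""
    if FM <= F0:
        raise DegenerateTransientError("FM must exceed F0 for variable fluorescence")
    return (F_t - F0) / (FM - F0)


def initial_slope_m0(F0: float, F300: float, FM: float) -> float:
    """Approximate initial slope of relative variable fluorescence,
    M0 = 4 * (F300us - F0) / (FM - F0), in 1/ms."""
    if FM <= F0:
        raise DegenerateTransientError("FM must exceed F0 for M0")
    if F300 < F0:
        warnings.warn("F300 < F0: negative initial slope; noisy O-phase?", stacklevel=2)
    return 4.0 * (F300 - F0) / (FM - F0)


def complementary_area(
    transient: Transient, FM: float, t_fm: float
) -> tuple[float, float, float]:
    """(Area, Sm, N) for one transient.

    Area is the trapezoidal integral of (FM - F(t)) from the first recorded
    sample to ``t_fm``, with time in milliseconds; Sm = Area / (FM - F0)
    normalises it to single-turnover units, and N = Sm * M0 * (1/VJ) counts
    Q_A reduction events up to the fluorescence peak.
    """
    F0 = fluorescence_at(transient, T_F0)
    if FM <= F0:
        raise DegenerateTransientError("FM must exceed F0 for the complementary area")
    mask = transient.times <= t_fm
    times_ms = transient.times[mask] * 1e3
    deficit = FM - transient.values[mask]
    if times_ms.size < 2:
        return 0.0, 0.0, 0.0
    area = float(np.trapezoid(deficit, times_ms))
    area = max(area, 0.0)
    sm = area / (FM - F0)
    F300 = fluorescence_at(transient, T_F300)
    FJ = fluorescence_at(transient, T_FJ)
    m0 = initial_slope_m0(F0, F300, FM)
    vj = relative_variable_fluorescence(FJ, F0, FM)
    n = sm * m0 / vj if vj > 0 else 0.0
    return area, sm, n


def extract_landmarks(transient: Transient) -> Landmarks:
    """Read the OJIP landmarks off a transient.

    F0, F300, FJ, FI are linear interpolations at 50 us / 300 us / 2 ms /
    30 ms; FM is the maximum recorded value with ties broken by earliest
    time.  Raises :class:`DegenerateTransientError` when the curve carries no
    variable fluorescence (FM <= F0).
    """
    F0 = fluorescence_at(transient, T_F0)
    F300 = fluorescence_at(transient, T_F300)
    FJ = fluorescence_at(transient, T_FJ)
    FI = fluorescence_at(transient, T_FI)
    i_max = int(np.argmax(transient.values))  # argmax returns the first maximum
    FM = float(transient.values[i_max])
    t_fm = float(transient.times[i_max])
    if FM - F0 <= 0:
        raise DegenerateTransientError(
            f"{transient.sample_id!r}: no variable fluorescence (FM <= F0)"
        )
    area, _, _ = complementary_area(transient, FM, t_fm)
    return Landmarks(F0=F0, F300=F300, FJ=FJ, FI=FI, FM=FM, t_fm=t_fm, area=area)


def compute_jip_parameters(
    landmarks: Landmarks,
    M0: float,
    Sm: float,
    variant: Variant = "as_printed",
) -> JipParameters:
    """Derive the full JIP-test panel from landmarks plus M0 and Sm.

    Requires FM > F0, 0 < VJ < 1 and phi_Po > 0; otherwise raises
    :class:`UndefinedParameterError` (or :class:`DegenerateTransientError`
    for FM <= F0).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    F0, FM = landmarks.F0, landmarks.FM
    vj = relative_variable_fluorescence(landmarks.FJ, F0, FM)
    vi = relative_variable_fluorescence(landmarks.FI, F0, FM)
    if not 0.0 < vj < 1.0:
        raise UndefinedParameterError(f"VJ = {vj:g} outside (0, 1)")
    phi_po = 1.0 - F0 / FM
    if phi_po <= 0.0:
        raise UndefinedParameterError("phi_Po = 0: no photochemistry")
    psi_eo = 1.0 - vj
    phi_eo = phi_po * psi_eo
    phi_ro = phi_po * (1.0 - vi)

    tr0_rc = M0 / vj
    abs_rc = tr0_rc / phi_po
    et0_rc = tr0_rc * psi_eo
    di0_rc = abs_rc - tr0_rc

    abs_cs = FM
    tr0_cs = phi_po * abs_cs
    di0_cs = abs_cs - tr0_cs
    rc_abs = phi_po * (vj / M0)
    rc_cs = rc_abs * abs_cs
    pi_abs = rc_abs * (phi_po / (1.0 - phi_po)) * (psi_eo / (1.0 - psi_eo))

    if variant == "as_printed":
        re0_rc = M0 * (1.0 / vj) * psi_eo * phi_ro
        et0_cs = phi_po * phi_eo * abs_cs
        re0_cs = phi_eo * phi_ro * abs_cs
    else:
        re0_rc = M0 * (1.0 / vj) * (1.0 - vi)
        et0_cs = phi_eo * abs_cs
        re0_cs = phi_ro * abs_cs

    n = Sm * M0 / vj
    return JipParameters(
        VJ=vj, VI=vi, M0=M0, Sm=Sm, N=n,
        phi_Po=phi_po, psi_Eo=psi_eo, phi_Eo=phi_eo, phi_Ro=phi_ro,
        ABS_RC=abs_rc, TR0_RC=tr0_rc, ET0_RC=et0_rc, DI0_RC=di0_rc, RE0_RC=re0_rc,
        ABS_CS=abs_cs, TR0_CS=tr0_cs, ET0_CS=et0_cs, DI0_CS=di0_cs, RE0_CS=re0_cs,
        RC_CS=rc_cs, PI_ABS=pi_abs, variant=variant,
    )


def jip_panel(transient: Transient, variant: Variant = "as_printed") -> tuple[Landmarks, JipParameters]:
    """Convenience: landmarks + full derived panel for one transient."""
    lm = extract_landmarks(transient)
    m0 = initial_slope_m0(lm.F0, lm.F300, lm.FM)
    sm = lm.area / (lm.FM - lm.F0)
    return lm, compute_jip_parameters(lm, m0, sm, variant=variant)


def double_normalize(transient: Transient) -> np.ndarray:
    """Double-normalise a transient between F0 and the peak FP.

    Returns (F(t) - F0) / (FP - F0) at the recorded times: 0 at the F0 anchor
    and 1 at the peak, removing between-sample differences in absolute
    intensity.
    """
    F0 = fluorescence_at(transient, T_F0)
    FP = float(np.max(transient.values))
    if FP <= F0:
        raise DegenerateTransientError("cannot normalise a non-variable transient")
    return (transient.values - F0) / (FP - F0)


def classify_ji_phase(landmarks: Landmarks, delta: float = 0.01) -> str:
    """Classify the J-to-I phase as ``JI_rise``, ``JI_fall`` or ``flat``.

    A JI-fall (FI below FJ beyond the relative tolerance ``delta``) marks fast
    re-oxidation of the plastoquinone pool, typical of young sink leaves; the
    canonical polyphasic rise has FI above FJ.
    """
    if landmarks.FI < landmarks.FJ * (1.0 - delta):
        return "JI_fall"
    if landmarks.FI > landmarks.FJ * (1.0 + delta):
        return "JI_rise"
    return "flat"
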