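"""Synthetic OJIP transients and canopy datasets with known ground truth.

The transient generator is phenomenological: a sum of three saturating
exponentials standing for the O-J (Q_A reduction), J-I (plastoquinone-pool
reduction) and I-P (PSI acceptor-side reduction) phases,

    S(t) = wOJ*(1 - exp(-t/tauOJ)) + wJI*(1 - exp(-t/tauJI)) + wIP*(1 - exp(-t/tauIP))
    F(t) = F0 + amplitude * S(t) / max S,

with default time constants 0.25 ms / 5 ms / 80 ms.  A negative middle-phase
weight wJI produces the JI-fall morphology of young sink leaves; positive wJI
gives the canonical polyphasic rise.  Because the curve is closed-form, every
landmark has an exact ground truth, making extraction tests exact oracles.
Measurement noise is multiplicative Gaussian per sample point.

The canopy generator composes these transients into a full factorial trial:
3 nitrogen levels x 8 growth stages x 3-5 canopy layers x replicates, with
(i) a vertical chlorophyll profile whose layer slope flips sign at a
configurable, nitrogen-dependent reversal stage (bottom-heavy early,
top-heavy late — earlier under nitrogen deficit, later under surplus),
(ii) within-leaf basal->top gradients (increasing in upper layers, decreasing
in lower), (iii) stage-driven JI morphology (vegetative leaves JI-fall,
reproductive JI-rise), and (iv) a planted chlorophyll dependence targeting
the PSI end-acceptor flux per cross-section, RE0/CS = phi_Eo*phi_Ro*FM:
a leaf's chlorophyll scales the transient amplitude (more pigment, more
absorbed light) and, more strongly, sets a target value of the noise-free
RE0/CS itself, which the generator realises exactly by solving for the I-P
phase weight given the other shape parameters.  Because FM = F0 + amplitude
is independent of the phase weights, this inverse step absorbs the
amplitude jitter, so RE0/CS is the designed best single predictor of
chlorophyll while FM-proportional fluxes and the solo yield ratios carry the
leaf-to-leaf jitter in full.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ParameterError
from .jip import Landmarks
from .transients import (
    DEFAULT_GRID,
    LAYERS,
    STAGES,
    T_F0,
    T_F300,
    T_FI,
    T_FJ,
    VEGETATIVE_STAGES,
    InstrumentGrid,
    Transient,
)


@dataclass(frozen=True)
class OjipShapeParams:
    """Closed-form shape of one synthetic transient."""

    f0: float = 500.0
    amplitude: float = 2000.0
    w_oj: float = 1.0
    w_ji: float = 0.4
    w_ip: float = 0.3
    tau_oj: float = 0.25e-3
    tau_ji: float = 5e-3
    tau_ip: float = 80e-3
    noise_cv: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.amplitude <= 0:
            raise ParameterError("f0 and amplitude must be positive")
        if not self.tau_oj < self.tau_ji < self.tau_ip:
            raise ParameterError("time constants must be strictly increasing")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")

    def shape(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        return (
            self.w_oj * (1.0 - np.exp(-t / self.tau_oj))
            + self.w_ji * (1.0 - np.exp(-t / self.tau_ji))
            + self.w_ip * (1.0 - np.exp(-t / self.tau_ip))
        )


@dataclass(frozen=True)
class OjipGroundTruth:
    """Noise-free landmark values implied by the closed form on a grid."""

    F0: float
    F300: float
    FJ: float
    FI: float
    FM: float
    t_fm: float
    VJ: float
    VI: float
    M0: float


def _noise_free_curve(params: OjipShapeParams, grid: InstrumentGrid) -> tuple[np.ndarray, np.ndarray]:
    times = grid.times()
    s = np.asarray(params.shape(times), dtype=float)
    s_max = float(s.max())
    if s_max <= 0:
        raise ParameterError("shape maximum must be positive")
    values = params.f0 + params.amplitude * s / s_max
    if np.any(values <= 0):
        raise ParameterError("shape parameters yield a non-positive curve")
    return times, values


def ojip_ground_truth(params: OjipShapeParams, grid: InstrumentGrid = DEFAULT_GRID) -> OjipGroundTruth:
    """Exact landmarks of the noise-free closed form evaluated on ``grid``."""
    times, values = _noise_free_curve(params, grid)
    s_max = float(np.asarray(params.shape(times)).max())

    def f_at(t: float) -> float:
        return params.f0 + params.amplitude * float(params.shape(t)) / s_max

    i_max = int(np.argmax(values))
    f0, f300 = f_at(T_F0), f_at(T_F300)
    fj, fi = f_at(T_FJ), f_at(T_FI)
    fm = float(values[i_max])
    return OjipGroundTruth(
        F0=f0, F300=f300, FJ=fj, FI=fi, FM=fm, t_fm=float(times[i_max]),
        VJ=(fj - f0) / (fm - f0), VI=(fi - f0) / (fm - f0),
        M0=4.0 * (f300 - f0) / (fm - f0),
    )


def simulate_ojip(
    params: OjipShapeParams,
    grid: InstrumentGrid = DEFAULT_GRID,
    *,
    sample_id: str = "sim",
    nitrogen: str = "N1",
    stage: str = "V1",
    layer: str = "L1",
    rng: np.random.Generator | None = None,
) -> tuple[Transient, OjipGroundTruth]:
    """Simulate one transient on ``grid`` and return it with its ground truth.

    Multiplicative Gaussian noise with coefficient of variation ``noise_cv``
    is applied per point, drawn from ``rng`` or from ``params.seed`` (the same
    seed reproduces the same curve bitwise).
    """
    times, values = _noise_free_curve(params, grid)
    truth = ojip_ground_truth(params, grid)
    if params.noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        values = values * (1.0 + params.noise_cv * rng.standard_normal(values.size))
        values = np.maximum(values, 1e-9)  # multiplicative noise; keep physical
    return (
        Transient(sample_id=sample_id, nitrogen=nitrogen, stage=stage, layer=layer,
                  times=times, values=values),
        truth,
    )


def _default_layers_per_stage() -> dict[str, int]:
    # three expanded leaves at initial tillering, five from jointing onward
    return {"V1": 3, "V2": 4, "V3": 5, "R1": 5, "R2": 5, "R3": 5, "R4": 5, "R5": 5}


@dataclass(frozen=True)
class CanopyDesign:
    """Study design of a synthetic canopy trial.

    Chlorophyll (ug/cm2) for layer rank r of n layers:
    ``chl_base + nitrogen_effect + slope * (r - (n+1)/2) + N(0, chl_noise_sd)``
    per leaf portion, where ``slope`` is ``layer_slope_pre`` (< 0,
    bottom-heavy) before the nitrogen level's reversal stage and
    ``layer_slope_post`` (> 0, top-heavy) from it onward.  Portions add a
    relative basal->top gradient of magnitude ``portion_gradient`` —
    increasing in the upper half of the canopy, decreasing in the lower.

    ``coupling`` scales the planted chlorophyll -> RE0/CS dependence
    (0 = none): with leaf-relative chlorophyll ``rel = coupling *
    (chl - chl_base) / chl_base``, the transient amplitude is scaled by
    ``1 + AMPLITUDE_ROUTE_GAIN * rel`` and the noise-free RE0/CS is driven
    to ``re0cs_base * (1 + RE0CS_ROUTE_GAIN * rel)`` (up to
    ``re0cs_noise_cv``) by solving for the I-P weight.  All randomness
    derives from ``seed`` through one spawned child stream per leaf, so
    datasets are bitwise reproducible.
    """

    reversal_stage: Mapping[str, str] = field(
        default_factory=lambda: {"N0": "R1", "N1": "R2", "N2": "R3"}
    )
    stages: tuple[str, ...] = STAGES
    layers_per_stage: Mapping[str, int] = field(default_factory=_default_layers_per_stage)
    replicates: int = 4
    chl_base: float = 45.0
    nitrogen_effect: Mapping[str, float] = field(
        default_factory=lambda: {"N0": -8.0, "N1": 0.0, "N2": 4.0}
    )
    layer_slope_pre: float = -3.0
    layer_slope_post: float = 3.0
    portion_gradient: float = 0.08
    chl_noise_sd: float = 2.0
    w_ji_vegetative: float = -0.4
    w_ji_reproductive: float = 0.3
    coupling: float = 1.0
    re0cs_base: float = 80.0
    re0cs_noise_cv: float = 0.03
    amplitude_jitter_cv: float = 0.15
    shape_jitter_cv: float = 0.12
    noise_cv: float = 0.02
    seed: int = 0
    grid: InstrumentGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        for level, stage in self.reversal_stage.items():
            if stage not in self.stages:
                raise ParameterError(f"reversal stage {stage!r} for {level} not in stages")
        for stage, n in self.layers_per_stage.items():
            if not 1 <= n <= len(LAYERS):
                raise ParameterError(f"{stage}: layer count {n} out of range")


PORTIONS = ("basal", "central", "top")

#: Route gains of the planted chlorophyll dependence: the amplitude route is
#: deliberately weaker than the RE0/CS target route so that FM-proportional
#: fluxes are a diluted proxy of chlorophyll while RE0/CS tracks it directly.
AMPLITUDE_ROUTE_GAIN = 0.8
RE0CS_ROUTE_GAIN = 2.0

#: Solver bounds for the I-P phase weight.
_W_IP_BOUNDS = (0.02, 2.0)


def _portion_factors(gradient: float, upper: bool) -> dict[str, float]:
    g = gradient if upper else -gradient
    return {"basal": 1.0 - g, "central": 1.0, "top": 1.0 + g}


def _re0cs_of(params: OjipShapeParams, grid: InstrumentGrid) -> float:
    """Noise-free RE0/CS = phi_Po^2 * (1-VJ) * (1-VI) * FM of the closed form."""
    t = ojip_ground_truth(params, grid)
    phi_po = 1.0 - t.F0 / t.FM
    return phi_po * (1.0 - t.VJ) * phi_po * (1.0 - t.VI) * t.FM


def _solve_w_ip(base: OjipShapeParams, target: float, grid: InstrumentGrid) -> float:
    """I-P weight at which the noise-free RE0/CS equals ``target``.

    RE0/CS is monotone increasing in the I-P weight (FM = F0 + amplitude is
    weight-independent, while 1-VI and 1-VJ grow with it); targets outside
    the attainable range clamp to the nearer bound.
    """
    lo, hi = _W_IP_BOUNDS
    f_lo = _re0cs_of(replace(base, w_ip=lo), grid) - target
    f_hi = _re0cs_of(replace(base, w_ip=hi), grid) - target
    if f_lo >= 0:
        return lo
    if f_hi <= 0:
        return hi
    return float(
        brentq(lambda w: _re0cs_of(replace(base, w_ip=w), grid) - target, lo, hi, xtol=1e-6)
    )


def generate_canopy_dataset(
    design: CanopyDesign = CanopyDesign(),
) -> tuple[pd.DataFrame, list[Transient], pd.DataFrame]:
    """Generate a full synthetic trial.

    Returns ``(samples, transients, truth)``: a long leaf-sample table (one
    row per nitrogen x stage x layer x replicate x portion with its
    chlorophyll value), one transient per leaf, and a ground-truth table
    keyed by ``sample_id`` recording every generating value (leaf chlorophyll,
    shape parameters, noise-free landmarks, VJ/VI/M0).
    """
    root = np.random.SeedSequence(design.seed)
    samples: list[dict] = []
    transients: list[Transient] = []
    truth_rows: list[dict] = []

    cells = [
        (nitrogen, stage, layer_rank, rep)
        for nitrogen in sorted(design.nitrogen_effect)
        for stage in design.stages
        for layer_rank in range(1, design.layers_per_stage[stage] + 1)
        for rep in range(1, design.replicates + 1)
    ]
    children = root.spawn(len(cells))

    for (nitrogen, stage, layer_rank, rep), child in zip(cells, children):
        rng = np.random.default_rng(child)
        n_layers = design.layers_per_stage[stage]
        layer = LAYERS[layer_rank - 1]
        stage_idx = design.stages.index(stage)
        reversal_idx = design.stages.index(design.reversal_stage[nitrogen])
        slope = design.layer_slope_post if stage_idx >= reversal_idx else design.layer_slope_pre
        centre = (1 + n_layers) / 2.0
        leaf_mean = (
            design.chl_base
            + design.nitrogen_effect[nitrogen]
            + slope * (layer_rank - centre)
        )
        upper = layer_rank > n_layers - (n_layers + 1) // 2
        factors = _portion_factors(design.portion_gradient, upper)
        sample_id = f"{nitrogen}_{stage}_{layer}_r{rep}"
        portion_values = {}
        for portion in PORTIONS:
            chl = leaf_mean * factors[portion] + rng.normal(0.0, design.chl_noise_sd)
            chl = max(chl, 0.1)
            portion_values[portion] = chl
            samples.append(
                {
                    "sample_id": sample_id,
                    "plot": f"{nitrogen}-p{rep}",
                    "nitrogen": nitrogen,
                    "stage": stage,
                    "layer": layer,
                    "portion": portion,
                    "replicate": rep,
                    "chl_ug_cm2": chl,
                }
            )
        leaf_chl = float(np.mean(list(portion_values.values())))
        rel = design.coupling * (leaf_chl - design.chl_base) / design.chl_base

        def jitter(cv: float) -> float:
            return 1.0 + cv * rng.standard_normal()

        w_ji_base = (
            design.w_ji_vegetative if stage in VEGETATIVE_STAGES else design.w_ji_reproductive
        )
        base = OjipShapeParams(
            f0=500.0 * jitter(design.shape_jitter_cv),
            amplitude=2000.0
            * max(1.0 + AMPLITUDE_ROUTE_GAIN * rel, 0.1)
            * jitter(design.amplitude_jitter_cv),
            w_oj=1.0 * jitter(design.shape_jitter_cv),
            w_ji=w_ji_base * jitter(design.shape_jitter_cv),
            w_ip=0.45,
            tau_oj=0.25e-3 * jitter(design.shape_jitter_cv),
            tau_ji=5e-3 * jitter(design.shape_jitter_cv),
            tau_ip=80e-3 * jitter(design.shape_jitter_cv),
            noise_cv=design.noise_cv,
        )
        target = (
            design.re0cs_base
            * max(1.0 + RE0CS_ROUTE_GAIN * rel, 0.05)
            * jitter(design.re0cs_noise_cv)
        )
        params = replace(base, w_ip=_solve_w_ip(base, target, design.grid))
        transient, truth = simulate_ojip(
            params, design.grid, sample_id=sample_id, nitrogen=nitrogen,
            stage=stage, layer=layer, rng=rng,
        )
        transients.append(transient)
        truth_rows.append(
            {
                "sample_id": sample_id,
                "nitrogen": nitrogen,
                "stage": stage,
                "layer": layer,
                "replicate": rep,
                "leaf_chl": leaf_chl,
                "f0": params.f0,
                "amplitude": params.amplitude,
                "w_oj": params.w_oj,
                "w_ji": params.w_ji,
                "w_ip": params.w_ip,
                "tau_oj": params.tau_oj,
                "tau_ji": params.tau_ji,
                "tau_ip": params.tau_ip,
                "true_F0": truth.F0,
                "true_F300": truth.F300,
                "true_FJ": truth.FJ,
                "true_FI": truth.FI,
                "true_FM": truth.FM,
                "true_t_fm": truth.t_fm,
                "true_VJ": truth.VJ,
                "true_VI": truth.VI,
                "true_M0": truth.M0,
            }
        )

    return pd.DataFrame(samples), transients, pd.DataFrame(truth_rows)


def truth_landmarks(truth: OjipGroundTruth, area: float = 0.0) -> Landmarks:
    """Adapter: ground truth as a :class:`Landmarks` (area optional)."""
    return Landmarks(
        F0=truth.F0, F300=truth.F300, FJ=truth.FJ, FI=truth.FI,
        FM=truth.FM, t_fm=truth.t_fm, area=area,
    )
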