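"""Synthetic data with known ground truth for every pipeline stage.

Emulates the four kinds of raw input the analysis consumes:

* placentome series -- three-compartment signal decay on a (b, TE) grid
  with Rician magnitude noise;
* vessel T2-prep series -- mono-exponential decay at the standard
  preparation times;
* cine phase-contrast stacks -- circular vessel cross-sections with plug
  or parabolic through-plane velocity profiles and a pulsatile waveform;
* a cohort of ewes scanned in three physiological states (basal, then
  two windows after a vasodilator bolus, TAD1/TAD2) with animal-level
  random effects and injectable state effects.

Default cohort magnitudes follow the measured physiology of anaesthetised
late-gestation ewes (maternal Hb ~80 g/L, fetal ~95 g/L, LVCO ~7 L/min,
total uterine artery flow ~1.2 L/min, umbilical vein flow ~650 mL/min);
the injected effects reproduce the study's qualitative pattern: maternal
placental blood volume fraction raised in the second post-drug window,
uterine flow as a share of cardiac output lowered in both windows, and
all fetal oxygen endpoints null.  Ground truth accompanies every
artefact so downstream recovery is always checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_GRID,
    AcquisitionGrid,
    FixedCompartmentConstants,
    PlacentomeModelParams,
    PlacentomeSeries,
    forward_signal,
)
from .oximetry import (
    CALIBRATION_PRESETS,
    DEFAULT_PREP_TIMES,
    OximetryCalibration,
    T2PrepSeries,
)
from .flow import PCCineSeries

__all__ = [
    "NoiseSpec",
    "CohortDesign",
    "CohortDataset",
    "SimulatedCine",
    "simulate_placentome",
    "simulate_t2prep",
    "simulate_pc_cine",
    "simulate_cohort",
    "block_phantom",
]

STATES = ("basal", "TAD1", "TAD2")


@dataclass(frozen=True)
class NoiseSpec:
    """Magnitude-image noise: model in {rician, gaussian, none}, snr = S0/sigma."""

    model: str = "rician"
    snr: float = 50.0

    def __post_init__(self) -> None:
        if self.model not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.model != "none" and not self.snr > 0:
            raise ValueError("snr must be positive")

    def apply(self, clean, s0_ref: float, rng: np.random.Generator):
        """Corrupt a clean magnitude signal; sigma = s0_ref / snr."""
        clean = np.asarray(clean, dtype=float)
        if self.model == "none":
            return clean.copy()
        sigma = s0_ref / self.snr
        if self.model == "gaussian":
            return clean + rng.normal(0.0, sigma, clean.shape)
        re = clean + rng.normal(0.0, sigma, clean.shape)
        im = rng.normal(0.0, sigma, clean.shape)
        return np.hypot(re, im)


def block_phantom(shape, blocks):
    """Build per-parameter 3D truth maps from (slice, params) blocks.

    ``blocks`` is a list of ``(index_expression, PlacentomeModelParams)``;
    later blocks overwrite earlier ones.  Returns (maps dict, mask).
    """
    names = ("f", "d", "d_star", "t2fb", "v", "s0")
    maps = {n: np.full(shape, np.nan) for n in names}
    mask = np.zeros(shape, dtype=bool)
    for sl, params in blocks:
        for n in names:
            maps[n][sl] = getattr(params, n)
        mask[sl] = True
    return maps, mask


def simulate_placentome(
    params_map,
    mask,
    grid: AcquisitionGrid = DEFAULT_GRID,
    noise: NoiseSpec = NoiseSpec(model="none"),
    constants: FixedCompartmentConstants | None = None,
    rng: np.random.Generator | None = None,
):
    """Forward-simulate a 4D placentome series from per-voxel truth maps.

    ``params_map`` maps parameter name -> 3D array (f, d, d_star, t2fb,
    v, s0); out-of-mask voxels are zero-filled.  Returns
    ``(PlacentomeSeries, params_map)`` -- the truth travels with the data.
    """
    rng = rng or np.random.default_rng()
    constants = constants or FixedCompartmentConstants()
    mask = np.asarray(mask).astype(bool)
    import warnings as _warnings

    if not grid.identifiable:
        _warnings.warn("acquisition grid is non-identifiable for a 6-parameter fit")
    shape = mask.shape
    b, te = grid.b, grid.te
    signal = np.zeros(shape + (len(grid),))
    s0_ref = 0.0
    for idx in np.argwhere(mask):
        i, j, k = idx
        p = PlacentomeModelParams(
            **{n: float(params_map[n][i, j, k])
               for n in ("f", "d", "d_star", "t2fb", "v", "s0")}
        )
        signal[i, j, k] = forward_signal(p, constants, b, te)
        s0_ref = max(s0_ref, p.s0)
    noisy = noise.apply(signal, s0_ref or 1.0, rng)
    np.clip(noisy, 0.0, None, out=noisy)
    return PlacentomeSeries(signal=noisy, mask=mask, grid=grid), params_map


def simulate_t2prep(
    t2_ms: float,
    s0: float = 100.0,
    prep_times=DEFAULT_PREP_TIMES,
    noise: NoiseSpec = NoiseSpec(model="none"),
    vessel_label: str = "UV",
    rng: np.random.Generator | None = None,
) -> T2PrepSeries:
    """Mono-exponential T2-prep decay series with optional noise."""
    rng = rng or np.random.default_rng()
    tau = np.asarray(prep_times, dtype=float)
    clean = s0 * np.exp(-tau / t2_ms)
    noisy = noise.apply(clean, s0, rng)
    noisy = np.clip(noisy, 1e-9 * s0, None)  # series signals must stay positive
    return T2PrepSeries(
        prep_times=tuple(tau), signals=tuple(noisy), vessel_label=vessel_label
    )


@dataclass
class SimulatedCine:
    """A simulated cine PC acquisition plus its analytic ground truth.

    ``phase`` may exceed [-pi, pi] when aliasing was requested; in that
    case ``to_series`` raises, mirroring the contract that wrapped or
    aliased input must be rejected rather than quietly integrated.
    """

    phase: np.ndarray
    magnitude: np.ndarray
    venc: float
    pixel_area_cm2: float
    roi: np.ndarray
    true_mean_flow: float
    aliased: bool

    def to_series(self) -> PCCineSeries:
        return PCCineSeries(
            phase_images=self.phase,
            magnitude_images=self.magnitude,
            venc=self.venc,
            pixel_area=self.pixel_area_cm2,
        )


def simulate_pc_cine(
    profile: str = "parabolic",
    vmax: float = 40.0,
    radius_mm: float = 5.0,
    venc: float = 150.0,
    pixel_size_mm: float = 0.5,
    n_phases: int = 15,
    modulation: float = 0.0,
    noise_phase_sd: float = 0.0,
    allow_aliasing: bool = False,
    rng: np.random.Generator | None = None,
) -> SimulatedCine:
    """Simulate a circular vessel's cine PC stack.

    The through-plane velocity is ``vmax`` (plug) or
    ``vmax (1 - r^2/R^2)`` (parabolic), scaled per cardiac phase by the
    waveform ``1 + modulation * sin(2 pi k / n_phases)`` whose discrete
    mean is exactly 1, so the analytic mean flow is vmax*pi*R^2 (plug)
    or vmax/2*pi*R^2 (parabolic).

    Raises unless ``allow_aliasing`` when the peak velocity exceeds VENC;
    with ``allow_aliasing`` the raw (unwrapped) phase is returned and the
    downstream contract rejects it.
    """
    rng = rng or np.random.default_rng()
    if profile not in ("plug", "parabolic"):
        raise ValueError(f"unknown profile {profile!r}")
    peak = abs(vmax) * (1.0 + abs(modulation))
    if peak >= venc and not allow_aliasing:
        raise ValueError(
            f"peak velocity {peak} cm/s >= VENC {venc} cm/s; pass "
            "allow_aliasing=True for a deliberate aliasing phantom"
        )

    r_cm = radius_mm / 10.0
    h_cm = pixel_size_mm / 10.0
    n_pix = int(math.ceil(2 * r_cm / h_cm)) + 4
    centre = (n_pix - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(n_pix), np.arange(n_pix), indexing="ij")
    rr = np.hypot(ii - centre, jj - centre) * h_cm
    roi = rr <= r_cm
    if profile == "plug":
        v0 = np.where(roi, vmax, 0.0)
        q_true = vmax * math.pi * r_cm**2  # cm^3/s
    else:
        v0 = np.where(roi, vmax * (1.0 - (rr / r_cm) ** 2), 0.0)
        q_true = 0.5 * vmax * math.pi * r_cm**2

    k = np.arange(n_phases)
    waveform = 1.0 + modulation * np.sin(2 * math.pi * k / n_phases)
    velocity = waveform[:, None, None] * v0[None]
    phase = math.pi * velocity / venc
    if noise_phase_sd > 0:
        phase = phase + rng.normal(0.0, noise_phase_sd, phase.shape)
        phase = np.clip(phase, -math.pi, math.pi)
    magnitude = np.where(roi, 1.0, 0.2)[None] * np.ones((n_phases, 1, 1))
    return SimulatedCine(
        phase=phase,
        magnitude=magnitude,
        venc=venc,
        pixel_area_cm2=h_cm**2,
        roi=roi,
        true_mean_flow=q_true * 60.0,  # mL/min
        aliased=bool(np.abs(phase).max() > math.pi + 1e-12),
    )


def _default_means():
    # basal-state cohort means; flows mL/min, Hb g/L, T2 ms, MAP mmHg
    return {
        "lvco": 7000.0,
        "uta_flow": 1200.0,
        "uv_flow": 650.0,
        "v": 0.25,
        "f": 0.25,
        "d": 1.5e-3,
        "d_star": 0.03,
        "t2fb": 60.0,
        "y_uv": 0.80,
        "y_dao": 0.55,
        "y_uta": 0.95,
        "y_utv": 0.75,
        "hb_maternal": 80.0,
        "hb_fetal": 95.0,
        "map_maternal": 90.0,
        "hr_maternal": 100.0,
        "maternal_weight": 65.0,
    }


def _default_between_sd():
    # animal-level spread: lognormal sigma for flows, additive SD otherwise
    return {
        "lvco": 0.12,
        "uta_flow": 0.15,
        "uv_flow": 0.12,
        "v": 0.04,
        "f": 0.04,
        "d": 1.5e-4,
        "d_star": 3e-3,
        "t2fb": 5.0,
        "y_uv": 0.03,
        "y_dao": 0.03,
        "y_uta": 0.015,
        "y_utv": 0.03,
        "hb_maternal": 8.0,
        "hb_fetal": 6.0,
        "map_maternal": 8.0,
        "hr_maternal": 10.0,
        "maternal_weight": 6.0,
    }


def _default_within_sd():
    # state-to-state physiological jitter within an animal
    return {
        "lvco": 0.05,
        "uta_flow": 0.05,
        "uv_flow": 0.05,
        "v": 0.012,
        "f": 0.012,
        "d": 5e-5,
        "d_star": 1e-3,
        "t2fb": 2.0,
        "y_uv": 0.012,
        "y_dao": 0.012,
        "y_uta": 0.008,
        "y_utv": 0.012,
        "hb_maternal": 3.0,
        "hb_fetal": 2.5,
        "map_maternal": 4.0,
        "hr_maternal": 5.0,
        "maternal_weight": 0.0,
    }


LOGNORMAL_VARS = ("lvco", "uta_flow", "uv_flow")

# state-specific plasma drug concentration (mean, sd), ng/mL
TADALAFIL = {
    "maternal": {"basal": (0.0, 0.0), "TAD1": (1270.0, 740.0), "TAD2": (318.0, 108.0)},
    "fetal": {"basal": (0.0, 0.0), "TAD1": (74.0, 16.0), "TAD2": (62.0, 21.0)},
}


@dataclass
class CohortDesign:
    """Ground-truth design of a simulated three-state cohort.

    Effects (each switchable) reproduce the study's qualitative pattern:

    * ``v_increase_tad2``: maternal placental blood volume fraction
      raised by ``v_effect`` in the TAD2 window only;
    * ``uta_fraction_decrease``: uterine artery flow multiplied by
      ``uta_flow_factor`` in both TAD windows at unchanged cardiac
      output, lowering its share of LVCO;
    * ``map_decrease``: maternal arterial pressure lowered by
      ``map_effect`` mmHg in both TAD windows;
    * fetal endpoints (f, d, d_star, T2fb, UV flow, fetal SO2s, Hb) carry
      no state effect (``null_fetal_effects`` is informational and always
      honoured -- no fetal effect is ever injected).
    """

    n_animals: int = 7
    states: tuple = STATES
    means: dict = field(default_factory=_default_means)
    between_sd: dict = field(default_factory=_default_between_sd)
    within_sd: dict = field(default_factory=_default_within_sd)
    v_increase_tad2: bool = True
    v_effect: float = 0.08
    uta_fraction_decrease: bool = True
    uta_flow_factor: float = 0.78
    map_decrease: bool = True
    map_effect: float = 12.0
    null_fetal_effects: bool = True
    calibration: str | OximetryCalibration = "sheep_default"
    snr_placentome: float = 50.0
    snr_t2prep: float = 100.0
    phase_noise_sd: float = 0.01
    placentome_shape: tuple = (4, 4, 2)
    n_phases: int = 15
    pixel_size_mm: float = 0.5
    grid: AcquisitionGrid = DEFAULT_GRID
    prep_times: tuple = DEFAULT_PREP_TIMES

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("need at least 2 animals")
        if any(sd < 0 for sd in self.between_sd.values()):
            raise ValueError("between-animal SDs must be >= 0")
        if any(sd < 0 for sd in self.within_sd.values()):
            raise ValueError("within-animal SDs must be >= 0")
        # ground-truth placentome parameters must respect the model boxes
        PlacentomeModelParams(
            f=self.means["f"], d=self.means["d"], d_star=self.means["d_star"],
            t2fb=self.means["t2fb"], v=self.means["v"], s0=1.0,
        )

    def get_calibration(self) -> OximetryCalibration:
        if isinstance(self.calibration, OximetryCalibration):
            return self.calibration
        return CALIBRATION_PRESETS[self.calibration]

    def state_mean(self, var: str, state: str) -> float:
        """Ground-truth cohort mean of a variable in a given state."""
        base = self.means[var]
        if state == "basal":
            return base
        if var == "v" and self.v_increase_tad2 and state == "TAD2":
            return base + self.v_effect
        if var == "uta_flow" and self.uta_fraction_decrease:
            return base * self.uta_flow_factor
        if var == "map_maternal" and self.map_decrease:
            return base - self.map_effect
        return base


# clamping boxes for perturbed truth values
_CLAMPS = {
    "v": (0.01, 0.9), "f": (0.01, 0.9), "d": (1e-5, 0.99),
    "d_star": (1e-4, 0.99), "t2fb": (5.0, 145.0),
    "y_uv": (0.01, 0.999), "y_dao": (0.01, 0.999),
    "y_uta": (0.01, 0.999), "y_utv": (0.01, 0.999),
}

# vessel geometry for the cine simulator: radius mm, venc cm/s, waveform
_VESSELS = {
    "AAo": {"radius_mm": 10.0, "venc": 150.0, "modulation": 0.35},
    "UtA_left": {"radius_mm": 3.5, "venc": 150.0, "modulation": 0.35},
    "UtA_right": {"radius_mm": 3.5, "venc": 150.0, "modulation": 0.35},
    "UV": {"radius_mm": 4.5, "venc": 100.0, "modulation": 0.05},
}


@dataclass
class CohortDataset:
    """Everything a simulated cohort produced, truth included.

    ``truth`` is a tidy DataFrame with one row per animal x state;
    ``placentome``, ``t2prep`` and ``cine`` are keyed by
    (animal_id, state[, vessel]).
    """

    design: CohortDesign
    truth: pd.DataFrame
    placentome: dict
    t2prep: dict
    cine: dict


def _truth_value(rng, design, var, state, animal_offset):
    mean = design.state_mean(var, state)
    w = design.within_sd.get(var, 0.0)
    if var in LOGNORMAL_VARS:
        val = mean * animal_offset[var] * math.exp(rng.normal(0.0, w))
    else:
        val = mean + animal_offset[var] + rng.normal(0.0, w)
    if var in _CLAMPS:
        val = min(max(val, _CLAMPS[var][0]), _CLAMPS[var][1])
    return val


def simulate_cohort(design: CohortDesign, seed: int | None = None) -> CohortDataset:
    """Generate a full synthetic cohort: images, series and truth table.

    Animal-level variability enters as lognormal multipliers on flows and
    additive normal shifts elsewhere; state effects are applied to the
    cohort means per the design switches; within-animal jitter is drawn
    per state.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    calib = design.get_calibration()
    rows = []
    placentome, t2prep, cine = {}, {}, {}
    variables = list(design.means)

    for a in range(design.n_animals):
        animal = f"ewe{a + 1:02d}"
        offset = {}
        for var in variables:
            sd = design.between_sd.get(var, 0.0)
            if var in LOGNORMAL_VARS:
                offset[var] = math.exp(rng.normal(0.0, sd))
            else:
                offset[var] = rng.normal(0.0, sd)
        for state in design.states:
            tv = {
                var: _truth_value(rng, design, var, state, offset)
                for var in variables
            }
            # keep the tissue fraction positive after perturbation
            tv["v"] = min(tv["v"], 0.95 - tv["f"])
            for circ in ("maternal", "fetal"):
                m, sd = TADALAFIL[circ][state]
                tv[f"tadalafil_{circ}"] = (
                    max(rng.normal(m, sd), 0.0) if m > 0 else 0.0
                )
            row = {"animal_id": animal, "state": state, **tv}

            # placentome block (homogeneous truth across the small ROI)
            shape = design.placentome_shape
            params = PlacentomeModelParams(
                f=tv["f"], d=tv["d"], d_star=tv["d_star"],
                t2fb=tv["t2fb"], v=tv["v"], s0=100.0,
            )
            maps, mask = block_phantom(shape, [(np.s_[:, :, :], params)])
            series, _ = simulate_placentome(
                maps, mask, design.grid,
                NoiseSpec("rician", design.snr_placentome), rng=rng,
            )
            placentome[(animal, state)] = (series, maps)

            # vessel T2-prep series from the true saturations
            for vessel, y_key in (
                ("UV", "y_uv"), ("DAo", "y_dao"), ("UtA", "y_uta"),
                ("UtV_left", "y_utv"), ("UtV_right", "y_utv"),
            ):
                t2_true = calib.t2_from_so2(tv[y_key])
                t2prep[(animal, state, vessel)] = simulate_t2prep(
                    t2_true, 100.0, design.prep_times,
                    NoiseSpec("rician", design.snr_t2prep),
                    vessel_label=vessel, rng=rng,
                )
                row[f"t2_{vessel}"] = t2_true

            # cine PC stacks sized so the analytic flow equals the truth
            flows = {
                "AAo": tv["lvco"],
                "UtA_left": 0.5 * tv["uta_flow"],
                "UtA_right": 0.5 * tv["uta_flow"],
                "UV": tv["uv_flow"],
            }
            for vessel, geom in _VESSELS.items():
                r_cm = geom["radius_mm"] / 10.0
                vmax = 2.0 * (flows[vessel] / 60.0) / (math.pi * r_cm**2)
                # vessel-appropriate VENC: the nominal per-vessel value,
                # raised when an extreme animal's peak velocity would
                # alias (emulating the operator's re-prescription)
                peak = vmax * (1.0 + geom["modulation"])
                venc = max(geom["venc"], 1.25 * peak)
                cine[(animal, state, vessel)] = simulate_pc_cine(
                    profile="parabolic", vmax=vmax,
                    radius_mm=geom["radius_mm"], venc=venc,
                    pixel_size_mm=design.pixel_size_mm,
                    n_phases=design.n_phases,
                    modulation=geom["modulation"],
                    noise_phase_sd=design.phase_noise_sd, rng=rng,
                )
            rows.append(row)

    truth = pd.DataFrame(rows)
    return CohortDataset(
        design=design, truth=truth,
        placentome=placentome, t2prep=t2prep, cine=cine,
    )
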