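"""Phase-contrast cine flow quantification.

Phase-contrast MRI encodes through-plane velocity in the image phase:
phase +/- pi maps linearly to velocity +/- VENC.  Summing velocity x pixel
area over a vessel ROI gives the instantaneous flow per cardiac phase;
the mean over the cardiac cycle is the reported vessel flow.  Composite
measures follow the study design: maternal left ventricular cardiac
output (LVCO) equals ascending-aorta flow, total uterine-artery flow is
the sum of the left and right uterine arteries, and flows are normalised
to maternal weight (mL/min/kg) or to LVCO (%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PCCineSeries",
    "FlowResult",
    "phase_to_velocity",
    "roi_flow",
    "total_uta_flow",
    "normalize_flow",
]

VESSEL_LABELS = ("AAo", "UtA_left", "UtA_right", "UV")


@dataclass
class PCCineSeries:
    """One vessel's cine PC acquisition.

    ``phase_images``/``magnitude_images`` are (n_phases, ny, nx) stacks;
    phase is in radians within [-pi, pi].  ``venc`` is the velocity
    encoding limit in cm/s, ``pixel_area`` the in-plane pixel area in
    cm^2, ``rr_interval`` the optional R-R interval metadata in ms.
    """

    phase_images: np.ndarray
    magnitude_images: np.ndarray
    venc: float
    pixel_area: float
    rr_interval: float | None = None

    def __post_init__(self) -> None:
        self.phase_images = np.atleast_3d(np.asarray(self.phase_images, dtype=float))
        self.magnitude_images = np.atleast_3d(
            np.asarray(self.magnitude_images, dtype=float)
        )
        if self.phase_images.shape != self.magnitude_images.shape:
            raise ValueError("phase and magnitude stacks must be congruent")
        if self.phase_images.ndim != 3 or self.phase_images.shape[0] < 1:
            raise ValueError("need a (n_phases, ny, nx) stack with n_phases >= 1")
        if not self.venc > 0:
            raise ValueError("VENC must be positive")
        if not self.pixel_area > 0:
            raise ValueError("pixel_area must be positive")
        if np.any(np.abs(self.phase_images) > np.pi + 1e-12):
            raise ValueError("phase values outside [-pi, pi]: aliased input")

    @property
    def n_phases(self) -> int:
        return self.phase_images.shape[0]


@dataclass
class FlowResult:
    """Vessel flow: per-cardiac-phase values and their mean, mL/min."""

    mean_flow: float
    per_phase_flow: tuple
    vessel_label: str

    def __post_init__(self) -> None:
        if self.vessel_label not in VESSEL_LABELS:
            raise ValueError(
                f"vessel_label {self.vessel_label!r} not in {VESSEL_LABELS}"
            )


def phase_to_velocity(phase, venc: float):
    """Map PC phase (radians) to velocity (cm/s): v = VENC * phase / pi."""
    phase = np.asarray(phase, dtype=float)
    if not venc > 0:
        raise ValueError("VENC must be positive")
    if np.any(np.abs(phase) > np.pi + 1e-12):
        raise ValueError("phase outside [-pi, pi]: aliased/unwrapped input required")
    out = venc * phase / np.pi
    return float(out) if out.ndim == 0 else out


def roi_flow(series: PCCineSeries, roi, vessel_label: str = "AAo") -> FlowResult:
    """Flow through an ROI from a cine PC series.

    Per-phase flow is sum over ROI of velocity (cm/s) x pixel area (cm^2),
    converted to mL/min; the reported mean is the unweighted average over
    cardiac phases (uniform phase sampling assumed).
    """
    roi = np.asarray(roi).astype(bool)
    if roi.shape != series.phase_images.shape[1:]:
        raise ValueError(
            f"ROI shape {roi.shape} does not match image shape "
            f"{series.phase_images.shape[1:]}"
        )
    if not roi.any():
        raise ValueError("empty ROI")
    velocity = phase_to_velocity(series.phase_images, series.venc)  # cm/s
    per_phase = velocity[:, roi].sum(axis=1) * series.pixel_area * 60.0  # mL/min
    return FlowResult(
        mean_flow=float(per_phase.mean()),
        per_phase_flow=tuple(float(q) for q in per_phase),
        vessel_label=vessel_label,
    )


def total_uta_flow(left: FlowResult, right: FlowResult) -> float:
    """Total uterine artery flow: left + right mean flows, mL/min."""
    if left.vessel_label != "UtA_left" or right.vessel_label != "UtA_right":
        raise ValueError(
            f"expected (UtA_left, UtA_right), got "
            f"({left.vessel_label!r}, {right.vessel_label!r})"
        )
    return left.mean_flow + right.mean_flow


def normalize_flow(flow: float, *, weight_kg: float | None = None,
                   lvco: float | None = None) -> float:
    """Index a flow to maternal weight or normalise it to LVCO.

    Exactly one denominator must be given: ``weight_kg`` returns
    mL/min/kg; ``lvco`` returns the flow as a percentage of LVCO.
    """
    if (weight_kg is None) == (lvco is None):
        raise ValueError("give exactly one of weight_kg or lvco")
    denom = weight_kg if weight_kg is not None else lvco
    if not denom > 0:
        raise ValueError("denominator must be positive")
    if weight_kg is not None:
        return flow / weight_kg
    return 100.0 * flow / lvco
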