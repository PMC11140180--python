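"""Vessel T2-prep oximetry: T2 estimation and the T2 - SO2 calibration.

Blood T2 depends on oxygen saturation through the paramagnetism of
deoxyhaemoglobin.  A T2-prepared acquisition samples the mono-exponential
decay S(tau) = S0 exp(-tau/T2) at a handful of preparation times; the
fitted T2 is converted to saturation with a quadratic Luz-Meiboom type
relationship R2 = A + B (1 - Y)^2 calibrated for the species and
haematocrit of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .model import t2_to_so2

__all__ = [
    "DEFAULT_PREP_TIMES",
    "OximetryCalibration",
    "CALIBRATION_PRESETS",
    "T2PrepSeries",
    "T2DecayModel",
    "T2FitResult",
    "central_fraction_roi",
    "fit_t2_decay",
    "so2_from_t2",
    "so2_to_t2",
]

#: Default T2 preparation times, ms.
DEFAULT_PREP_TIMES = (32.0, 64.0, 96.0, 128.0, 160.0, 192.0)

VESSEL_LABELS = ("UV", "DAo", "UtV_left", "UtV_right", "UtA")


@dataclass(frozen=True)
class OximetryCalibration:
    """Quadratic T2 - SO2 calibration: R2 = A + B (1 - Y)^2, rates in 1/s.

    ``a`` is the relaxation rate of fully saturated blood and ``b`` the
    desaturation coefficient; both depend on species, haematocrit and
    field strength, so the constants are required configuration with a
    named sheep preset shipped as a documented default.
    """

    a: float
    b: float
    species: str = ""
    hct: float | None = None

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"calibration A={self.a!r} must be > 0")
        if not self.b > 0:
            raise ValueError(f"calibration B={self.b!r} must be > 0")

    def t2_from_so2(self, y: float) -> float:
        """Forward map: saturation fraction -> blood T2 in ms."""
        if not 0.0 <= y <= 1.0:
            raise ValueError("SO2 must lie in [0, 1]")
        r2 = self.a + self.b * (1.0 - y) ** 2
        return 1000.0 / r2


#: Named presets.  "sheep_default" is a synthetic representative
#: calibration for sheep blood at 3 T (see docs/methods.md); real
#: analyses must supply bench-calibrated constants.
CALIBRATION_PRESETS = {
    "sheep_default": OximetryCalibration(a=10.0, b=70.0, species="sheep", hct=0.30),
}


@dataclass
class T2PrepSeries:
    """Mean ROI signal of one vessel at each T2 preparation time."""

    prep_times: tuple
    signals: tuple
    vessel_label: str = "UV"

    def __post_init__(self) -> None:
        pt = tuple(float(t) for t in self.prep_times)
        sig = tuple(float(s) for s in self.signals)
        if len(pt) != len(sig):
            raise ValueError("prep_times and signals lengths differ")
        if len(pt) < 2:
            raise ValueError("need at least 2 preparation times")
        if any(t2 <= t1 for t1, t2 in zip(pt, pt[1:])):
            raise ValueError("prep_times must be strictly increasing")
        if any(s <= 0 for s in sig):
            raise ValueError("signals must be positive")
        if self.vessel_label not in VESSEL_LABELS:
            raise ValueError(
                f"vessel_label {self.vessel_label!r} not in {VESSEL_LABELS}"
            )
        object.__setattr__(self, "prep_times", pt)
        object.__setattr__(self, "signals", sig)


@dataclass
class T2FitResult:
    t2_ms: float
    s0: float
    residual_norm: float
    converged: bool
    degenerate: bool = False
    message: str = ""


class T2DecayModel(RegressorMixin, BaseEstimator):
    """Mono-exponential decay fit S(tau) = S0 exp(-tau / T2).

    scikit-learn style estimator: ``X`` is the ``(n, 1)`` column of
    preparation times (ms), ``y`` the positive ROI signals.  A log-linear
    regression provides the initial point for the nonlinear refinement.
    An optional constant offset term (noise floor) is available behind
    ``with_offset``; the default matches a 2-parameter fit.

    Attributes
    ----------
    t2_ms_ : float
    s0_ : float
    offset_ : float
    residual_norm_ : float
    converged_ : bool
    degenerate_ : bool
        True when the series carries no usable decay (flat or rising).
    """

    def __init__(self, with_offset=False, ftol=1e-12, max_iter=200):
        self.with_offset = with_offset
        self.ftol = ftol
        self.max_iter = max_iter

    def fit(self, X, y):
        tau = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if tau.shape != y.shape or tau.size < 2:
            raise ValueError("need >=2 (prep_time, signal) pairs")
        if np.any(y <= 0):
            raise ValueError("signals must be positive")
        if len(np.unique(tau)) < 2:
            raise ValueError("need >=2 distinct prep times")

        # log-linear initialiser: ln S = ln S0 - tau / T2
        slope, intercept = np.polyfit(tau, np.log(y), 1)
        degenerate = slope >= -1e-12
        if degenerate:
            # no decay information: report the flat-curve limit, flagged
            self.t2_ms_ = math.inf
            self.s0_ = float(np.mean(y))
            self.offset_ = 0.0
            self.residual_norm_ = float(np.linalg.norm(y - self.s0_))
            self.converged_ = False
            self.degenerate_ = True
            self.message_ = "non-decaying series"
            return self

        t2_0 = -1.0 / slope
        s0_0 = math.exp(intercept)

        if self.with_offset:
            x0 = np.array([s0_0, t2_0, 0.0])

            def resid(p):
                return p[0] * np.exp(-tau / p[1]) + p[2] - y

            lo = [1e-30, 1e-6, 0.0]
            hi = [np.inf, np.inf, np.inf]
        else:
            x0 = np.array([s0_0, t2_0])

            def resid(p):
                return p[0] * np.exp(-tau / p[1]) - y

            lo = [1e-30, 1e-6]
            hi = [np.inf, np.inf]

        sol = least_squares(
            resid, x0, bounds=(lo, hi), method="trf",
            ftol=self.ftol, xtol=1e-14, gtol=1e-14,
            max_nfev=self.max_iter,
        )
        self.s0_ = float(sol.x[0])
        self.t2_ms_ = float(sol.x[1])
        self.offset_ = float(sol.x[2]) if self.with_offset else 0.0
        self.residual_norm_ = float(np.linalg.norm(resid(sol.x)))
        self.converged_ = bool(sol.success and self.t2_ms_ > 0)
        self.degenerate_ = False
        self.message_ = str(sol.message)
        return self

    def predict(self, X):
        tau = np.asarray(X, dtype=float).ravel()
        return self.s0_ * np.exp(-tau / self.t2_ms_) + self.offset_


def fit_t2_decay(series: T2PrepSeries, **kwargs) -> T2FitResult:
    """Fit the vessel T2 from a T2-prep series (thin estimator wrapper)."""
    est = T2DecayModel(**kwargs)
    est.fit(np.asarray(series.prep_times)[:, None], series.signals)
    return T2FitResult(
        t2_ms=est.t2_ms_,
        s0=est.s0_,
        residual_norm=est.residual_norm_,
        converged=est.converged_,
        degenerate=est.degenerate_,
        message=est.message_,
    )


def central_fraction_roi(full_vessel_mask, fraction: float = 0.6) -> np.ndarray:
    """Select the central fraction of a vessel cross-section mask.

    Operationalises the "central 60% of the vessel" ROI rule
    deterministically: pixels are ranked by descending Euclidean
    distance-to-boundary, ties broken by ascending distance to the mask
    centroid, then row-major order, and the top ceil(fraction * N) pixels
    are kept.

    Parameters
    ----------
    full_vessel_mask : 2D bool array
    fraction : float in (0, 1]

    Returns
    -------
    2D bool array, subset of the input with exactly ceil(fraction * N)
    True pixels.
    """
    mask = np.asarray(full_vessel_mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("vessel mask must be 2D")
    if not mask.any():
        raise ValueError("empty vessel mask")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")

    n_keep = math.ceil(fraction * mask.sum())
    if n_keep == mask.sum():
        return mask.copy()

    # distance to boundary: background just outside the array counts
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    rows, cols = np.nonzero(mask)
    centroid = rows.mean(), cols.mean()
    d_centroid = np.hypot(rows - centroid[0], cols - centroid[1])
    order = np.lexsort((cols, rows, d_centroid, -dist[rows, cols]))
    keep = order[:n_keep]
    out = np.zeros_like(mask)
    out[rows[keep], cols[keep]] = True
    return out


def so2_from_t2(t2_ms, calibration, clamp=True, saturate=False):
    """Blood oxygen saturation from T2 (shared quadratic inversion).

    See :func:`placentamri.model.t2_to_so2`; re-exported here as the
    oximetry-facing name.
    """
    return t2_to_so2(t2_ms, calibration, clamp=clamp, saturate=saturate)


def so2_to_t2(y, calibration) -> float:
    """Forward calibration map: saturation fraction -> T2 in ms."""
    return calibration.t2_from_so2(y)
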