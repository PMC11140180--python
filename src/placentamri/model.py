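"""Three-compartment diffusion-relaxation (DECIDE) placentome signal model.

The signal measured at diffusion weighting ``b`` (s/mm^2) and echo time
``TE`` (ms) is modelled as the sum of three compartments -- feto-placental
blood, maternal blood and trophoblast tissue::

    S(b, TE) = S0 * [ f * exp(-b*d_star) * exp(-TE/T2fb)
                      + v * exp(-TE/T2mb)
                      + (1 - f - v) * exp(-b*d) * exp(-TE/T2ts) ]

with five free tissue parameters (f, d, d_star, T2fb, v) plus the
unattenuated amplitude S0, and two fixed literature-based relaxation times
for highly saturated maternal blood (T2mb) and tissue (T2ts) at 3 T.
Maternal blood carries no diffusion attenuation: incoherent flow through
the large maternal sinuses dephases completely at the b-values used, so its
pseudo-diffusion term is taken as fully attenuated into the f and v
partition rather than modelled explicitly.

The inversion is a box-constrained nonlinear least-squares fit
(trust-region reflective by default, optionally Levenberg-Marquardt on
logit/log-transformed parameters) exposed as a scikit-learn style
estimator, :class:`DecideSignalModel`, whose design matrix ``X`` is the
``(n_points, 2)`` array of (b, TE) sample coordinates and whose target
``y`` is the measured signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PlacentomeModelParams",
    "FixedCompartmentConstants",
    "AcquisitionGrid",
    "PlacentomeSeries",
    "ParameterMaps",
    "DecideSignalModel",
    "forward_signal",
    "fit_roi_average",
    "fit_voxelwise",
    "t2_to_so2",
    "DEFAULT_GRID",
]

PARAM_NAMES = ("f", "d", "d_star", "t2fb", "v", "s0")

#: Box constraints used to stabilise the fit: 0 < f < 1, 0 < d < 1 mm^2/s,
#: 0 < d* < 1 mm^2/s, 0 < T2fb < 150 ms, 0 < v < 1.  S0 is bounded below by
#: zero only; its upper bound is set per-fit from the data scale.
PARAM_BOUNDS = {
    "f": (0.0, 1.0),
    "d": (0.0, 1.0),
    "d_star": (0.0, 1.0),
    "t2fb": (0.0, 150.0),
    "v": (0.0, 1.0),
}


class ModelDomainError(ValueError):
    """A model parameter violates its physical domain."""


@dataclass(frozen=True)
class PlacentomeModelParams:
    """Free parameters of the placentome signal model for one voxel or ROI.

    Parameters
    ----------
    f : float
        Feto-placental blood volume fraction (dimensionless, in (0, 1)).
    d : float
        Trophoblast/tissue apparent diffusivity (mm^2/s, in (0, 1)).
    d_star : float
        Pseudo-diffusivity of feto-placental blood (mm^2/s, in (0, 1)).
    t2fb : float
        Feto-placental blood transverse relaxation time (ms, in (0, 150)).
    v : float
        Maternal blood volume fraction (dimensionless, in (0, 1)).
    s0 : float
        Unattenuated signal amplitude (arbitrary units, > 0).
    """

    f: float
    d: float
    d_star: float
    t2fb: float
    v: float
    s0: float = 1.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in PARAM_BOUNDS.items():
            val = getattr(self, name)
            if not (lo < val < hi):
                raise ModelDomainError(
                    f"parameter {name}={val!r} outside open box ({lo}, {hi})"
                )
        if not self.s0 > 0:
            raise ModelDomainError(f"parameter s0={self.s0!r} must be positive")
        if not self.f + self.v < 1.0:
            raise ModelDomainError(
                f"f + v = {self.f + self.v!r} must be < 1 (tissue fraction "
                "1-f-v must be positive)"
            )

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "PlacentomeModelParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, vec))))


@dataclass(frozen=True)
class FixedCompartmentConstants:
    """Fixed relaxation times of the non-fitted compartments at 3 T.

    ``t2mb`` is the transverse relaxation time of highly saturated maternal
    blood and ``t2ts`` that of placental tissue, both in ms.  Defaults are
    the literature-based values 150 ms and 42 ms.
    """

    t2mb: float = 150.0
    t2ts: float = 42.0

    def __post_init__(self) -> None:
        if not self.t2mb > 0:
            raise ModelDomainError(f"t2mb={self.t2mb!r} must be positive")
        if not self.t2ts > 0:
            raise ModelDomainError(f"t2ts={self.t2ts!r} must be positive")

    @property
    def r2mb(self) -> float:
        """Maternal blood relaxation rate, 1/ms."""
        return 1.0 / self.t2mb

    @property
    def r2ts(self) -> float:
        """Tissue relaxation rate, 1/ms."""
        return 1.0 / self.t2ts


@dataclass(frozen=True)
class AcquisitionGrid:
    """Ordered (b, TE) sample points of a placentome series.

    ``points`` is a sequence of (b in s/mm^2, TE in ms) pairs.  A grid is
    *identifiable* for the 6-parameter fit when it has at least 6 distinct
    points spanning at least 2 distinct b and 2 distinct TE values.
    """

    points: tuple = ()

    def __post_init__(self) -> None:
        pts = tuple((float(b), float(te)) for b, te in self.points)
        object.__setattr__(self, "points", pts)
        for b, te in pts:
            if b < 0:
                raise ValueError(f"b-value {b} must be >= 0")
            if te <= 0:
                raise ValueError(f"echo time {te} must be > 0")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def b(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def te(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def identifiable(self) -> bool:
        distinct = set(self.points)
        return (
            len(distinct) >= 6
            and len({b for b, _ in distinct}) >= 2
            and len({te for _, te in distinct}) >= 2
        )

    @classmethod
    def from_product(cls, b_values, te_values) -> "AcquisitionGrid":
        """Full factorial grid: all (b, TE) combinations, b-major order."""
        return cls(tuple((b, te) for b in b_values for te in te_values))


#: Default acquisition grid (full b x TE factorial), configurable.
DEFAULT_GRID = AcquisitionGrid.from_product(
    (0.0, 50.0, 100.0, 200.0, 400.0, 600.0),
    (72.0, 96.0, 120.0, 144.0, 192.0),
)


@dataclass
class PlacentomeSeries:
    """A 4D placentome acquisition: signal volume, mask, and its grid."""

    signal: np.ndarray
    mask: np.ndarray
    grid: AcquisitionGrid

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4D, got shape {self.signal.shape}")
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match signal "
                f"spatial shape {self.signal.shape[:3]}"
            )
        if self.signal.shape[3] != len(self.grid):
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but grid has "
                f"{len(self.grid)} points"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")

    def roi_mean_curve(self) -> np.ndarray:
        """Mean in-mask signal at each grid point."""
        if not self.mask.any():
            raise ValueError("empty mask")
        return self.signal[self.mask].mean(axis=0)


@dataclass
class ParameterMaps:
    """Voxelwise fit output: one 3D map per parameter plus diagnostics.

    Out-of-mask / unfitted voxels hold NaN; ``fitted`` is the companion
    boolean volume.  ``converged`` marks voxels where the optimiser
    reported success and the solution respects every box constraint.
    """

    maps: dict
    residual_norm: np.ndarray
    converged: np.ndarray
    iterations: np.ndarray
    fitted: np.ndarray
    roi_fit: "FitResult" = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


@dataclass
class FitResult:
    """ROI-level fit: recovered parameters and diagnostics."""

    params: PlacentomeModelParams
    residual_norm: float
    converged: bool
    iterations: int
    message: str = ""
    degenerate: bool = False


def _signal_components(vec, constants, b, te):
    f, d, d_star, t2fb, v, s0 = vec
    fv = f + v
    fetal = f * np.exp(-b * d_star - te / t2fb)
    maternal = v * np.exp(-te / constants.t2mb)
    tissue = (1.0 - fv) * np.exp(-b * d - te / constants.t2ts)
    # grouping keeps the b=TE=0 normalisation exact in floating point:
    # (f + v) + (1 - (f + v)) rounds to 1 for all f, v in [0, 1]
    return s0 * ((fetal + maternal) + tissue)


def forward_signal(params, constants=None, b=0.0, te=0.0):
    """Evaluate the three-compartment signal model.

    Parameters
    ----------
    params : PlacentomeModelParams
    constants : FixedCompartmentConstants, optional
        Fixed maternal-blood and tissue relaxation times; defaults to
        (150 ms, 42 ms).
    b : array_like
        Diffusion weighting, s/mm^2 (>= 0).
    te : array_like
        Echo time, ms (>= 0).

    Returns
    -------
    ndarray or float
        Signal in the units of ``params.s0``; S(0, 0) = S0 exactly.
    """
    constants = constants or FixedCompartmentConstants()
    b = np.asarray(b, dtype=float)
    te = np.asarray(te, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    if np.any(te < 0):
        raise ValueError("TE must be >= 0")
    out = _signal_components(params.as_vector(), constants, b, te)
    return float(out) if out.ndim == 0 else out


class DecideSignalModel(RegressorMixin, BaseEstimator):
    """Box-constrained inversion of the placentome signal model.

    A scikit-learn style regressor whose design matrix ``X`` holds the
    acquisition coordinates, one row per measurement, columns ``(b, TE)``
    in (s/mm^2, ms), and whose target ``y`` is the measured magnitude
    signal.  ``fit`` recovers the six parameters (f, d, d_star, T2fb, v,
    S0) by nonlinear least squares inside the stabilising boxes; the joint
    physicality constraint f + v < 1 is enforced through a hinge penalty
    residual (weight ``fv_penalty``).

    Parameters
    ----------
    constants : FixedCompartmentConstants, optional
        Fixed maternal-blood/tissue relaxation times.
    init : PlacentomeModelParams or None
        Starting point; when None a mid-box default (f=0.2, v=0.2,
        d=1.5e-3, d_star=0.03, T2fb=75, S0=max(y)) is used.
    method : {"trf", "lm-transformed"}
        "trf" solves the bound-constrained problem directly with a
        trust-region reflective solver; "lm-transformed" runs plain
        Levenberg-Marquardt on logit/log reparametrised coordinates.
    fv_penalty : float
        Weight of the hinge penalty on f + v >= 1.
    ftol : float
        Cost tolerance of the solver.
    max_iter : int
        Maximum number of residual evaluations.

    Attributes
    ----------
    params_ : PlacentomeModelParams
        Recovered parameters.
    residual_norm_ : float
        2-norm of the data residual at the solution.
    converged_ : bool
        Solver success with all constraints satisfied.
    degenerate_ : bool
        True when the data carry no decay information (flat curve).
    n_iter_ : int
        Residual evaluations used.
    """

    _parameter_constraints: dict = {}  # validated manually

    def __init__(
        self,
        constants=None,
        init=None,
        method="trf",
        fv_penalty=1e3,
        ftol=1e-10,
        max_iter=400,
    ):
        self.constants = constants
        self.init = init
        self.method = method
        self.fv_penalty = fv_penalty
        self.ftol = ftol
        self.max_iter = max_iter

    # -- reparametrisation for the unconstrained LM route ---------------
    @staticmethod
    def _to_internal(vec, s0_scale):
        eps = 1e-12
        out = np.empty(6)
        for i, name in enumerate(PARAM_NAMES[:5]):
            lo, hi = PARAM_BOUNDS[name]
            u = np.clip((vec[i] - lo) / (hi - lo), eps, 1 - eps)
            out[i] = math.log(u / (1 - u))
        out[5] = math.log(max(vec[5] / s0_scale, eps))
        return out

    @staticmethod
    def _from_internal(z, s0_scale):
        out = np.empty(6)
        for i, name in enumerate(PARAM_NAMES[:5]):
            lo, hi = PARAM_BOUNDS[name]
            out[i] = lo + (hi - lo) / (1.0 + math.exp(-z[i]))
        out[5] = s0_scale * math.exp(z[5])
        return out

    def _default_init(self, y):
        return np.array([0.2, 1.5e-3, 0.03, 75.0, 0.2, float(np.max(y))])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_points, 2) columns (b, TE)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        grid = AcquisitionGrid(tuple(map(tuple, X)))
        if not grid.identifiable:
            raise ValueError(
                "acquisition grid is non-identifiable: need >=6 distinct "
                "(b, TE) points spanning >=2 b and >=2 TE values"
            )
        constants = self.constants or FixedCompartmentConstants()
        b, te = X[:, 0], X[:, 1]

        if isinstance(self.init, PlacentomeModelParams):
            x0 = self.init.as_vector()
        elif self.init is not None:
            x0 = np.asarray(self.init, dtype=float)
        else:
            x0 = self._default_init(y)
        s0_scale = max(float(np.max(y)), 1e-30)

        span = float(np.ptp(y))
        degenerate = span <= 1e-12 * max(abs(float(np.max(y))), 1.0)

        def residuals(vec):
            r = _signal_components(vec, constants, b, te) - y
            fv_excess = max(vec[0] + vec[4] - 1.0 + 1e-9, 0.0)
            return np.append(r, self.fv_penalty * fv_excess)

        if self.method == "trf":
            margin = 1e-9  # keep the open box strictly open
            lo = np.array([margin, margin, margin, margin, margin, margin * s0_scale])
            hi = np.array(
                [1 - margin, 1 - margin, 1 - margin, 150 - margin, 1 - margin,
                 10.0 * s0_scale]
            )
            x0 = np.clip(x0, lo + margin, hi - margin)
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                ftol=self.ftol, xtol=1e-12, gtol=1e-12,
                max_nfev=self.max_iter * 6,
            )
            vec = sol.x
        elif self.method == "lm-transformed":
            z0 = self._to_internal(x0, s0_scale)
            sol = least_squares(
                lambda z: residuals(self._from_internal(z, s0_scale)),
                z0, method="lm", ftol=self.ftol, xtol=1e-12,
                max_nfev=self.max_iter * 6,
            )
            vec = self._from_internal(sol.x, s0_scale)
        else:
            raise ValueError(f"unknown method {self.method!r}")

        in_box = all(
            PARAM_BOUNDS[n][0] < vec[i] < PARAM_BOUNDS[n][1]
            for i, n in enumerate(PARAM_NAMES[:5])
        ) and vec[5] > 0 and vec[0] + vec[4] < 1.0

        # clamp strictly inside the open box so params_ always validates
        safe = vec.copy()
        for i, n in enumerate(PARAM_NAMES[:5]):
            lo_i, hi_i = PARAM_BOUNDS[n]
            w = hi_i - lo_i
            safe[i] = np.clip(safe[i], lo_i + 1e-10 * w, hi_i - 1e-10 * w)
        safe[5] = max(safe[5], 1e-30)
        if safe[0] + safe[4] >= 1.0:
            scale = (1.0 - 1e-10) / (safe[0] + safe[4])
            safe[0] *= scale
            safe[4] *= scale

        self.params_ = PlacentomeModelParams.from_vector(safe)
        data_resid = _signal_components(vec, constants, b, te) - y
        self.residual_norm_ = float(np.linalg.norm(data_resid))
        self.degenerate_ = bool(degenerate)
        self.converged_ = bool(sol.success and in_box and not degenerate)
        self.n_iter_ = int(sol.nfev)
        self.message_ = str(sol.message)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return forward_signal(
            self.params_, self.constants or FixedCompartmentConstants(),
            X[:, 0], X[:, 1],
        )


def _grid_design(grid: AcquisitionGrid) -> np.ndarray:
    return np.column_stack([grid.b, grid.te])


def fit_roi_average(series, constants=None, init=None, **fit_kwargs) -> FitResult:
    """Fit the mean in-mask signal curve of a placentome series.

    This is the stage-1 fit whose estimate initialises the voxelwise
    stage.  Raises on an empty mask or a non-identifiable grid; a flat
    (no-decay) curve yields a degenerate, non-converged result rather
    than a silent answer.
    """
    if not series.mask.any():
        raise ValueError("empty mask")
    curve = series.roi_mean_curve()
    est = DecideSignalModel(constants=constants, init=init, **fit_kwargs)
    est.fit(_grid_design(series.grid), curve)
    return FitResult(
        params=est.params_,
        residual_norm=est.residual_norm_,
        converged=est.converged_,
        iterations=est.n_iter_,
        message=est.message_,
        degenerate=est.degenerate_,
    )


def fit_voxelwise(series, constants=None, **fit_kwargs) -> ParameterMaps:
    """Two-stage voxelwise inversion of a placentome series.

    Stage 1 fits the ROI-average curve; stage 2 fits every in-mask voxel
    initialised at the stage-1 estimate.  Per-voxel failures are flagged
    in the diagnostics, never fatal.
    """
    if not series.mask.any():
        raise ValueError("empty mask")
    roi = fit_roi_average(series, constants=constants, **fit_kwargs)
    shape = series.mask.shape
    maps = {n: np.full(shape, np.nan) for n in PARAM_NAMES}
    residual_norm = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)
    iterations = np.zeros(shape, dtype=int)
    X = _grid_design(series.grid)
    est = DecideSignalModel(constants=constants, init=roi.params, **fit_kwargs)
    for idx in np.argwhere(series.mask):
        i, j, k = idx
        try:
            est.fit(X, series.signal[i, j, k])
        except Exception:
            continue
        for n in PARAM_NAMES:
            maps[n][i, j, k] = getattr(est.params_, n)
        residual_norm[i, j, k] = est.residual_norm_
        converged[i, j, k] = est.converged_
        iterations[i, j, k] = est.n_iter_
    fitted = np.isfinite(maps["f"])
    return ParameterMaps(
        maps=maps,
        residual_norm=residual_norm,
        converged=converged,
        iterations=iterations,
        fitted=fitted,
        roi_fit=roi,
    )


def t2_to_so2(t2_ms, calibration, clamp=True, saturate=False):
    """Convert blood T2 to oxygen saturation via a quadratic calibration.

    Inverts R2 = A + B (1 - Y)^2 (rates in 1/s, T2 in ms) for the
    saturation fraction Y, taking the physical root Y <= 1.

    Returns ``(Y, clamped)`` where ``clamped`` is True when the raw root
    fell outside [0, 1] and was clamped.  A relaxation rate below A
    (beyond tolerance) means the T2 is longer than fully oxygenated blood
    allows and raises ``ValueError``; with ``saturate=True`` (for noisy
    measured T2s) it returns (1.0, True) instead.
    """
    t2_ms = float(t2_ms)
    if t2_ms <= 0:
        raise ValueError("T2 must be positive")
    r2 = 1000.0 / t2_ms  # 1/s
    delta = r2 - calibration.a
    tol = 1e-9 * max(calibration.a, 1.0)
    if delta < -tol:
        if saturate:
            return (1.0, True)
        raise ValueError(
            f"T2={t2_ms} ms gives R2={r2:.4f}/s below the fully-oxygenated "
            f"calibration limit A={calibration.a}/s"
        )
    delta = max(delta, 0.0)
    y = 1.0 - math.sqrt(delta / calibration.b)
    clamped = y < 0.0
    if clamped and not clamp:
        raise ValueError(f"SO2 root {y:.4f} outside [0, 1]")
    return (min(max(y, 0.0), 1.0), clamped)
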