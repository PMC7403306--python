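"""Inverse problem: recover (R_max, eta, eps_f_rr) from radius-time data.

The measured quantity is a set of (delay, radius) points with replicate
structure — typically one bubble photographed per laser shot, several
shots per 1 µs delay increment.  The forward model is one simulated
growth/collapse cycle; the fit is a bounded nonlinear least-squares
(a trust-region-reflective variant of Levenberg-Marquardt) over

* ``R_max`` — maximum bubble radius (also fixes the gas law),
* ``eta`` — Neo-Hookean elastic modulus,
* ``eps_f_rr`` — radial failure strain (frozen in no-failure mode),
* ``t0`` — optional nuisance time offset between the laser pulse and
  the model's inception turning point.

The primary user-facing surface is :class:`CavitationRheometer`, a
scikit-learn-style estimator (``fit(t, R)`` then fitted attributes with
trailing underscores); :func:`fit_dataset` is a thin wrapper over it.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .constitutive import (
    AmbientConditions,
    Material,
    circumferential_failure_strain,
)
from .dynamics import SolverError, Trajectory, simulate_cycle, water_cycle_time_analytic

__all__ = [
    "RadiusTimeDataset",
    "FitParameters",
    "FitResult",
    "FitSummary",
    "CavitationRheometer",
    "residuals",
    "initial_guess",
    "fit_dataset",
    "aggregate_fits",
]

#: residual (m) injected per point when the forward simulation fails,
#: steering the optimizer back into the feasible region
_PENALTY_RESIDUAL = 1e-3

_DATASET_COLUMNS = ("time_us", "radius_um", "replicate_id", "sample_id")


@dataclass
class RadiusTimeDataset:
    """Radius-time measurements for one sample.

    ``points`` holds SI columns ``time_s``, ``radius_m``,
    ``replicate_id``; file I/O uses the boundary schema
    (``time_us``, ``radius_um``, ``replicate_id``, ``sample_id``).
    """

    sample_id: str
    points: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"time_s", "radius_m", "replicate_id"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"points missing columns {sorted(missing)}")
        if len(self.points) == 0:
            raise ValueError("dataset must contain at least one point")
        if (self.points["time_s"] < 0).any():
            raise ValueError("delays must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.points["time_s"].to_numpy(dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return self.points["radius_m"].to_numpy(dtype=float)

    def n_delays(self) -> int:
        return self.points["time_s"].nunique()

    def replicate_counts(self) -> pd.Series:
        return self.points.groupby("time_s")["replicate_id"].count()

    def checksum(self) -> str:
        """SHA-256 of the canonical table, for provenance in fit reports."""
        buf = io.StringIO()
        self.to_table().to_csv(buf, index=False, float_format="%.9g")
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()

    def to_table(self) -> pd.DataFrame:
        """Boundary-unit table (µs, µm) in the standard column schema."""
        return pd.DataFrame(
            {
                "time_us": self.points["time_s"] * 1e6,
                "radius_um": self.points["radius_m"] * 1e6,
                "replicate_id": self.points["replicate_id"],
                "sample_id": self.sample_id,
            }
        )

    def write_csv(self, path, header_comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.to_table().to_csv(fh, index=False)

    @classmethod
    def from_table(cls, table: pd.DataFrame, metadata: Optional[dict] = None) -> "RadiusTimeDataset":
        missing = set(_DATASET_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"dataset table missing columns {sorted(missing)}")
        sample_ids = table["sample_id"].unique()
        if len(sample_ids) != 1:
            raise ValueError(
                "one RadiusTimeDataset per sample; use split_samples() for "
                f"multi-sample tables (found {list(sample_ids)})"
            )
        points = pd.DataFrame(
            {
                "time_s": table["time_us"].astype(float) * 1e-6,
                "radius_m": table["radius_um"].astype(float) * 1e-6,
                "replicate_id": table["replicate_id"].astype(int),
            }
        )
        return cls(sample_id=str(sample_ids[0]), points=points, metadata=metadata or {})

    @classmethod
    def read_csv(cls, path, metadata: Optional[dict] = None) -> "RadiusTimeDataset":
        table = pd.read_csv(path, comment="#")
        return cls.from_table(table, metadata=metadata)

    @staticmethod
    def split_samples(table: pd.DataFrame) -> list["RadiusTimeDataset"]:
        return [
            RadiusTimeDataset.from_table(group)
            for _, group in table.groupby("sample_id", sort=True)
        ]


@dataclass(frozen=True)
class FitParameters:
    """Point in the fit parameter space (SI units)."""

    r_max: float
    eta: float
    eps_f_rr: Optional[float] = None  # None = no-failure model
    t0: float = 0.0

    def as_material(self, base: Material) -> Material:
        return replace(
            base,
            elastic_modulus=self.eta,
            radial_failure_strain=self.eps_f_rr,
        )


@dataclass
class FitBounds:
    """Box bounds for the fit.

    ``r_max_window`` multiplies the largest observed radius; the other
    bounds are absolute (SI).
    """

    r_max_window: tuple[float, float] = (0.9, 1.5)
    eta: tuple[float, float] = (0.0, 2.0e5)
    eps_f_rr: tuple[float, float] = (0.0, 0.499)
    t0: float = 2.0e-6  # |t0| bound


@dataclass
class FitResult:
    """Outcome of one dataset fit."""

    params: FitParameters
    eps_f_tt: Optional[float]
    residual_norm: float
    per_point_residuals: np.ndarray
    n_iter: int
    status: int
    message: str
    converged: bool
    covariance: Optional[np.ndarray]
    param_names: tuple[str, ...]
    sample_id: str = ""

    def uncertainties(self) -> dict[str, float]:
        """One-sigma uncertainties from the approximate covariance."""
        if self.covariance is None:
            return {}
        sig = np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))
        return dict(zip(self.param_names, sig))

    def to_dict(self) -> dict:
        out = {
            "sample_id": self.sample_id,
            "estimate": {
                "r_max_um": self.params.r_max * 1e6,
                "eta_kpa": self.params.eta * 1e-3,
                "eps_f_rr": self.params.eps_f_rr,
                "eps_f_tt": self.eps_f_tt,
                "t0_us": self.params.t0 * 1e6,
            },
            "uncertainty": self.uncertainties(),
            "convergence": {
                "iterations": self.n_iter,
                "status": self.status,
                "message": self.message,
                "converged": self.converged,
                "residual_norm_m": self.residual_norm,
            },
        }
        return out


@dataclass
class FitSummary:
    """Per-condition mean and sample standard deviation across fits."""

    table: pd.DataFrame
    n_samples: int


def _model_radius(
    trajectory: Trajectory, times: np.ndarray, t0: float
) -> np.ndarray:
    """Model radius at observation times, with out-of-window points
    clamped to the nearest cycle-endpoint radius."""
    t = np.asarray(times, dtype=float) - t0
    # np.interp clamps to endpoint values outside the window, which is
    # exactly the documented convention
    return np.interp(t, trajectory.times, trajectory.radii)


def residuals(
    params: FitParameters,
    dataset: RadiusTimeDataset,
    material_fixed: Material = Material(),
    ambient: AmbientConditions = AmbientConditions(),
    mode: str = "failure",
    weighting: str = "point",
    rtol: float = 1e-8,
) -> np.ndarray:
    """Vector of (model - observed) radii, m.

    ``weighting="point"`` uses every replicate point; ``"delay-mean"``
    first averages replicates at each delay.  A failed forward
    simulation yields a constant large penalty vector (with a warning)
    rather than an exception, keeping the optimizer moving.
    """
    if weighting not in ("point", "delay-mean"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "delay-mean":
        grouped = dataset.points.groupby("time_s", as_index=False)["radius_m"].mean()
        times = grouped["time_s"].to_numpy()
        radii = grouped["radius_m"].to_numpy()
    else:
        times = dataset.times
        radii = dataset.radii
    material = params.as_material(material_fixed)
    try:
        trajectory = simulate_cycle(
            params.r_max, material, ambient, mode=mode, rtol=rtol
        )
    except (SolverError, ValueError) as err:
        warnings.warn(
            f"forward simulation failed at {params} ({err}); "
            "returning penalty residuals",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(times.shape, _PENALTY_RESIDUAL)
    return _model_radius(trajectory, times, params.t0) - radii


def initial_guess(
    dataset: RadiusTimeDataset,
    material_fixed: Material = Material(),
    ambient: AmbientConditions = AmbientConditions(),
    rtol: float = 1e-7,
) -> FitParameters:
    """Starting point for the optimizer.

    ``R_max`` starts at the largest observed radius; ``eta`` from a
    one-point cycle-shortening inversion (the observed cycle time
    relative to the water limit, read against a simulated shortening at
    a reference modulus with eps_f_rr = 0.25); ``eps_f_rr`` at 0.25 and
    ``t0`` at 0.
    """
    if dataset.n_delays() < 4:
        raise ValueError(
            f"under-determined data: {dataset.n_delays()} distinct delays (< 4)"
        )
    r_max0 = float(dataset.radii.max())
    t_obs = float(dataset.times.max()) - float(dataset.times.min())
    t_w = water_cycle_time_analytic(r_max0, material_fixed.density, ambient)
    ratio_obs = min(t_obs / t_w, 1.0)
    eta_ref = 3.0e4
    ref = simulate_cycle(
        r_max0,
        replace(material_fixed, elastic_modulus=eta_ref, radial_failure_strain=0.25),
        ambient,
        mode="failure",
        rtol=rtol,
    )
    ratio_ref = ref.cycle_time / t_w
    # linear shortening through (eta=0, ratio=1): eta ~ (1 - r_obs)/slope
    if ratio_ref >= 1.0:
        eta0 = 0.0
    else:
        eta0 = eta_ref * (1.0 - ratio_obs) / (1.0 - ratio_ref)
    eta0 = float(np.clip(eta0, 0.0, 1.0e5))
    return FitParameters(r_max=r_max0, eta=eta0, eps_f_rr=0.25, t0=0.0)


class CavitationRheometer(RegressorMixin, BaseEstimator):
    """Estimator recovering hydrogel mechanics from bubble radius-time data.

    ``fit(t, R)`` takes observation times (s, shape ``(n,)`` or
    ``(n, 1)``) and bubble radii (m) and recovers the maximum bubble
    radius, the Neo-Hookean elastic modulus and (in failure mode) the
    radial failure strain by bounded nonlinear least squares against
    the forward cycle simulation; ``predict(t)`` returns the fitted
    model radii.

    Parameters
    ----------
    mode : {"with_failure", "no_failure"}
        "no_failure" freezes the failure strain at the never-fails
        sentinel and fits only (R_max, eta[, t0]).
    fit_time_offset : bool
        Whether to fit the nuisance offset t0 between the laser pulse
        and the model inception point.  Default True.
    kinematic_viscosity, density, surface_tension : float
        Fixed material constants (SI); not fitted.
    ambient : AmbientConditions, optional
        Far-field/gas constants.  Default: water at 25 degC, kappa=4/3.
    weighting : {"point", "delay-mean"}
        Residual weighting; see :func:`residuals`.
    bounds : FitBounds, optional
    init : FitParameters, optional
        Override the automatic initial guess.
    rtol : float
        ODE tolerance used inside residual evaluations.
    diff_step : float
        Relative forward-difference step for the Jacobian.
    xtol, ftol, gtol : float
        Optimizer termination tolerances.
    max_nfev : int, optional
        Cap on residual evaluations.

    Attributes
    ----------
    r_max_ : float
        Fitted maximum bubble radius, m.
    elastic_modulus_ : float
        Fitted elastic modulus eta, Pa.
    radial_failure_strain_ : float or None
        Fitted eps_f_rr (None in no-failure mode).
    circumferential_failure_strain_ : float or None
        Derived eps_f_tt (exactly the constitutive composition).
    time_offset_ : float
        Fitted (or frozen) t0, s.
    result_ : FitResult
        Full fit report including covariance and convergence block.
    trajectory_ : Trajectory
        Forward simulation at the fitted parameters.
    """

    def __init__(
        self,
        mode: str = "with_failure",
        fit_time_offset: bool = True,
        kinematic_viscosity: float = 1.0e-6,
        density: float = 997.0,
        surface_tension: float = 0.072,
        ambient: Optional[AmbientConditions] = None,
        weighting: str = "point",
        bounds: Optional[FitBounds] = None,
        init: Optional[FitParameters] = None,
        rtol: float = 1e-8,
        diff_step: float = 1e-4,
        xtol: float = 1e-8,
        ftol: float = 1e-10,
        gtol: float = 1e-10,
        max_nfev: Optional[int] = None,
    ) -> None:
        self.mode = mode
        self.fit_time_offset = fit_time_offset
        self.kinematic_viscosity = kinematic_viscosity
        self.density = density
        self.surface_tension = surface_tension
        self.ambient = ambient
        self.weighting = weighting
        self.bounds = bounds
        self.init = init
        self.rtol = rtol
        self.diff_step = diff_step
        self.xtol = xtol
        self.ftol = ftol
        self.gtol = gtol
        self.max_nfev = max_nfev

    # -- helpers -------------------------------------------------------
    def _material_fixed(self) -> Material:
        return Material(
            elastic_modulus=0.0,
            kinematic_viscosity=self.kinematic_viscosity,
            density=self.density,
            surface_tension=self.surface_tension,
            radial_failure_strain=None,
        )

    def _ambient(self) -> AmbientConditions:
        return self.ambient if self.ambient is not None else AmbientConditions()

    @staticmethod
    def _as_dataset(t, r) -> RadiusTimeDataset:
        t = np.asarray(t, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        r = np.asarray(r, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValueError("t and R must be 1-d arrays of equal length")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(r)):
            raise ValueError("non-finite values in input")
        points = pd.DataFrame(
            {"time_s": t, "radius_m": r, "replicate_id": np.arange(len(t))}
        )
        return RadiusTimeDataset(sample_id="<array>", points=points)

    # -- estimator API -------------------------------------------------
    def fit(self, X, y, dataset: Optional[RadiusTimeDataset] = None):
        """Fit the bubble model to radius-time observations.

        ``X``: times since the laser pulse, s; ``y``: radii, m.
        Alternatively pass a prebuilt ``dataset`` (then X, y may be
        None).
        """
        if self.mode not in ("with_failure", "no_failure"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if dataset is None:
            dataset = self._as_dataset(X, y)
        material_fixed = self._material_fixed()
        ambient = self._ambient()
        bounds = self.bounds if self.bounds is not None else FitBounds()
        init = self.init
        if init is None:
            init = initial_guess(dataset, material_fixed, ambient)
        sim_mode = "failure" if self.mode == "with_failure" else "elastic"

        r_obs_max = float(dataset.radii.max())
        lo_rmax = bounds.r_max_window[0] * r_obs_max
        hi_rmax = bounds.r_max_window[1] * r_obs_max

        names = ["r_max", "eta"]
        x0 = [np.clip(init.r_max, lo_rmax, hi_rmax), init.eta]
        lo = [lo_rmax, bounds.eta[0]]
        hi = [hi_rmax, bounds.eta[1]]
        scales = [r_obs_max, 1.0e4]
        if self.mode == "with_failure":
            names.append("eps_f_rr")
            x0.append(init.eps_f_rr if init.eps_f_rr is not None else 0.25)
            lo.append(bounds.eps_f_rr[0])
            hi.append(bounds.eps_f_rr[1])
            scales.append(0.1)
        if self.fit_time_offset:
            names.append("t0")
            x0.append(init.t0)
            lo.append(-bounds.t0)
            hi.append(bounds.t0)
            scales.append(1.0e-6)

        def unpack(x) -> FitParameters:
            d = dict(zip(names, x))
            return FitParameters(
                r_max=d["r_max"],
                eta=d["eta"],
                eps_f_rr=d.get("eps_f_rr") if self.mode == "with_failure" else None,
                t0=d.get("t0", init.t0 if not self.fit_time_offset else 0.0),
            )

        def fun(x):
            # optimize on the µm scale so the default termination
            # tolerances are meaningful for O(100 µm) radii
            return 1e6 * residuals(
                unpack(x),
                dataset,
                material_fixed,
                ambient,
                mode=sim_mode,
                weighting=self.weighting,
                rtol=self.rtol,
            )

        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        sol = least_squares(
            fun,
            x0,
            bounds=(lo, hi),
            method="trf",
            x_scale=np.asarray(scales),
            diff_step=self.diff_step,
            xtol=self.xtol,
            ftol=self.ftol,
            gtol=self.gtol,
            max_nfev=self.max_nfev,
        )
        params = unpack(sol.x)
        eps_tt = (
            circumferential_failure_strain(params.eps_f_rr)
            if params.eps_f_rr is not None
            else None
        )

        m, k = len(sol.fun), len(sol.x)
        cov = None
        if m > k:
            jtj = sol.jac.T @ sol.jac
            try:
                sigma2 = 2.0 * sol.cost / (m - k)
                cov = sigma2 * np.linalg.pinv(jtj)
            except np.linalg.LinAlgError:  # pragma: no cover
                cov = None

        self.result_ = FitResult(
            params=params,
            eps_f_tt=eps_tt,
            residual_norm=float(np.linalg.norm(sol.fun)) * 1e-6,
            per_point_residuals=sol.fun * 1e-6,
            n_iter=int(sol.nfev),
            status=int(sol.status),
            message=sol.message,
            converged=bool(sol.status > 0),
            covariance=cov,
            param_names=tuple(names),
            sample_id=dataset.sample_id,
        )
        if not self.result_.converged:
            warnings.warn(
                f"fit did not converge ({sol.message}); best-so-far estimate kept",
                RuntimeWarning,
                stacklevel=2,
            )
        self.r_max_ = params.r_max
        self.elastic_modulus_ = params.eta
        self.radial_failure_strain_ = params.eps_f_rr
        self.circumferential_failure_strain_ = eps_tt
        self.time_offset_ = params.t0
        self.trajectory_ = simulate_cycle(
            params.r_max,
            params.as_material(material_fixed),
            ambient,
            mode=sim_mode,
            rtol=self.rtol,
        )
        self.n_iter_ = self.result_.n_iter
        return self

    def predict(self, X) -> np.ndarray:
        """Fitted model radius (m) at the given times (s)."""
        if not hasattr(self, "trajectory_"):
            raise AttributeError("estimator is not fitted yet")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        return _model_radius(self.trajectory_, t, self.time_offset_)


def fit_dataset(
    dataset: RadiusTimeDataset,
    init: Optional[FitParameters] = None,
    bounds: Optional[FitBounds] = None,
    mode: str = "with_failure",
    **options,
) -> FitResult:
    """Fit one dataset and return the :class:`FitResult` (wrapper over
    :class:`CavitationRheometer`)."""
    est = CavitationRheometer(mode=mode, init=init, bounds=bounds, **options)
    est.fit(None, None, dataset=dataset)
    return est.result_


def aggregate_fits(results: Sequence[FitResult]) -> FitSummary:
    """Mean and sample standard deviation (n-1 denominator) of each
    fitted parameter across per-sample fits; a single fit reports sd 0
    by convention."""
    if len(results) == 0:
        raise ValueError("need at least one fit result")
    rows = []
    for res in results:
        rows.append(
            {
                "sample_id": res.sample_id,
                "r_max_um": res.params.r_max * 1e6,
                "eta_kpa": res.params.eta * 1e-3,
                "eps_f_rr": np.nan if res.params.eps_f_rr is None else res.params.eps_f_rr,
                "eps_f_tt": np.nan if res.eps_f_tt is None else res.eps_f_tt,
            }
        )
    per_sample = pd.DataFrame(rows)
    params = ["r_max_um", "eta_kpa", "eps_f_rr", "eps_f_tt"]
    mean = per_sample[params].mean()
    sd = per_sample[params].std(ddof=1).fillna(0.0) if len(results) > 1 else pd.Series(
        0.0, index=params
    )
    table = pd.DataFrame({"mean": mean, "sd": sd})
    return FitSummary(table=table, n_samples=len(results))
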