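"""Tracer-kinetic forward models and bounded nonlinear fitting.

Implements the two-compartment Kety-Tofts model

    Ct(t) = Ktrans * int_0^t Cp(u) exp(-(Ktrans/ve)(t-u)) du,

its early-phase Patlak linearisation

    Ct(t) = Ktrans * int_0^t Cp(u) du + vp * Cp(t),

and the reference-region (AIF-free) variants that replace the plasma
input with a measured curve from a tissue of assumed kinetics (chest-wall
muscle).  The reference-region Kety-Tofts solution used here is the
closed form

    C_toi(t) = R [ C_rr(t) + (k_ep,rr - k_ep,toi) * int_0^t C_rr(u)
                   exp(-k_ep,toi (t-u)) du ],   R = Ktrans / Ktrans_rr,

which solves the usual integral relation exactly; the reference-region
Patlak variant is its no-efflux limit,

    C_toi(t) = R C_rr(t) + (Ktrans / ve_rr) * int_0^t C_rr(u) du.

Convolutions with the exponential kernel use a recursion that is exact
for piecewise-linear inputs, so accuracy on coarse (15 s) grids is set by
how well the sampled input represents the true curve, not by the
quadrature.  Time is in minutes, Ktrans in 1/min, concentrations in mM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares, lsq_linear

__all__ = [
    "AifCurve",
    "VoxelParams",
    "RefRegionParams",
    "FitResult",
    "population_aif",
    "exp_conv",
    "skt_forward",
    "patlak_forward",
    "rr_skt_forward",
    "rr_patlak_forward",
    "fit_model",
    "filter_physiological",
    "in_physiological_range",
    "PHYSIO_KTRANS",
    "PHYSIO_VE",
    "aif_to_csv",
    "aif_from_csv",
]

# open physiological box applied voxelwise after fitting
PHYSIO_KTRANS = (0.001, 5.0)
PHYSIO_VE = (0.001, 1.0)

KTRANS_BOUNDS = (1e-5, 10.0)
VE_BOUNDS = (1e-5, 1.0)
VP_BOUNDS = (0.0, 0.5)

# default muscle kinetics for the reference-region models (literature
# values for skeletal muscle; configurable, nothing is published for
# either cohort)
MUSCLE_KTRANS = 0.1  # 1/min
MUSCLE_VE = 0.1


@dataclass(frozen=True)
class VoxelParams:
    """Per-voxel kinetic parameters."""

    ktrans: float  # 1/min
    ve: float  # fraction
    vp: float | None = None  # plasma fraction, Patlak only

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("ktrans must be >= 0")
        if not (0 <= self.ve <= 1):
            raise ValueError("ve must be in [0, 1]")
        if self.vp is not None and not (0 <= self.vp <= 1):
            raise ValueError("vp must be in [0, 1]")

    @property
    def kep(self) -> float:
        if self.ktrans == 0:
            return 0.0
        if self.ve == 0:
            raise ValueError("ve must be positive when ktrans > 0")
        return self.ktrans / self.ve


@dataclass(frozen=True)
class RefRegionParams:
    """Assumed kinetics of the reference tissue."""

    ktrans_rr: float = MUSCLE_KTRANS
    ve_rr: float = MUSCLE_VE

    def __post_init__(self) -> None:
        if self.ktrans_rr <= 0 or self.ve_rr <= 0:
            raise ValueError("reference-region parameters must be strictly positive")

    @property
    def kep_rr(self) -> float:
        return self.ktrans_rr / self.ve_rr


@dataclass(frozen=True)
class FitResult:
    params: VoxelParams
    residual_norm: float
    converged: bool
    in_physiological_range: bool


@dataclass(frozen=True)
class AifCurve:
    """Plasma concentration vs time; zero before the bolus onset."""

    time_min: np.ndarray
    cp: np.ndarray  # mM
    onset_min: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        c = np.asarray(self.cp, dtype=float)
        if t.shape != c.shape:
            raise ValueError("time and cp must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "cp", c)

    def resample(self, time_min) -> "AifCurve":
        t = np.asarray(time_min, dtype=float)
        return AifCurve(t, np.interp(t, self.time_min, self.cp), self.onset_min)


# Parker-type population AIF: two Gaussian bolus passes plus a
# sigmoid-gated exponential washout.  Amplitudes in mmol (scaled by the
# Gaussian normalisation), centres/widths in minutes.
_PARKER = dict(
    a1=0.809, a2=0.330,
    t1=0.17046, t2=0.365,
    s1=0.0563, s2=0.132,
    alpha=1.050, beta=0.1685,
    s=38.078, tau=0.483,
)


def population_aif(time_min, onset_min: float = 0.0, dose_scale: float = 1.0) -> AifCurve:
    """Population-averaged arterial input function on ``time_min``.

    A standard bi-Gaussian-plus-washout mixture shifted so the bolus
    starts at ``onset_min`` and scaled linearly by ``dose_scale``.
    """
    t = np.asarray(time_min, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("time grid must be 1-D, sorted ascending")
    ts = t - onset_min
    p = _PARKER
    cp = np.zeros_like(ts)
    pos = ts > 0
    u = ts[pos]
    for a, mu, sig in ((p["a1"], p["t1"], p["s1"]), (p["a2"], p["t2"], p["s2"])):
        cp[pos] += a / (sig * np.sqrt(2 * np.pi)) * np.exp(-((u - mu) ** 2) / (2 * sig**2))
    cp[pos] += p["alpha"] * np.exp(-p["beta"] * u) / (1 + np.exp(-p["s"] * (u - p["tau"])))
    return AifCurve(t, dose_scale * cp, onset_min=onset_min)


def exp_conv(time_min, c, kep: float):
    """``int_0^t c(u) exp(-kep (t-u)) du`` for piecewise-linear ``c``.

    Exact for an input that is linear between samples; reduces to the
    cumulative trapezoid when ``kep`` is (numerically) zero.  ``c`` may be
    1-D or (frames x voxels).
    """
    t = np.asarray(time_min, dtype=float)
    c = np.asarray(c, dtype=float)
    if c.shape[0] != t.shape[0]:
        raise ValueError("time grid and curve must align on axis 0")
    dt = np.diff(t)
    out = np.zeros_like(c)
    if kep * np.max(dt, initial=0.0) < 1e-12:
        if c.ndim == 1:
            out[1:] = cumulative_trapezoid(c, t)
        else:
            out[1:] = cumulative_trapezoid(c, t, axis=0)
        return out
    e = np.exp(-kep * dt)
    # per-interval integral of (c0 + m u) exp(-kep (dt - u)) on [0, dt]
    f0 = (1.0 - e) / kep
    f1 = (dt - f0) / kep  # integral of u exp(-kep (dt-u)) / dt-slope helper
    if c.ndim > 1:
        e = e[:, None]
        f0 = f0[:, None]
        f1 = f1[:, None]
        dt = dt[:, None]
    m = (c[1:] - c[:-1]) / dt
    seg = c[:-1] * f0 + m * f1
    dts = np.diff(t)
    if np.ptp(dts) <= 1e-9 * dts[0]:
        # uniform grid: the recursion is a constant-coefficient IIR filter
        from scipy.signal import lfilter

        e0 = float(np.exp(-kep * dts[0]))
        out[1:] = lfilter([1.0], [1.0, -e0], seg, axis=0)
        return out
    for k in range(1, c.shape[0]):
        out[k] = out[k - 1] * e[k - 1] + seg[k - 1]
    return out


def _prepare_input(aif: AifCurve, time_min):
    """Return (grid, cp, needs_interp) — convolve on the AIF's own grid
    when it is denser than the requested output grid."""
    t_out = np.asarray(time_min, dtype=float)
    t_in = aif.time_min
    if t_out.shape == t_in.shape and np.allclose(t_out, t_in):
        return t_in, aif.cp, False
    if t_in[-1] < t_out[-1] - 1e-9 or t_in[0] > t_out[0] + 1e-9:
        # AIF grid does not span the output: fall back to resampling
        return t_out, np.interp(t_out, t_in, aif.cp), False
    # trim the (possibly dense) input grid to the fitted window
    stop = int(np.searchsorted(t_in, t_out[-1] + 1e-12, side="left"))
    stop = min(stop + 1, t_in.size)
    return t_in[:stop], aif.cp[:stop], True


def skt_forward(params: VoxelParams, aif: AifCurve, time_min) -> np.ndarray:
    """Kety-Tofts tissue concentration on ``time_min`` (mM).

    The convolution is evaluated on the AIF's native grid (which may be
    finer than the acquisition grid) and interpolated to the output
    times, so a densely tabulated input keeps coarse-grid evaluations
    accurate.
    """
    t_out = np.asarray(time_min, dtype=float)
    if params.ktrans == 0:
        return np.zeros_like(t_out)
    grid, cp, interp = _prepare_input(aif, t_out)
    ct = params.ktrans * exp_conv(grid, cp, params.kep)
    return np.interp(t_out, grid, ct) if interp else ct


def patlak_forward(params: VoxelParams, aif: AifCurve, time_min) -> np.ndarray:
    """Patlak tissue concentration: influx plus plasma term, no efflux."""
    t_out = np.asarray(time_min, dtype=float)
    vp = params.vp or 0.0
    grid, cp, interp = _prepare_input(aif, t_out)
    integral = np.concatenate(([0.0], cumulative_trapezoid(cp, grid)))
    ct = params.ktrans * integral + vp * cp
    return np.interp(t_out, grid, ct) if interp else ct


def _check_rr_grid(c_rr, time_min):
    t = np.asarray(time_min, dtype=float)
    c = np.asarray(c_rr, dtype=float)
    if c.shape != t.shape:
        raise ValueError("reference-region curve must be on the same grid")
    return t, c


def rr_skt_forward(
    params_toi: VoxelParams, rr: RefRegionParams, c_rr, time_min
) -> np.ndarray:
    """Reference-region Kety-Tofts tissue curve from a measured muscle curve."""
    t, c = _check_rr_grid(c_rr, time_min)
    if params_toi.ktrans == 0:
        return np.zeros_like(t)
    ratio = params_toi.ktrans / rr.ktrans_rr
    kep = params_toi.kep
    return ratio * (c + (rr.kep_rr - kep) * exp_conv(t, c, kep))


def rr_patlak_forward(
    params_toi: VoxelParams, rr: RefRegionParams, c_rr, time_min
) -> np.ndarray:
    """No-efflux limit of the reference-region model (early phase only)."""
    t, c = _check_rr_grid(c_rr, time_min)
    if params_toi.ktrans == 0:
        return np.zeros_like(t)
    integral = np.concatenate(([0.0], cumulative_trapezoid(c, t)))
    return (params_toi.ktrans / rr.ktrans_rr) * c + (
        params_toi.ktrans / rr.ve_rr
    ) * integral


def in_physiological_range(ktrans: float, ve: float | None) -> bool:
    """Strict open-box filter; ``ve`` is skipped when the model has none."""
    ok = PHYSIO_KTRANS[0] < ktrans < PHYSIO_KTRANS[1]
    if ve is not None and not np.isnan(ve):
        ok = ok and PHYSIO_VE[0] < ve < PHYSIO_VE[1]
    return bool(ok)


MODELS = ("skt", "patlak", "rr_skt", "rr_patlak")

_MULTISTART = (
    (0.1, 0.3),  # default initialisation
    (0.5, 0.6),
    (0.02, 0.15),
)


def fit_model(
    model: str,
    curve,
    aif_or_rr,
    time_min,
    c_rr=None,
    init: tuple | None = None,
    bounds: dict | None = None,
) -> FitResult:
    """Bounded least-squares fit of one tissue curve (concentration, mM).

    ``model`` selects among ``skt``/``patlak`` (``aif_or_rr`` is an
    :class:`AifCurve`) and ``rr_skt``/``rr_patlak`` (``aif_or_rr`` is a
    :class:`RefRegionParams` and ``c_rr`` the measured reference curve).
    Patlak-family fits are linear in their parameters and solved
    directly; Kety-Tofts fits use bounded nonlinear least squares with a
    deterministic 3-point multi-start on non-convergence.  Fitted
    parameters are screened by the strict physiological filter.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(curve, dtype=float)
    if y.shape != t.shape:
        raise ValueError("curve and time grid must align")
    if not np.all(np.isfinite(y)):
        raise ValueError("curve must be finite")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")

    kt_b = (bounds or {}).get("ktrans", KTRANS_BOUNDS)
    ve_b = (bounds or {}).get("ve", VE_BOUNDS)
    vp_b = (bounds or {}).get("vp", VP_BOUNDS)

    if model == "patlak":
        grid, cp, _ = _prepare_input(aif_or_rr, t)
        integral = np.interp(t, grid, np.concatenate(([0.0], cumulative_trapezoid(cp, grid))))
        cp_t = np.interp(t, grid, cp)
        design = np.column_stack([integral, cp_t])
        sol = lsq_linear(design, y, bounds=([kt_b[0], vp_b[0]], [kt_b[1], vp_b[1]]))
        ktrans, vp = float(sol.x[0]), float(sol.x[1])
        params = VoxelParams(ktrans=ktrans, ve=0.0, vp=vp)
        return FitResult(
            params=params,
            residual_norm=float(np.linalg.norm(design @ sol.x - y)),
            converged=bool(sol.success),
            in_physiological_range=in_physiological_range(ktrans, None),
        )

    if model == "rr_patlak":
        rr = aif_or_rr
        c = np.asarray(c_rr, dtype=float)
        integral = np.concatenate(([0.0], cumulative_trapezoid(c, t)))
        x = c / rr.ktrans_rr + integral / rr.ve_rr  # Ct = ktrans * x
        denom = float(x @ x)
        ktrans = float(np.clip(x @ y / denom, *kt_b)) if denom > 0 else kt_b[0]
        params = VoxelParams(ktrans=ktrans, ve=0.0, vp=None)
        return FitResult(
            params=params,
            residual_norm=float(np.linalg.norm(ktrans * x - y)),
            converged=denom > 0,
            in_physiological_range=in_physiological_range(ktrans, None),
        )

    # nonlinear Kety-Tofts pathways
    if model == "skt":
        grid, cp, interp = _prepare_input(aif_or_rr, t)

        def forward(kt, ve):
            ct = kt * exp_conv(grid, cp, kt / ve)
            return np.interp(t, grid, ct) if interp else ct

    else:  # rr_skt
        rr = aif_or_rr
        c = np.asarray(c_rr, dtype=float)

        def forward(kt, ve):
            kep = kt / ve
            return (kt / rr.ktrans_rr) * (c + (rr.kep_rr - kep) * exp_conv(t, c, kep))

    def resid(p):
        return forward(p[0], p[1]) - y

    if init is not None:
        starts = [init]
    else:
        # data-driven first start: influx-only linear pre-estimate of
        # ktrans pins the scale and avoids spurious local minima
        if model == "skt":
            x_lin = np.interp(
                t, grid, np.concatenate(([0.0], cumulative_trapezoid(cp, grid)))
            )
        else:
            x_lin = c / aif_or_rr.ktrans_rr + np.concatenate(
                ([0.0], cumulative_trapezoid(c, t))
            ) / aif_or_rr.ve_rr
        xx = float(x_lin @ x_lin)
        kt0 = float(np.clip(x_lin @ y / xx, *kt_b)) if xx > 0 else 0.1
        starts = [(kt0, 0.3)] + [s for s in _MULTISTART if s != (kt0, 0.3)]

    def at_bound(x):
        return (
            x[0] < kt_b[0] * (1 + 1e-6) or x[0] > kt_b[1] * (1 - 1e-6)
            or x[1] < ve_b[0] * (1 + 1e-6) or x[1] > ve_b[1] * (1 - 1e-6)
        )

    best = None
    for k, (kt0, ve0) in enumerate(starts):
        sol = least_squares(
            resid,
            x0=[np.clip(kt0, *kt_b), np.clip(ve0, *ve_b)],
            bounds=([kt_b[0], ve_b[0]], [kt_b[1], ve_b[1]]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and k == 0 and not at_bound(sol.x):
            break  # first start converged cleanly; multi-start is a rescue
    ktrans, ve = float(best.x[0]), float(best.x[1])
    params = VoxelParams(ktrans=ktrans, ve=ve)
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
        in_physiological_range=in_physiological_range(ktrans, ve),
    )


def filter_physiological(param_map: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop voxels outside the strict open box; return (kept, n_removed).

    Expects columns ``ktrans`` and, when the model estimates it, ``ve``.
    ``ve`` entries that are NaN (Patlak-family fits) are not screened.
    """
    if len(param_map) == 0:
        return param_map, 0
    kt = param_map["ktrans"].to_numpy(dtype=float)
    keep = (kt > PHYSIO_KTRANS[0]) & (kt < PHYSIO_KTRANS[1])
    if "ve" in param_map.columns:
        ve = param_map["ve"].to_numpy(dtype=float)
        has_ve = ~np.isnan(ve)
        keep &= ~has_ve | ((ve > PHYSIO_VE[0]) & (ve < PHYSIO_VE[1]))
    kept = param_map.loc[keep]
    return kept, int(len(param_map) - len(kept))


def aif_to_csv(aif: AifCurve, path) -> None:
    pd.DataFrame({"time_min": aif.time_min, "cp_mM": aif.cp}).to_csv(path, index=False)


def aif_from_csv(path, onset_min: float = 0.0) -> AifCurve:
    df = pd.read_csv(path)
    return AifCurve(df["time_min"].to_numpy(), df["cp_mM"].to_numpy(), onset_min)
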