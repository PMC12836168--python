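"""Point-source diffusion model, forward simulator and coefficient fitting.

Fluorescent tracer released in a well spreads into the surrounding gel. The
intensity profile along a line drawn outward from the well rim is modelled by
the 1D instantaneous point-source solution of the diffusion equation,

    I(x, t) = A0 / sqrt(4 * pi * D * t) * exp(-x**2 / (4 * D * t)),

where ``A0`` is the total amount of diffusing substance, ``D`` the diffusion
coefficient (µm²/s), ``t`` the time since injection (s) and ``x`` the
distance from the release point (µm). The solution is singular at t = 0, so
t = 0 frames are never fitted.

The well is in reality a finite disk, not a point; profiles are anchored at
the rim and ``x`` measured outward from it. This is accurate once the
diffusion length ``sqrt(4*D*t)`` is small compared with the well radius and
is the same approximation the fitting model itself makes; the mismatch at
very early times is a known validity caveat.

Fitting is a joint nonlinear least squares over the full (x, t) dataset. On
per-time-point normalized profiles (each time column divided by its value at
x = 0) the model reduces to ``exp(-x**2 / (4*D*t))`` and only ``D`` is free.
The initializer is a method-of-moments estimate from the second spatial
moment of the latest time point; the search is bounded to
D in [1e-4, 1e4] µm²/s and is deterministic.

A 2D explicit finite-difference simulator (5-point stencil, zero-flux
boundaries, time step 0.9x the stability limit) provides a forward model of
tracer spread from a well footprint across the whole chamber.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import ChamberLayout, well_mask

__all__ = [
    "TracerSpec",
    "DiffusionProfile",
    "DiffusionFit",
    "ALBUMIN_FITC",
    "DEXTRAN_RHODAMINE_B",
    "point_source_intensity",
    "model_profile",
    "simulate_chamber_diffusion",
    "extract_line_profiles",
    "normalize_profile",
    "fit_diffusion_coefficient",
]

logger = logging.getLogger(__name__)

D_BOUNDS = (1e-4, 1e4)  # µm²/s search bounds for the fitted coefficient


@dataclass(frozen=True)
class TracerSpec:
    """A fluorescent tracer: identity, size, and ground-truth transport."""

    name: str
    molecular_weight: float  # Da
    true_D: float  # µm²/s, ground truth for synthetic data
    initial_amount: float = 1.0  # A0, arbitrary intensity units

    def __post_init__(self):
        if self.true_D <= 0:
            raise ValueError("true_D must be positive")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")


# Tracer presets: the 66 kDa albumin conjugate diffuses much more slowly than
# the 10 kDa dextran; true_D values are the gel-phase coefficients these
# probes exhibit in 4 mg/ml collagen.
ALBUMIN_FITC = TracerSpec("albumin-FITC", 66_000.0, 0.6009)
DEXTRAN_RHODAMINE_B = TracerSpec("rhodamineB-dextran-10kDa", 10_000.0, 6.393)


@dataclass
class DiffusionProfile:
    """Averaged intensity vs. distance per time point.

    ``intensities`` has shape ``(len(distances), len(times))``; distances are
    µm from the well rim (starting at 0, strictly increasing), times are
    seconds since injection.
    """

    distances: np.ndarray
    times: np.ndarray
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.distances[0] != 0 or np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must start at 0 and be strictly increasing")
        if self.intensities.shape != (len(self.distances), len(self.times)):
            raise ValueError("intensities must be shaped (n_distances, n_times)")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.normalized and not np.allclose(self.intensities[0, :], 1.0):
            raise ValueError("normalized profile must have I(0, t) == 1")


@dataclass
class DiffusionFit:
    """Best-fit coefficient and diagnostics of a joint spatio-temporal fit."""

    D_hat: float  # µm²/s
    A0_hat: float | None  # None when fitted on normalized profiles
    residual_sum_of_squares: float
    n_points: int
    ill_posed: bool = False
    success: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def point_source_intensity(x, t, D: float, A0: float = 1.0):
    """1D instantaneous point-source solution I(x, t); see module docstring.

    Even in x; singular at t = 0 (rejected). Broadcasts over x and t.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive (the model is singular at t = 0)")
    x = np.asarray(x, dtype=float)
    out = A0 / np.sqrt(4.0 * math.pi * D * t) * np.exp(-(x**2) / (4.0 * D * t))
    return out if out.ndim else float(out)


def model_profile(
    distances, times, D: float, A0: float = 1.0, normalized: bool = True
) -> DiffusionProfile:
    """Noiseless model profile on a grid, optionally per-time normalized."""
    x = np.asarray(distances, dtype=float)[:, None]
    t = np.asarray(times, dtype=float)[None, :]
    intens = point_source_intensity(x, t, D, A0)
    if normalized:
        intens = intens / intens[0:1, :]
    return DiffusionProfile(
        np.asarray(distances, float), np.asarray(times, float), intens, normalized
    )


# ---------------------------------------------------------------------------
# finite-difference forward simulator
# ---------------------------------------------------------------------------


def simulate_chamber_diffusion(
    layout: ChamberLayout,
    sources: list[tuple[str, TracerSpec]],
    grid_spacing: float,
    output_times: list[float],
    dt: float | None = None,
    strict: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit FD diffusion of tracers from their well footprints.

    Each source starts as a uniform concentration (``initial_amount`` per
    grid cell) inside its well disk and zero outside, and diffuses with its
    own coefficient on a closed (zero-flux) chamber; independent sources are
    summed. Total mass is conserved and concentrations stay non-negative
    (explicit stable scheme).

    Parameters
    ----------
    grid_spacing:
        FD cell size in µm.
    output_times:
        Ascending times (s) at which fields are returned; 0 gives the initial
        condition.
    dt:
        Optional explicit time step. If it violates the stability limit
        ``grid_spacing**2 / (4 * D)`` it is refined (or rejected when
        ``strict``). Default: 0.9x the stability limit.

    Returns
    -------
    (times, fields):
        ``times`` as an array and ``fields`` shaped ``(n_times, ny, nx)``.
    """
    output_times = np.asarray(sorted(output_times), dtype=float)
    if np.any(output_times < 0):
        raise ValueError("output times must be non-negative")
    w, h = layout.chamber_extent
    nx = max(int(round(w / grid_spacing)), 3)
    ny = max(int(round(h / grid_spacing)), 3)
    # Simulate on a layout copy whose pixel size equals the grid spacing so
    # well footprints rasterize consistently.
    glayout = ChamberLayout(
        layout.center_well_position,
        layout.outer_well_positions,
        layout.well_radius,
        layout.edge_to_edge_spacing,
        layout.chamber_extent,
        pixel_size=grid_spacing,
        orientation_deg=layout.orientation_deg,
    )
    total = np.zeros((len(output_times), ny, nx), dtype=float)
    for well_id, tracer in sources:
        init = well_mask(glayout, (ny, nx), well_id).astype(float)
        init *= tracer.initial_amount
        total += _fd_evolve(init, tracer.true_D, grid_spacing, output_times, dt, strict)
    return output_times, total


def _fd_evolve(field, D, h, output_times, dt, strict):
    limit = h * h / (4.0 * D)
    if dt is None:
        dt = 0.9 * limit
    elif dt > limit:
        if strict:
            raise ValueError(
                f"requested dt={dt} exceeds the explicit stability limit {limit:.4g}"
            )
        logger.warning("dt=%g unstable; refined to %g", dt, 0.9 * limit)
        dt = 0.9 * limit
    c = field.copy()
    out = np.empty((len(output_times),) + field.shape)
    t = 0.0
    for i, t_out in enumerate(output_times):
        while t < t_out - 1e-12:
            step = min(dt, t_out - t)
            c = c + (D * step / (h * h)) * _laplacian_reflecting(c)
            t += step
        out[i] = c
    return out


def _laplacian_reflecting(c: np.ndarray) -> np.ndarray:
    """Discrete 5-point Laplacian (times h²) with zero-flux boundaries."""
    p = np.pad(c, 1, mode="edge")
    return p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * c


# ---------------------------------------------------------------------------
# line-profile extraction
# ---------------------------------------------------------------------------


def extract_line_profiles(
    stack,
    layout: ChamberLayout,
    well: str,
    length_um: float = 500.0,
    strict: bool = False,
) -> DiffusionProfile:
    """Average of four rim-anchored line profiles (N, S, E, W) per frame.

    Four profiles of ``length_um`` start at the rim-adjacent first gel pixel
    along the +x, -x, +y and -y axes and are sampled once per pixel; the four
    are averaged pointwise, giving one intensity-vs-distance curve per time
    point. Profiles that would exit the raster are truncated (all four arms
    are kept at a common length) unless ``strict``.
    """
    frames = np.asarray(stack.frames, dtype=float)
    ps = stack.pixel_size
    n_frames, height, width = frames.shape
    row_f, col_f = layout.well_center_px(well)
    row0, col0 = int(round(row_f)), int(round(col_f))
    r_px = layout.well_radius_px
    n = int(length_um // ps) + 1

    # first gel pixel index along each arm (center strictly outside the disk)
    east0 = int(math.floor(col_f + r_px)) + 1
    west0 = int(math.ceil(col_f - r_px)) - 1
    south0 = int(math.floor(row_f + r_px)) + 1
    north0 = int(math.ceil(row_f - r_px)) - 1

    avail = min(width - east0, west0 + 1, height - south0, north0 + 1)
    if avail < n:
        if strict:
            raise ValueError(
                f"profile of {n} px exits the raster (only {avail} px available)"
            )
        logger.warning("profile truncated from %d to %d samples", n, avail)
        n = avail
    if n < 1:
        raise ValueError("no gel pixels available outside the well")

    k = np.arange(n)
    arms = np.stack(
        [
            frames[:, row0, east0 + k],
            frames[:, row0, west0 - k],
            frames[:, south0 + k, col0],
            frames[:, north0 - k, col0],
        ]
    )  # (4, n_frames, n)
    intens = arms.mean(axis=0).T  # (n, n_frames)
    return DiffusionProfile(
        distances=k * ps,
        times=np.asarray(stack.timestamps, dtype=float),
        intensities=np.clip(intens, 0.0, None),
        normalized=False,
    )


def normalize_profile(profile: DiffusionProfile) -> DiffusionProfile:
    """Divide each time column by its x = 0 intensity (idempotent).

    Time points with I(0, t) == 0 are dropped with a warning.
    """
    i0 = profile.intensities[0, :]
    keep = i0 > 0
    if not keep.all():
        logger.warning(
            "dropping %d time point(s) with zero rim intensity", int((~keep).sum())
        )
    intens = profile.intensities[:, keep] / i0[keep][None, :]
    return DiffusionProfile(
        profile.distances, profile.times[keep], intens, normalized=True
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _moment_initializer(x, t, intens) -> float:
    """Method-of-moments D from the second spatial moment at the latest time."""
    w = np.clip(intens[:, -1], 0.0, None)
    if w.sum() <= 0:
        return 1.0
    m2 = float((w * x**2).sum() / w.sum())
    d0 = m2 / (2.0 * t[-1])
    return float(np.clip(d0, 1e-3, 1e3))


def fit_diffusion_coefficient(
    profile: DiffusionProfile,
    times_used=None,
    fit_A0: bool | None = None,
) -> DiffusionFit:
    """Joint least-squares fit of the point-source model over all (x, t).

    t = 0 (and any non-positive) time points are excluded. On normalized
    profiles only D is fitted against ``exp(-x**2/(4*D*t))``; otherwise A0 is
    fitted too (``fit_A0`` overrides the default). The optimizer works in
    log-parameters with bounds, a fixed moment-based initializer, and no
    randomness, so the fit is deterministic.
    """
    if fit_A0 is None:
        fit_A0 = not profile.normalized
    tmask = profile.times > 0
    if times_used is not None:
        tmask &= np.isin(profile.times, np.asarray(times_used, dtype=float))
    t = profile.times[tmask]
    intens = profile.intensities[:, tmask]
    x = profile.distances
    if len(t) < 2:
        raise ValueError("need at least 2 positive time points")
    if len(x) < 5:
        raise ValueError("need at least 5 distances")

    if float(np.ptp(intens)) < 1e-12:
        return DiffusionFit(
            D_hat=float("nan"),
            A0_hat=None,
            residual_sum_of_squares=0.0,
            n_points=intens.size,
            ill_posed=True,
            success=False,
            message="flat profile: D is unidentifiable",
        )

    xg = x[:, None]
    tg = t[None, :]
    d0 = _moment_initializer(x, t, intens)
    lb, ub = np.log(D_BOUNDS[0]), np.log(D_BOUNDS[1])

    if fit_A0:
        a0_0 = float(intens.max() * math.sqrt(4.0 * math.pi * d0 * t.min()))
        a0_0 = max(a0_0, 1e-12)

        def resid(p):
            d, a0 = np.exp(p)
            model = a0 / np.sqrt(4.0 * math.pi * d * tg) * np.exp(
                -(xg**2) / (4.0 * d * tg)
            )
            return (model - intens).ravel()

        res = least_squares(
            resid,
            x0=[math.log(d0), math.log(a0_0)],
            bounds=([lb, -50.0], [ub, 50.0 + math.log(a0_0 + 1.0)]),
        )
        d_hat, a0_hat = (float(v) for v in np.exp(res.x))
    else:
        if not profile.normalized:
            base = intens[0:1, :]
            if np.any(base <= 0):
                raise ValueError("cannot fit normalized model: I(0, t) == 0")
            intens = intens / base

        def resid(p):
            d = math.exp(p[0])
            model = np.exp(-(xg**2) / (4.0 * d * tg))
            return (model - intens).ravel()

        res = least_squares(resid, x0=[math.log(d0)], bounds=([lb], [ub]))
        d_hat, a0_hat = float(math.exp(res.x[0])), None

    return DiffusionFit(
        D_hat=d_hat,
        A0_hat=a0_hat,
        residual_sum_of_squares=float(2.0 * res.cost),
        n_points=intens.size,
        success=bool(res.success),
        message=res.message if not res.success else "",
    )
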