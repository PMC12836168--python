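"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the assay's raw data:

* **tracer stacks** — frames of a fluorescent tracer spreading from a well,
  either rendered from the analytic point-source solution (default; anchored
  at the same rim pixel the line-profile extractor uses, so noiseless stacks
  refit exactly) or from the finite-difference chamber simulator;
* **migration movies** — an agent-based biased persistent random walk:
  agents start on their well's rim and, at each imaging interval, draw a new
  heading from a von Mises distribution centered on the weighted circular
  mean of their previous heading (weight = persistence) and the attractant
  gradient direction (weight = chemotactic bias x normalized gradient
  magnitude), then step a fixed distance; frames render agents as
  anti-aliased dark disks on a light background together with exact
  ground-truth masks;
* **confluency images** — random ellipses ("cells": darker, strongly
  textured) composited onto a shaded, lightly noisy bright background until
  a target covered-area fraction is reached, returned with the exact boolean
  truth mask.

The attractant field is quasi-static: a single snapshot of the 2D
point-source solution at a reference time (default 24 h), evaluated
analytically. This is the generator's own motion model — a testbed for the
quantification pipeline, not a biophysically calibrated cell model.

All randomness flows from explicit seeds; rendering given trajectories is
seed-free and deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import imaging, migration_quant
from .diffusion import TracerSpec, point_source_intensity, simulate_chamber_diffusion
from .geometry import ChamberLayout, GeometryError, build_layout

__all__ = [
    "AgentParams",
    "CellTypeProfile",
    "Appearance",
    "AttractantField",
    "pixel_aligned_layout",
    "generate_tracer_stack",
    "simulate_migration",
    "render_migration_frames",
    "generate_confluency_image",
    "train_confluency_classifier",
    "simulate_well_assay",
    "directional_detection_experiment",
]

logger = logging.getLogger(__name__)

# Imaging cadence: one frame every 30 minutes for 3 days.
FRAME_INTERVAL_S = 1800.0
ASSAY_DURATION_S = 3 * 24 * 3600.0
# Cells seeded per well in the reference assay.
DEFAULT_CELLS_PER_WELL = 1e4


@dataclass(frozen=True)
class AgentParams:
    """Motion parameters of one synthetic cell type.

    speed is µm per step (one step per imaging interval); persistence in
    [0, 1) weights the previous heading; chemotactic_bias (kappa >= 0) scales
    alignment to the attractant gradient; heading_noise_kappa is the von
    Mises concentration of the per-step heading noise.
    """

    speed: float = 10.0
    persistence: float = 0.6
    chemotactic_bias: float = 0.0
    step_interval: float = FRAME_INTERVAL_S
    n_agents: int = 100
    motile: bool = True
    heading_noise_kappa: float = 4.0

    def __post_init__(self):
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.chemotactic_bias < 0:
            raise ValueError("chemotactic_bias must be >= 0")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must lie in [0, 1)")


@dataclass(frozen=True)
class CellTypeProfile:
    """A named cell population: motion parameters plus seeding/rendering."""

    name: str
    params: AgentParams
    seeded_well: str
    rendered_radius: float = 30.0  # µm blob radius in rendered frames
    density: float = DEFAULT_CELLS_PER_WELL

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class Appearance:
    """Rendering of agents: light background, darker cell disks."""

    background: float = 200.0
    cell_intensity: float = 60.0


# ---------------------------------------------------------------------------
# layout helper
# ---------------------------------------------------------------------------


def pixel_aligned_layout(layout: ChamberLayout) -> ChamberLayout:
    """Snap well centers to pixel centers and the radius to whole pixels.

    Synthetic tracer stacks use aligned layouts so the analytic rendering
    anchor coincides exactly with the line-profile extraction anchor on all
    four arms; the sub-micrometre shifts are irrelevant to migration assays.
    """
    ps = layout.pixel_size

    def snap(p):
        return (
            (round(p[0] / ps - 0.5) + 0.5) * ps,
            (round(p[1] / ps - 0.5) + 0.5) * ps,
        )

    center = snap(layout.center_well_position)
    outer = tuple(snap(p) for p in layout.outer_well_positions)
    r = max(round(layout.well_radius / ps), 1) * ps
    spacing = math.dist(center, outer[0]) - 2.0 * r
    return ChamberLayout(
        center,
        outer,
        r,
        spacing,
        layout.chamber_extent,
        pixel_size=ps,
        orientation_deg=layout.orientation_deg,
    )


# ---------------------------------------------------------------------------
# tracer stacks
# ---------------------------------------------------------------------------


def generate_tracer_stack(
    layout: ChamberLayout,
    tracer: TracerSpec,
    times,
    noise_sigma: float = 0.0,
    seed: int = 0,
    source_well: str = "center",
    mode: str = "analytic",
    grid_spacing: float | None = None,
) -> imaging.ImageStack:
    """Frames of tracer fluorescence at the requested times since injection.

    ``mode="analytic"`` (default) renders the point-source solution radially,
    with x = 0 anchored at the rim-adjacent first gel pixel — the same anchor
    the profile extractor uses — so noiseless stacks refit to the true D
    essentially exactly. ``mode="fd"`` instead samples the finite-difference
    chamber simulation (a finite disk source, which deviates from the
    point-source model near the rim at early times). The t = 0 frame shows
    the initial condition (tracer confined to the well).

    Multiplicative Gaussian noise of relative sigma ``noise_sigma`` is
    applied per pixel; frames are float32 and the ground-truth coefficient is
    recorded in the stack metadata.
    """
    times = np.asarray(sorted(times), dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    ps = layout.pixel_size
    w, h = layout.chamber_extent
    shape = (int(round(h / ps)), int(round(w / ps)))

    if mode == "analytic":
        cx, cy = layout.well_position(source_well)
        r_px = layout.well_radius_px
        col_f = cx / ps - 0.5
        anchor = ((math.floor(col_f + r_px) + 1) + 0.5) * ps - cx
        yy = (np.arange(shape[0]) + 0.5) * ps
        xx = (np.arange(shape[1]) + 0.5) * ps
        rho = np.hypot(xx[None, :] - cx, yy[:, None] - cy)
        x_eff = np.clip(rho - anchor, 0.0, None)
        frames = np.empty((len(times),) + shape, dtype=float)
        for i, t in enumerate(times):
            if t <= 0:
                frames[i] = np.where(rho <= layout.well_radius, tracer.initial_amount, 0.0)
            else:
                frames[i] = point_source_intensity(x_eff, t, tracer.true_D, tracer.initial_amount)
    elif mode == "fd":
        gs = grid_spacing if grid_spacing is not None else ps
        _, fields = simulate_chamber_diffusion(
            layout, [(source_well, tracer)], gs, list(times)
        )
        frames = fields
        shape = frames.shape[1:]
    else:
        raise ValueError("mode must be 'analytic' or 'fd'")

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames = frames * (1.0 + noise_sigma * rng.standard_normal(frames.shape))
        frames = np.clip(frames, 0.0, None)
    return imaging.ImageStack(
        frames.astype(np.float32),
        times,
        ps,
        bit_depth=16,
        metadata={
            "tracer": tracer.name,
            "true_D_um2_s": tracer.true_D,
            "A0": tracer.initial_amount,
            "source_well": source_well,
            "mode": mode,
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# attractant field
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttractantField:
    """Quasi-static 2D point-source attractant snapshot at a reference time.

    C(rho) = A / (4*pi*D*t_ref) * exp(-rho^2 / (4*D*t_ref)); the gradient
    points toward the source with magnitude C * rho / (2*D*t_ref). Gradient
    magnitudes are exposed normalized by the field's global maximum so the
    chemotactic weight kappa is scale-free.
    """

    source_xy: tuple[float, float]
    D: float = 100.0  # µm²/s, a small soluble attractant in gel
    t_ref: float = 86400.0  # 24 h snapshot
    amount: float = 1.0

    @property
    def _four_dt(self) -> float:
        return 4.0 * self.D * self.t_ref

    def gradient(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(unit directions toward source, normalized magnitudes) at positions."""
        delta = np.asarray(self.source_xy, dtype=float) - pos
        rho = np.linalg.norm(delta, axis=-1)
        c = self.amount / (math.pi * self._four_dt) * np.exp(-(rho**2) / self._four_dt)
        mag = c * rho / (2.0 * self.D * self.t_ref)
        # max of rho*exp(-rho^2/4Dt) at rho* = sqrt(2 D t_ref)
        rho_star = math.sqrt(2.0 * self.D * self.t_ref)
        gmax = (
            self.amount
            / (math.pi * self._four_dt)
            * rho_star
            * math.exp(-0.5)
            / (2.0 * self.D * self.t_ref)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(rho[..., None] > 0, delta / rho[..., None], 0.0)
        return unit, mag / gmax


# ---------------------------------------------------------------------------
# agent-based migration
# ---------------------------------------------------------------------------


def simulate_migration(
    layout: ChamberLayout,
    cell_types: list[CellTypeProfile],
    attractant_source: str = "center",
    attractant_D: float = 100.0,
    duration: float = ASSAY_DURATION_S,
    seed=0,
    t_ref: float = 86400.0,
) -> dict[str, np.ndarray]:
    """Biased persistent random walk trajectories per cell type.

    Agents start uniformly on their seeded well's rim. Non-motile types never
    move. Chamber boundaries reflect. Returns, per type name, an array of
    positions shaped ``(n_steps + 1, n_agents, 2)`` in µm (x, y).
    """
    fld = AttractantField(layout.well_position(attractant_source), attractant_D, t_ref)
    w, h = layout.chamber_extent
    out: dict[str, np.ndarray] = {}
    for ti, ct in enumerate(cell_types):
        p = ct.params
        if duration < p.step_interval:
            raise ValueError("duration must cover at least one step interval")
        n_steps = int(round(duration / p.step_interval))
        rng = np.random.default_rng(np.random.SeedSequence([_as_int(seed), ti]))
        wx, wy = layout.well_position(ct.seeded_well)
        if not (0 <= wx <= w and 0 <= wy <= h):
            raise GeometryError(f"well {ct.seeded_well!r} lies outside the chamber")
        phi = rng.uniform(0.0, 2.0 * math.pi, p.n_agents)
        pos = np.stack(
            [wx + layout.well_radius * np.cos(phi), wy + layout.well_radius * np.sin(phi)],
            axis=1,
        )
        traj = np.empty((n_steps + 1, p.n_agents, 2))
        traj[0] = pos
        if not p.motile or p.speed == 0.0:
            traj[1:] = pos[None]
            out[ct.name] = traj
            continue
        theta = phi.copy()  # initial headings: radially outward
        for step in range(1, n_steps + 1):
            unit, gnorm = fld.gradient(pos)
            vx = p.persistence * np.cos(theta) + p.chemotactic_bias * gnorm * unit[:, 0]
            vy = p.persistence * np.sin(theta) + p.chemotactic_bias * gnorm * unit[:, 1]
            small = np.hypot(vx, vy) < 1e-12
            target = np.where(small, theta, np.arctan2(vy, vx))
            theta = rng.vonmises(target, p.heading_noise_kappa)
            pos = pos + p.speed * np.stack([np.cos(theta), np.sin(theta)], axis=1)
            # reflecting chamber boundaries
            for dim, hi in ((0, w), (1, h)):
                low = pos[:, dim] < 0
                high = pos[:, dim] > hi
                pos[low, dim] = -pos[low, dim]
                pos[high, dim] = 2 * hi - pos[high, dim]
                if low.any() or high.any():
                    flip = low | high
                    if dim == 0:
                        theta[flip] = math.pi - theta[flip]
                    else:
                        theta[flip] = -theta[flip]
            traj[step] = pos
        out[ct.name] = traj
    return out


def _as_int(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return int(np.random.SeedSequence(seed).generate_state(1)[0])


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_migration_frames(
    trajectories: np.ndarray,
    layout: ChamberLayout,
    frame_shape: tuple[int, int],
    time_indices=None,
    appearance: Appearance = Appearance(),
    blob_radius_um: float = 30.0,
    origin_px: tuple[int, int] = (0, 0),
    timestamps=None,
) -> tuple[imaging.ImageStack, np.ndarray]:
    """Render agent positions as anti-aliased dark disks on a light background.

    ``trajectories`` is ``(n_steps+1, n_agents, 2)`` µm positions (one cell
    type; render repeatedly and composite for several). ``origin_px``
    offsets the raster so sub-regions (crops) can be rendered directly.
    Rendering is deterministic given trajectories (no randomness). Returns
    the stack and the exact per-frame boolean ground-truth masks.
    """
    traj = np.asarray(trajectories, dtype=float)
    if time_indices is None:
        time_indices = range(len(traj))
    time_indices = [int(i) for i in time_indices]
    ps = layout.pixel_size
    r_px = blob_radius_um / ps
    h, w = frame_shape
    frames = np.empty((len(time_indices), h, w), dtype=float)
    truths = np.zeros((len(time_indices), h, w), dtype=bool)
    n_clipped = 0
    for fi, idx in enumerate(time_indices):
        coverage = np.zeros((h, w))
        truth = np.zeros((h, w), dtype=bool)
        for x, y in traj[idx]:
            row = y / ps - 0.5 - origin_px[0]
            col = x / ps - 0.5 - origin_px[1]
            lo_r = int(math.floor(row - r_px - 1))
            hi_r = int(math.ceil(row + r_px + 1)) + 1
            lo_c = int(math.floor(col - r_px - 1))
            hi_c = int(math.ceil(col + r_px + 1)) + 1
            if hi_r <= 0 or hi_c <= 0 or lo_r >= h or lo_c >= w:
                n_clipped += 1
                continue
            if lo_r < 0 or lo_c < 0 or hi_r > h or hi_c > w:
                n_clipped += 1
            lo_r, lo_c = max(lo_r, 0), max(lo_c, 0)
            hi_r, hi_c = min(hi_r, h), min(hi_c, w)
            rr = np.arange(lo_r, hi_r)[:, None] - row
            cc = np.arange(lo_c, hi_c)[None, :] - col
            dist = np.hypot(rr, cc)
            patch = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
            sl = (slice(lo_r, hi_r), slice(lo_c, hi_c))
            coverage[sl] = np.maximum(coverage[sl], patch)
            truth[sl] |= dist < r_px
        frames[fi] = appearance.background - (
            appearance.background - appearance.cell_intensity
        ) * coverage
        truths[fi] = truth
    if n_clipped:
        logger.info("%d blob(s) clipped at the frame edge", n_clipped)
    if timestamps is None:
        timestamps = [i * FRAME_INTERVAL_S for i in time_indices]
    stack = imaging.ImageStack(
        frames,
        np.asarray(timestamps, dtype=float),
        ps,
        bit_depth=8,
        metadata={"blob_radius_um": blob_radius_um, "origin_px": list(origin_px)},
    )
    return stack, truths


# ---------------------------------------------------------------------------
# confluency images
# ---------------------------------------------------------------------------


def generate_confluency_image(
    shape: tuple[int, int] = (1496, 1495),
    target_fraction: float = 0.5,
    cell_radius_range: tuple[float, float] = (10.0, 25.0),
    seed: int = 0,
    background: float = 205.0,
    cell_level: float = 120.0,
    shading_amplitude: float = 12.0,
    background_noise: float = 3.0,
    cell_texture: float = 25.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic brightfield confluency image plus its exact truth mask.

    Random ellipses (semi-axes drawn from ``cell_radius_range``; the default
    10-25 px corresponds to spread cells of ~20-50 µm at the ~1 µm/px scale
    of the full-well brightfield images) are added until their union covers
    ``target_fraction`` of the frame; each ellipse adds at most ~0.1
    percentage points at the default sizes, so the truth fraction lands
    within ±0.5 points of the target. Cells are darker than
    the background and carry strong pixel-scale texture; the background has
    smooth shading and mild noise. Returns ``(uint8 image, bool mask)``.
    """
    if not (0.0 <= target_fraction <= 0.99):
        raise ValueError(
            "target_fraction must lie in [0, 0.99]; higher coverage is not "
            "reachable with random ellipse packing"
        )
    rng = np.random.default_rng(seed)
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    total_px = h * w
    covered = 0
    a_lo, a_hi = cell_radius_range
    max_iter = int(60 * total_px / (math.pi * a_lo * a_hi)) + 1000
    it = 0
    while covered / total_px < target_fraction:
        if it >= max_iter:
            raise ValueError(
                f"target fraction {target_fraction} unreachable; achieved "
                f"{covered / total_px:.4f}"
            )
        it += 1
        r0 = rng.uniform(0, h)
        c0 = rng.uniform(0, w)
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(a_lo, a_hi)
        ang = rng.uniform(0, math.pi)
        m = max(a, b) + 1.0
        lo_r, hi_r = int(max(r0 - m, 0)), int(min(r0 + m + 1, h))
        lo_c, hi_c = int(max(c0 - m, 0)), int(min(c0 + m + 1, w))
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        dr = np.arange(lo_r, hi_r)[:, None] - r0
        dc = np.arange(lo_c, hi_c)[None, :] - c0
        u = (dc * math.cos(ang) + dr * math.sin(ang)) / a
        v = (-dc * math.sin(ang) + dr * math.cos(ang)) / b
        patch = u * u + v * v <= 1.0
        sl = (slice(lo_r, hi_r), slice(lo_c, hi_c))
        before = int(mask[sl].sum())
        mask[sl] |= patch
        covered += int(mask[sl].sum()) - before

    # composite: shaded light background, dark textured cells
    rows = np.linspace(-1, 1, h)[:, None]
    cols = np.linspace(-1, 1, w)[None, :]
    shading = shading_amplitude * (
        0.5 * rows + 0.3 * cols + 0.2 * np.sin(2.0 * math.pi * cols)
    )
    img = background + shading + background_noise * rng.standard_normal(shape)
    cell_px = int(mask.sum())
    if cell_px:
        img[mask] = (
            cell_level + shading[mask] + cell_texture * rng.standard_normal(cell_px)
        )
    return np.clip(img, 0, 255).astype(np.uint8), mask


def train_confluency_classifier(
    seed: int = 0,
    params: imaging.SegmentationParams | None = None,
    shape: tuple[int, int] = (256, 256),
    targets: tuple[float, ...] = (0.35, 0.7),
) -> imaging.PixelClassifier:
    """Train the stand-in pixel classifier on labelled synthetic fixtures.

    Fixtures are generated with :func:`generate_confluency_image` and pushed
    through the same preprocessing front end used at prediction time.
    """
    if params is None:
        params = imaging.SegmentationParams()
    images, masks = [], []
    for i, t in enumerate(targets):
        img, truth = generate_confluency_image(shape, t, seed=seed * 1000 + i)
        images.append(migration_quant.preprocess_brightfield(img, params))
        masks.append(truth)
    return imaging.PixelClassifier().fit(images, masks, seed=seed)


# ---------------------------------------------------------------------------
# end-to-end directional-detection experiment
# ---------------------------------------------------------------------------


def simulate_well_assay(
    layout: ChamberLayout,
    well: str = "outer0",
    kappa: float = 2.0,
    seed=0,
    n_agents: int = 80,
    speed: float = 10.0,
    duration: float = ASSAY_DURATION_S,
    crop_side: int = 300,
    appearance: Appearance = Appearance(),
    use_truth_mask: bool = False,
    classifier=None,
) -> float:
    """One synthetic well, quantified end to end; returns the terminal bias.

    Simulates agents seeded on the well rim with chemotactic bias ``kappa``
    toward the central well, renders the terminal frame of the crop, segments
    it (rule-based probability map thresholded at 0.5, or the exact truth
    mask when ``use_truth_mask``) and computes the directional bias index
    toward the center-facing quadrants.
    """
    params = AgentParams(speed=speed, chemotactic_bias=kappa, n_agents=n_agents)
    ct = CellTypeProfile("cells", params, well)
    traj = simulate_migration(layout, [ct], duration=duration, seed=seed)["cells"]
    center_rc = layout.well_center_px(well)
    origin = (
        int(round(center_rc[0] - (crop_side - 1) / 2.0)),
        int(round(center_rc[1] - (crop_side - 1) / 2.0)),
    )
    stack, truths = render_migration_frames(
        traj,
        layout,
        (crop_side, crop_side),
        time_indices=[len(traj) - 1],
        appearance=appearance,
        origin_px=origin,
    )
    if use_truth_mask:
        mask = truths[0]
    else:
        if classifier is None:
            classifier = imaging.RuleBasedClassifier(
                appearance.background, appearance.cell_intensity
            )
        prob = classifier.predict_map(stack.frames[0])
        mask = imaging.binarize(prob, 0.5)
    qa = migration_quant.quadrant_migration_areas(mask, 1.05 * layout.well_radius_px)
    facing = migration_quant.facing_quadrants(layout, well)
    return migration_quant.directional_bias_index(qa, facing)


def directional_detection_experiment(
    n_runs: int = 20,
    seed: int = 1,
    kappa: float = 2.0,
    n_wells: int = 5,
    null: bool = False,
    use_truth_mask: bool = False,
    n_agents: int = 80,
    layout: ChamberLayout | None = None,
) -> dict:
    """Replicated biased-vs-control comparisons with a permutation test.

    Each run simulates ``n_wells`` wells whose agents carry chemotactic bias
    ``kappa`` (or 0 when ``null``: a type-I calibration) and ``n_wells``
    unbiased control wells, then tests the difference in mean terminal bias
    with a one-sided exact permutation test. Returns the per-run p-values
    and the fraction rejected at alpha = 0.05.
    """
    if layout is None:
        layout = pixel_aligned_layout(
            build_layout(1630.0, 1460.0, (10650.0, 9400.0), pixel_size=10.0)
        )
    kappa_a = 0.0 if null else kappa
    p_values = []
    for run in range(n_runs):
        biased = [
            simulate_well_assay(
                layout,
                kappa=kappa_a,
                seed=[seed, run, 0, wi],
                n_agents=n_agents,
                use_truth_mask=use_truth_mask,
            )
            for wi in range(n_wells)
        ]
        control = [
            simulate_well_assay(
                layout,
                kappa=0.0,
                seed=[seed, run, 1, wi],
                n_agents=n_agents,
                use_truth_mask=use_truth_mask,
            )
            for wi in range(n_wells)
        ]
        res = migration_quant.permutation_null(
            biased, control, seed=seed, alternative="greater"
        )
        p_values.append(res.p_value)
    p = np.asarray(p_values)
    return {
        "p_values": p_values,
        "rejection_rate": float((p < 0.05).mean()),
        "n_runs": n_runs,
        "kappa": kappa_a,
        "n_wells_per_arm": n_wells,
    }
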