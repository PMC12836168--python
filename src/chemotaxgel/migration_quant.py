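"""Quadrant-based quantification of directional cell migration.

Each outer (stromal) well is analyzed in a square crop centered on the well.
A central disk (by default 1.05x the well radius, so the well body and its
rim-attached cells are ignored) is excluded, and the remaining annulus is
split into the four intercardinal quadrants NW/NE/SW/SE. Per frame, the
segmented migrating-cell area in each quadrant is expressed as a fraction of
the analyzable (non-excluded) crop area, so the exclusion radius does not
silently rescale comparisons across wells.

Directionality is summarized by a bias index in [-1, 1]: the share of
migrated area found in the quadrants *facing* the central well, rescaled so
that a uniform spread scores 0, all area in the facing quadrants scores +1
and none scores -1. Conditions are compared by a label-permutation test on
replicate wells' terminal bias (exact enumeration when feasible); classical
ANOVA-style testing is deliberately left to standard statistical packages.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imaging
from .geometry import QUADRANTS, ChamberLayout, GeometryError, quadrant_masks

__all__ = [
    "QuadrantAreas",
    "MigrationResult",
    "PermutationTest",
    "crop_centered",
    "crop_to_well",
    "quadrant_migration_areas",
    "facing_quadrants",
    "directional_bias_index",
    "migration_time_series",
    "permutation_null",
    "confluency",
    "preprocess_brightfield",
    "spider_chart_export",
]

logger = logging.getLogger(__name__)

# Quadrant bisector directions as (x, y) unit vectors, image convention
# (y grows downward, so "N" is -y).
_BISECTORS = {
    "NW": (-math.sqrt(0.5), -math.sqrt(0.5)),
    "NE": (math.sqrt(0.5), -math.sqrt(0.5)),
    "SW": (-math.sqrt(0.5), math.sqrt(0.5)),
    "SE": (math.sqrt(0.5), math.sqrt(0.5)),
}


@dataclass
class QuadrantAreas:
    """Per-quadrant migrated-area fractions for one frame.

    ``fractions[q]`` is foreground pixels in quadrant q divided by the total
    analyzable (non-excluded) pixel count; the four therefore sum to
    ``total_fraction``. ``quadrant_px`` stores each quadrant's analyzable
    pixel count so expectation shares can be computed exactly.
    """

    frame_index: int
    time: float
    fractions: dict[str, float]
    total_fraction: float
    quadrant_px: dict[str, int]

    def __post_init__(self):
        s = sum(self.fractions.values())
        if abs(s - self.total_fraction) > 1e-12:
            raise ValueError("quadrant fractions must sum to total_fraction")


@dataclass
class MigrationResult:
    """Time series of quadrant areas for one well plus its bias trajectory."""

    series: list[QuadrantAreas]
    condition: str = ""
    well: str = ""
    facing: frozenset = frozenset()
    bias_index: list[float] = field(default_factory=list)

    @property
    def terminal_bias(self) -> float:
        return self.bias_index[-1] if self.bias_index else float("nan")


@dataclass
class PermutationTest:
    p_value: float
    observed: float
    n_arrangements: int
    exact: bool
    alternative: str


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------


def crop_centered(frame: np.ndarray, center_rc: tuple[float, float], side: int):
    """Square crop of ``side`` px centered (within 0.5 px) on ``center_rc``."""
    r0 = int(round(center_rc[0] - (side - 1) / 2.0))
    c0 = int(round(center_rc[1] - (side - 1) / 2.0))
    if r0 < 0 or c0 < 0 or r0 + side > frame.shape[0] or c0 + side > frame.shape[1]:
        raise GeometryError("crop exceeds the frame")
    return frame[r0 : r0 + side, c0 : c0 + side]


def crop_to_well(
    frame: np.ndarray, layout: ChamberLayout, well: str, side: int
) -> np.ndarray:
    """1:1 crop of ``side`` px centered on the given well."""
    return crop_centered(frame, layout.well_center_px(well), side)


# ---------------------------------------------------------------------------
# quadrant areas and bias
# ---------------------------------------------------------------------------


def quadrant_migration_areas(
    binary_mask: np.ndarray,
    exclusion_radius: float,
    frame_index: int = 0,
    time: float = 0.0,
) -> QuadrantAreas:
    """Per-quadrant area fractions of a square foreground mask.

    ``exclusion_radius`` is in pixels; the denominator is the analyzable
    area (crop minus the excluded central disk), shared by all quadrants.
    """
    mask = np.asarray(binary_mask, dtype=bool)
    qmasks = quadrant_masks(mask.shape, exclusion_radius)
    analyzable = int(sum(m.sum() for m in qmasks.values()))
    fractions = {
        q: float((mask & qm).sum()) / analyzable for q, qm in qmasks.items()
    }
    return QuadrantAreas(
        frame_index=frame_index,
        time=time,
        fractions=fractions,
        total_fraction=sum(fractions.values()),
        quadrant_px={q: int(qm.sum()) for q, qm in qmasks.items()},
    )


def facing_quadrants(layout: ChamberLayout, well: str) -> frozenset:
    """The two quadrants of an outer well's crop that face the central well.

    Chosen as the two quadrants whose bisectors are nearest the bearing from
    the well to the chamber center, so the statistic adapts to any chamber
    orientation instead of hard-coding particular quadrants.
    """
    if well == "center":
        raise GeometryError("facing quadrants are defined for outer wells only")
    wx, wy = layout.well_position(well)
    cx, cy = layout.center_well_position
    v = np.array([cx - wx, cy - wy], dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise GeometryError("well coincides with the chamber center")
    v /= norm
    scores = {q: float(v @ np.array(b)) for q, b in _BISECTORS.items()}
    best = sorted(QUADRANTS, key=lambda q: (-scores[q], QUADRANTS.index(q)))
    return frozenset(best[:2])


def directional_bias_index(areas: QuadrantAreas, facing) -> float:
    """Bias of migrated area toward the facing quadrants, in [-1, 1].

    With s the share of migrated area in the facing quadrants and q their
    share of analyzable area (the uniform-spread expectation), the index is
    ``(s - q) / (1 - q)`` for s >= q and ``(s - q) / q`` otherwise: 0 under
    uniform spread, +1 when all area is facing, -1 when none is. NaN (a
    flagged missing value) when no area migrated at all.
    """
    facing = frozenset(facing)
    if not facing or not facing < set(QUADRANTS):
        raise ValueError("facing must be a non-empty proper subset of the quadrants")
    total = areas.total_fraction
    if total <= 0:
        return float("nan")
    total_px = sum(areas.quadrant_px.values())
    q = sum(areas.quadrant_px[f] for f in facing) / total_px
    s = sum(areas.fractions[f] for f in facing) / total
    if s >= q:
        return float((s - q) / (1.0 - q))
    return float((s - q) / q)


# ---------------------------------------------------------------------------
# end-to-end series
# ---------------------------------------------------------------------------


def migration_time_series(
    stack: imaging.ImageStack,
    layout: ChamberLayout,
    well: str,
    params: imaging.SegmentationParams,
    side: int,
    exclusion_radius: float | None = None,
    condition: str = "",
) -> MigrationResult:
    """Crop -> probability map -> binarize -> quadrant areas, per frame.

    ``exclusion_radius`` (px) defaults to 1.05x the well radius. The
    segmentation uses ``params.classifier`` (its probability map is
    thresholded at ``params.probability_threshold``), matching a
    stable-background manual-threshold workflow.
    """
    if params.classifier is None:
        raise ValueError("params.classifier is required for migration segmentation")
    if exclusion_radius is None:
        exclusion_radius = 1.05 * layout.well_radius_px
    facing = facing_quadrants(layout, well)
    series: list[QuadrantAreas] = []
    bias: list[float] = []
    for i, frame in enumerate(stack.frames):
        try:
            crop = crop_to_well(frame, layout, well, side)
            prob = params.classifier.predict_map(crop)
            mask = imaging.binarize(prob, params.probability_threshold)
            qa = quadrant_migration_areas(
                mask, exclusion_radius, frame_index=i, time=float(stack.timestamps[i])
            )
        except Exception as exc:  # attach the frame index to component errors
            raise RuntimeError(f"frame {i}: {exc}") from exc
        series.append(qa)
        bias.append(directional_bias_index(qa, facing))
    return MigrationResult(
        series=series, condition=condition, well=well, facing=facing, bias_index=bias
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def _terminal_biases(group) -> np.ndarray:
    if isinstance(group, MigrationResult):
        group = [group]
    vals = []
    for g in group:
        vals.append(g.terminal_bias if isinstance(g, MigrationResult) else float(g))
    return np.asarray(vals, dtype=float)


def permutation_null(
    series_a,
    series_b,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationTest:
    """Label-permutation p-value for the difference in terminal bias index.

    ``series_a``/``series_b`` are replicate wells (lists of
    :class:`MigrationResult`, or bare bias values); a single result is
    wrapped. The statistic is ``mean(a) - mean(b)``; group labels are
    permuted, with exact enumeration whenever the number of arrangements is
    at most 10^4 and seeded Monte Carlo otherwise. NaN biases (wells with no
    migrated area) are treated as zero bias and flagged with a warning.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    a = _terminal_biases(series_a)
    b = _terminal_biases(series_b)
    if np.isnan(a).any() or np.isnan(b).any():
        warnings.warn("NaN terminal bias (no migrated area) treated as 0")
        a = np.nan_to_num(a)
        b = np.nan_to_num(b)
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    obs = float(a.mean() - b.mean())

    def stat(idx_a: np.ndarray) -> float:
        sel = np.zeros(n, dtype=bool)
        sel[list(idx_a)] = True
        return float(pooled[sel].mean() - pooled[~sel].mean())

    n_arr = math.comb(n, na)
    eps = 1e-12
    if alternative == "two-sided":
        extreme = lambda s: abs(s) >= abs(obs) - eps  # noqa: E731
    elif alternative == "greater":
        extreme = lambda s: s >= obs - eps  # noqa: E731
    elif alternative == "less":
        extreme = lambda s: s <= obs + eps  # noqa: E731
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")

    if n_arr <= 10_000:
        hits = sum(
            extreme(stat(np.array(comb)))
            for comb in itertools.combinations(range(n), na)
        )
        return PermutationTest(hits / n_arr, obs, n_arr, True, alternative)
    rng = np.random.default_rng(seed)
    hits = 1  # the identity arrangement
    for _ in range(n_perm):
        perm = rng.permutation(n)[:na]
        if extreme(stat(perm)):
            hits += 1
    return PermutationTest(hits / (n_perm + 1), obs, n_perm + 1, False, alternative)


# ---------------------------------------------------------------------------
# confluency
# ---------------------------------------------------------------------------


def preprocess_brightfield(
    image: np.ndarray, params: imaging.SegmentationParams
) -> np.ndarray:
    """8-bit conversion, rolling-ball subtraction and contrast enhancement.

    The shared front end of the confluency chain; classifier training on
    synthetic fixtures must apply the same transform.
    """
    img8 = imaging.to_8bit(image)
    dev = imaging.rolling_ball_subtract(
        img8, params.rolling_ball_radius, params.light_background
    )
    return imaging.enhance_contrast(dev, params.saturation)


def confluency(image: np.ndarray, params: imaging.SegmentationParams) -> float:
    """Cell-covered area fraction of a brightfield image.

    Full chain: 8-bit convert -> rolling-ball subtract -> contrast enhance ->
    probability map -> threshold (Yen on the probability histogram, or the
    fixed manual value) -> area fraction of the whole image.

    Fields whose background-subtracted dynamic range is below
    ``params.empty_field_floor`` of full scale are reported as empty (0.0):
    the normalized contrast stretch would only amplify sensor noise there,
    and no downstream threshold is meaningful.
    """
    if params.classifier is None:
        raise ValueError("params.classifier is required for confluency")
    img8 = imaging.to_8bit(image)
    dev = imaging.rolling_ball_subtract(
        img8, params.rolling_ball_radius, params.light_background
    )
    if (
        float(np.percentile(dev, 100.0 - params.saturation / 2.0))
        < params.empty_field_floor * 255.0
    ):
        return 0.0
    enhanced = imaging.enhance_contrast(dev, params.saturation)
    prob = params.classifier.predict_map(enhanced)
    if params.threshold_method == "yen":
        if float(prob.min()) == float(prob.max()):
            # degenerate map: nothing (or everything) detected
            return float(prob.mean() >= 0.5)
        thr = imaging.yen_threshold(prob.astype(float))
        mask = prob > thr
    else:
        mask = imaging.binarize(prob, params.probability_threshold)
    return float(mask.mean())


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def spider_chart_export(results, path=None) -> pd.DataFrame:
    """Terminal per-quadrant area fractions, one row per (condition, well,
    quadrant) — the data table behind a spider/radar chart."""
    if isinstance(results, MigrationResult):
        results = [results]
    rows = []
    for res in results:
        if not res.series:
            raise ValueError("cannot export an empty series")
        last = res.series[-1]
        for q in QUADRANTS:
            rows.append(
                {
                    "condition": res.condition,
                    "well": res.well,
                    "quadrant": q,
                    "terminal_area_fraction": last.fractions[q],
                    "time_s": last.time,
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
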