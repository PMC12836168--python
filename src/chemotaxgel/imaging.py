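"""Segmentation primitives for brightfield cell images.

This module re-implements, as documented and testable functions, the
processing chain usually delegated to interactive tools: rolling-ball
background subtraction, percentile contrast enhancement, Yen automatic
thresholding, a pixel classifier producing per-pixel foreground probability
maps, and fixed-threshold binarization.

The pixel classifier is an openly specified stand-in for interactive
pixel-classification workflows: a small fixed feature bank (Gaussian
smoothings, gradient magnitude, Laplacian-of-Gaussian magnitude and local
texture energy at 2-3 scales) feeding a logistic model trained on labelled
synthetic images. Its contract is simply "a probability map in [0, 1]",
which every downstream operation treats identically. A rule-based classifier
with explicit background/foreground intensity calibration is provided for
images with stable, known backgrounds.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "ImageStack",
    "SegmentationParams",
    "to_8bit",
    "rolling_ball_subtract",
    "enhance_contrast",
    "yen_threshold",
    "binarize",
    "PixelClassifier",
    "RuleBasedClassifier",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """Ordered grayscale frames with timestamps and physical calibration."""

    frames: np.ndarray  # (n_frames, h, w)
    timestamps: np.ndarray  # seconds, non-decreasing
    pixel_size: float  # µm per pixel
    bit_depth: int = 8
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def save_tiff(self, path) -> None:
        """Multi-page TIFF with a JSON description plus a timestamp sidecar CSV."""
        desc = json.dumps(
            {
                "timestamps_s": self.timestamps.tolist(),
                "pixel_size_um": self.pixel_size,
                "bit_depth": self.bit_depth,
                "metadata": self.metadata,
            }
        )
        tifffile.imwrite(
            path, self.frames, description=desc, photometric="minisblack"
        )
        sidecar = str(path) + ".timestamps.csv"
        pd.DataFrame(
            {"frame": np.arange(len(self)), "time_s": self.timestamps}
        ).to_csv(sidecar, index=False)

    @classmethod
    def from_tiff(cls, path, pixel_size: float | None = None) -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].description
        meta = {}
        try:
            meta = json.loads(desc) if desc else {}
        except (json.JSONDecodeError, TypeError):
            meta = {}
        if frames.ndim == 2:
            frames = frames[None]
        ts = meta.get("timestamps_s")
        if ts is None:
            ts = np.arange(len(frames), dtype=float)
        ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um", 1.0)
        return cls(
            frames,
            np.asarray(ts, dtype=float),
            float(ps),
            bit_depth=int(meta.get("bit_depth", 8)),
            metadata=meta.get("metadata", {}),
        )


@dataclass
class SegmentationParams:
    """Knobs of the §-style segmentation chain.

    ``threshold_method`` chooses how the probability map is binarized:
    ``"fixed"`` applies ``probability_threshold`` (the manual 0.5 used for
    stable-background migration images); ``"yen"`` derives the cut
    automatically from the probability histogram.
    """

    rolling_ball_radius: int = 6
    light_background: bool = True
    saturation: float = 0.35
    probability_threshold: float = 0.5
    threshold_method: str = "yen"
    classifier: object | None = None
    # Fields whose background-subtracted dynamic range (upper contrast
    # percentile) falls below this fraction of full 8-bit scale are treated
    # as empty: stretching such a field only amplifies sensor noise. The
    # default sits between the noise + morphology bias of an empty field
    # (< ~8% of scale) and the deviation a genuine dark cell produces
    # (> ~30% of scale).
    empty_field_floor: float = 0.15

    def __post_init__(self):
        if not (0.0 <= self.probability_threshold <= 1.0):
            raise ValueError("probability_threshold must lie in [0, 1]")
        if self.rolling_ball_radius < 1:
            raise ValueError("rolling_ball_radius must be >= 1")
        if self.threshold_method not in ("yen", "fixed"):
            raise ValueError("threshold_method must be 'yen' or 'fixed'")


# ---------------------------------------------------------------------------
# intensity primitives
# ---------------------------------------------------------------------------


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Convert a grayscale image to uint8.

    Already-8-bit input is returned unchanged (absolute intensity levels are
    meaningful and preserved); wider dtypes are min-max scaled to 0..255.
    A constant non-uint8 image maps to zeros with a warning.
    """
    img = np.asarray(image)
    if img.dtype == np.uint8:
        return img.copy()
    img = img.astype(float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        warnings.warn("constant image: 8-bit conversion returns zeros")
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255.0).astype(np.uint8)


def _ball_structure(radius: int, method: str = "ball"):
    """Non-flat structuring element: heights of a sphere cap (or paraboloid)."""
    ax = np.arange(-radius, radius + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    footprint = d2 <= radius * radius
    if method == "ball":
        heights = np.sqrt(np.clip(radius * radius - d2, 0.0, None))
    elif method == "paraboloid":
        heights = np.clip(radius - d2 / (2.0 * radius), 0.0, None)
    else:
        raise ValueError("method must be 'ball' or 'paraboloid'")
    heights[~footprint] = 0.0
    return footprint, heights


def rolling_ball_subtract(
    image: np.ndarray,
    radius: int = 6,
    light_background: bool = True,
    method: str = "ball",
) -> np.ndarray:
    """Rolling-ball background subtraction via grayscale morphology.

    The background is a grayscale closing (light background) or opening
    (dark background) with a non-flat ball structuring element of the given
    radius; the returned image is the non-negative deviation of each pixel
    from that background, with **foreground positive** regardless of input
    polarity (dark cells on a light field come out as positive deviations on
    a flat zero field). A constant image maps to a flat zero output.

    ``method="paraboloid"`` swaps in a paraboloid-shaped element, the legacy
    kernel of some plugin implementations.
    """
    img = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > min(img.shape):
        raise ValueError("radius too large for this image")
    footprint, heights = _ball_structure(radius, method)
    if light_background:
        bg = ndi.grey_closing(img, footprint=footprint, structure=heights)
        dev = bg - img
    else:
        bg = ndi.grey_opening(img, footprint=footprint, structure=heights)
        dev = img - bg
    return np.clip(dev, 0.0, None)


def enhance_contrast(
    image: np.ndarray,
    saturation: float = 0.35,
    normalize: bool = True,
    out_max: float = 255.0,
) -> np.ndarray:
    """Percentile contrast stretch: clip ``saturation``% of pixels, rescale.

    ``saturation/2`` percent of pixels saturate at each end; with
    ``normalize`` the clipped image is linearly rescaled to ``[0, out_max]``.
    Rank order of unclipped pixels is preserved. A constant image is returned
    unchanged with a warning (the stretch is undefined).
    """
    if not (0.0 <= saturation < 100.0):
        raise ValueError("saturation must lie in [0, 100)")
    img = np.asarray(image, dtype=float)
    lo = float(np.percentile(img, saturation / 2.0))
    hi = float(np.percentile(img, 100.0 - saturation / 2.0))
    if hi <= lo:
        warnings.warn("constant image: contrast enhancement is undefined")
        return img.copy()
    clipped = np.clip(img, lo, hi)
    if normalize:
        return (clipped - lo) / (hi - lo) * out_max
    return clipped


# ---------------------------------------------------------------------------
# Yen automatic threshold
# ---------------------------------------------------------------------------


def yen_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing Yen's maximum-correlation criterion.

    For a normalized histogram p and candidate split s (class 1 = bins <= s),
    with P1 = sum(p[:s+1]), S1 = sum(p[:s+1]**2), S2 = sum(p[s+1:]**2), the
    criterion is

        C(s) = 2*ln(P1*(1-P1)) - ln(S1*S2),

    maximized over all splits that leave both classes non-empty; ties are
    broken toward the lowest qualifying level. Integer images use one bin
    per gray level; float images are histogrammed into ``nbins`` bins and
    the bin center is returned. Foreground is ``image > threshold``.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    vmin, vmax = float(img.min()), float(img.max())
    if vmin == vmax:
        raise ValueError("constant image has no threshold")
    if np.issubdtype(img.dtype, np.integer):
        levels = np.arange(int(vmin), int(vmax) + 1, dtype=float)
        counts = np.bincount(
            (img.ravel() - int(vmin)).astype(np.int64), minlength=len(levels)
        ).astype(float)
    else:
        counts, edges = np.histogram(img.ravel(), bins=nbins, range=(vmin, vmax))
        counts = counts.astype(float)
        levels = (edges[:-1] + edges[1:]) / 2.0
    p = counts / counts.sum()
    p1 = np.cumsum(p)
    s1 = np.cumsum(p * p)
    s_total = s1[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = 2.0 * np.log(p1 * (1.0 - p1)) - np.log(s1 * (s_total - s1))
    valid = (p1 > 0) & (p1 < 1) & (s1 > 0) & (s_total - s1 > 0)
    crit[~valid] = -np.inf
    if not np.isfinite(crit).any():
        raise ValueError("no valid split: image effectively constant")
    return float(levels[int(np.argmax(crit))])


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground mask: probability >= threshold (inclusive, so masks are
    bit-reproducible at the 0.5 boundary)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(prob_map) >= threshold


# ---------------------------------------------------------------------------
# pixel classifiers
# ---------------------------------------------------------------------------

DEFAULT_FEATURE_SCALES = (1.0, 2.0)


def _feature_stack(image: np.ndarray, scales) -> np.ndarray:
    """Fixed feature bank: per scale, Gaussian smoothing, gradient magnitude,
    |LoG| and smoothed local texture energy; plus the raw image.

    Scales are kept small so foreground evidence does not bleed far past
    object borders: wide features widen the intermediate-probability halo
    around each object, which inflates areas when an automatic threshold
    lands near one end of a strongly bimodal probability histogram.
    """
    img = np.asarray(image, dtype=float)
    feats = [img]
    for s in scales:
        g = ndi.gaussian_filter(img, s)
        gx = ndi.gaussian_filter(img, s, order=(0, 1))
        gy = ndi.gaussian_filter(img, s, order=(1, 0))
        feats.append(g)
        feats.append(np.hypot(gx, gy))
        feats.append(np.abs(ndi.gaussian_laplace(img, s)))
        feats.append(ndi.gaussian_filter(np.abs(img - g), s))
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifier:
    """Logistic pixel classifier over the fixed feature bank.

    Trained with scikit-learn on labelled images; prediction uses the
    serialized weights directly, so a JSON round-trip fully determines the
    output.
    """

    scales: tuple = DEFAULT_FEATURE_SCALES
    coef: np.ndarray | None = None
    intercept: float = 0.0
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None
    seed: int = 0

    @property
    def trained(self) -> bool:
        return self.coef is not None

    def fit(
        self,
        images,
        masks,
        n_samples: int = 40_000,
        seed: int | None = None,
        C: float = 100.0,
    ):
        """Fit on pixels sampled (balanced per class) from labelled images.

        ``C`` is the inverse L2 regularization strength; the weak default
        regularization keeps the decision sharp so probability transitions at
        object borders stay spatially narrow.
        """
        from sklearn.linear_model import LogisticRegression

        if seed is not None:
            self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        xs, ys = [], []
        n_feat = 1 + 4 * len(self.scales)
        for img, mask in zip(images, masks):
            feats = _feature_stack(img, self.scales).reshape(-1, n_feat)
            lab = np.asarray(mask, dtype=bool).ravel()
            per_class = max(n_samples // (2 * len(images)), 100)
            for cls in (True, False):
                idx = np.nonzero(lab == cls)[0]
                if idx.size == 0:
                    continue
                take = rng.choice(idx, size=min(per_class, idx.size), replace=False)
                xs.append(feats[take])
                ys.append(np.full(len(take), cls, dtype=float))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        self.feat_mean = x.mean(axis=0)
        self.feat_std = x.std(axis=0) + 1e-12
        xz = (x - self.feat_mean) / self.feat_std
        clf = LogisticRegression(max_iter=2000, C=C, random_state=self.seed)
        clf.fit(xz, y)
        self.coef = clf.coef_.ravel().astype(float)
        self.intercept = float(clf.intercept_[0])
        return self

    def predict_map(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probability in [0, 1]."""
        if not self.trained:
            raise ValueError("classifier is untrained; call fit() or load weights")
        feats = _feature_stack(image, self.scales)
        z = (feats - self.feat_mean) / self.feat_std
        logit = z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))

    # JSON (de)serialization: feature scales, weights, standardization, seed.
    def to_json(self, path=None) -> str:
        if not self.trained:
            raise ValueError("cannot serialize an untrained classifier")
        blob = json.dumps(
            {
                "scales": list(self.scales),
                "coef": self.coef.tolist(),
                "intercept": self.intercept,
                "feat_mean": self.feat_mean.tolist(),
                "feat_std": self.feat_std.tolist(),
                "seed": self.seed,
            }
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob

    @classmethod
    def from_json(cls, source) -> "PixelClassifier":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            cfg = json.loads(source)
        else:
            with open(source) as fh:
                cfg = json.load(fh)
        return cls(
            scales=tuple(cfg["scales"]),
            coef=np.asarray(cfg["coef"], dtype=float),
            intercept=float(cfg["intercept"]),
            feat_mean=np.asarray(cfg["feat_mean"], dtype=float),
            feat_std=np.asarray(cfg["feat_std"], dtype=float),
            seed=int(cfg.get("seed", 0)),
        )


@dataclass
class RuleBasedClassifier:
    """Probability map from explicit intensity calibration.

    For images with a stable, known background (e.g. rendered brightfield
    frames), maps pixel intensity linearly between the calibrated background
    and foreground levels through a logistic squash. ``dark_foreground``
    selects polarity.
    """

    background_level: float
    foreground_level: float
    dark_foreground: bool = True
    steepness: float = 8.0

    def predict_map(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        span = self.background_level - self.foreground_level
        if span == 0:
            raise ValueError("background and foreground levels must differ")
        z = (self.background_level - img) / span  # 0 at bg, 1 at fg
        if not self.dark_foreground:
            z = (img - self.background_level) / -span
        return 1.0 / (1.0 + np.exp(-self.steepness * (z - 0.5)))
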