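"""End-to-end channel chains, co-positivity counting, and validation.

Each fluorescence channel runs through its own fixed sequence of
grayscale filters, one histogram auto-threshold, and binary morphology:

* DAPI   — rolling ball → 8-bit → sharpen → mean threshold → erode → dilate
* Pax-7  — edge magnitude → 8-bit → luminance stretch → watershed →
           rolling ball → Rényi entropy threshold → close → outline →
           fill holes → erode → small-object removal
* BrdU   — 8-bit → sharpen → rolling ball → kernel convolution →
           watershed → Intermodes threshold → small-object removal

Positives are then counted by mask intersection: a marker object counts
only where it co-locates with a DAPI nucleus, the BrdU/DAPI overlay is
median-filtered first, and every intersection is dilated so fragments of
signal inside one nucleus merge into a single countable object.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from . import filters, morphology, thresholding
from .errors import (
    ChannelProcessingError,
    DegenerateHistogramError,
    DimensionError,
    NotBimodalError,
    UndefinedFitError,
)
from .imaging import as_gray8, compute_histogram, to_gray8

__all__ = [
    "ChannelConfig",
    "CopositivityConfig",
    "PipelineConfig",
    "StageRecorder",
    "SectionQuantification",
    "ValidationFit",
    "DAPI_STAGES",
    "PAX7_STAGES",
    "BRDU_STAGES",
    "process_dapi",
    "process_pax7",
    "process_brdu",
    "count_copositive",
    "quantify_section",
    "validate_against_manual",
]

THRESHOLD_METHODS = {
    "mean": thresholding.threshold_mean,
    "renyi_entropy": thresholding.threshold_renyi_entropy,
    "intermodes": thresholding.threshold_intermodes,
}

#: Default smoothing kernel for the BrdU "filtration" convolution step.
DEFAULT_BRDU_KERNEL = [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]


@dataclass
class ChannelConfig:
    """Per-channel processing parameters.

    Defaults record every parameter the method leaves open: rolling-ball
    radii sized ≳2x the largest object of interest, 3x3 unit morphology,
    watershed minima depth 2 gray levels, and minimum object areas below
    which detections are treated as debris.
    """

    rolling_ball_radius: int = 25
    min_object_size: int = 20
    threshold_method: str = "mean"
    erode_iterations: int = 1
    dilate_iterations: int = 1
    watershed_enabled: bool = True
    watershed_h: int = 20
    convolution_kernel: list = field(default_factory=lambda: [row[:] for row in DEFAULT_BRDU_KERNEL])
    kernel_normalize: bool = True
    median_radius: int = 1

    def validate(self) -> None:
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ValueError(
                f"unknown threshold method {self.threshold_method!r}; "
                f"choose one of {sorted(THRESHOLD_METHODS)}"
            )
        for name in ("rolling_ball_radius", "min_object_size", "erode_iterations",
                     "dilate_iterations", "watershed_h", "median_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass
class CopositivityConfig:
    """Intersection-counting parameters (Fig-2-style merge panels)."""

    dilation_iterations: int = 2
    median_radius: int = 1

    def validate(self) -> None:
        if self.dilation_iterations < 1 or self.median_radius < 1:
            raise ValueError("copositivity parameters must be positive")


@dataclass
class PipelineConfig:
    """Complete parameter ledger for one quantification run."""

    dapi: ChannelConfig = field(default_factory=lambda: ChannelConfig(
        rolling_ball_radius=25, min_object_size=30, threshold_method="mean",
        watershed_enabled=False))
    pax7: ChannelConfig = field(default_factory=lambda: ChannelConfig(
        rolling_ball_radius=15, min_object_size=20, threshold_method="renyi_entropy"))
    brdu: ChannelConfig = field(default_factory=lambda: ChannelConfig(
        rolling_ball_radius=25, min_object_size=20, threshold_method="intermodes"))
    copositivity: CopositivityConfig = field(default_factory=CopositivityConfig)

    def validate(self) -> None:
        for ch in (self.dapi, self.pax7, self.brdu):
            ch.validate()
        self.copositivity.validate()

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls(
            dapi=ChannelConfig(**data.get("dapi", {})),
            pax7=ChannelConfig(**data.get("pax7", {})),
            brdu=ChannelConfig(**data.get("brdu", {})),
            copositivity=CopositivityConfig(**data.get("copositivity", {})),
        )
        cfg.validate()
        return cfg

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        """Stable sha256 of the canonical JSON form (audit trail)."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


class StageRecorder:
    """Collects the executed stage sequence and per-stage snapshots.

    Used both to assert stage-order fidelity in tests and to export the
    intermediate images for visual audit.
    """

    def __init__(self, keep_images: bool = False):
        self.stages: list[str] = []
        self.images: dict[str, np.ndarray] = {}
        self.thresholds: dict[str, int] = {}
        self._keep = keep_images

    def record(self, name: str, image: np.ndarray) -> np.ndarray:
        self.stages.append(name)
        if self._keep:
            self.images[name] = image.copy()
        return image

    def record_threshold(self, channel: str, result: thresholding.ThresholdResult) -> None:
        self.thresholds[channel] = result.t


def _null_recorder(recorder: StageRecorder | None) -> StageRecorder:
    return recorder if recorder is not None else StageRecorder(keep_images=False)


DAPI_STAGES = [
    "rolling_ball", "to_gray8", "sharpen", "threshold_mean", "erode", "dilate",
]
PAX7_STAGES = [
    "edge_magnitude", "to_gray8", "normalize_range", "watershed", "rolling_ball",
    "threshold_renyi_entropy", "close", "outline", "fill_holes", "erode",
    "remove_small_objects",
]
BRDU_STAGES = [
    "to_gray8", "sharpen", "rolling_ball", "convolve_kernel", "watershed",
    "threshold_intermodes", "remove_small_objects",
]


def process_dapi(image: np.ndarray, cfg: PipelineConfig | None = None,
                 recorder: StageRecorder | None = None) -> np.ndarray:
    """DAPI chain: nucleus mask from the counterstain channel."""
    cfg = cfg or PipelineConfig()
    ch = cfg.dapi
    rec = _null_recorder(recorder)
    x = as_gray8(image)
    x = rec.record("rolling_ball", filters.rolling_ball_subtract(x, ch.rolling_ball_radius))
    x = rec.record("to_gray8", to_gray8(x))
    x = rec.record("sharpen", filters.sharpen(x))
    result = thresholding.threshold_mean(compute_histogram(x))
    rec.record_threshold("dapi", result)
    mask = rec.record("threshold_mean", thresholding.apply_threshold(x, result))
    mask = rec.record("erode", morphology.erode(mask, ch.erode_iterations))
    mask = rec.record("dilate", morphology.dilate(mask, ch.dilate_iterations))
    return mask


def process_pax7(image: np.ndarray, cfg: PipelineConfig | None = None,
                 recorder: StageRecorder | None = None) -> np.ndarray:
    """Pax-7 chain: satellite-cell marker mask.

    A blank (single-gray-level) channel is a legitimate biological
    outcome, so a degenerate histogram yields an empty mask rather than
    an error.
    """
    cfg = cfg or PipelineConfig()
    ch = cfg.pax7
    rec = _null_recorder(recorder)
    img8 = as_gray8(image)
    x = rec.record("edge_magnitude", filters.edge_magnitude(img8))
    x = rec.record("to_gray8", to_gray8(x))
    x = rec.record("normalize_range", filters.normalize_range(x)) if x.min() != x.max() \
        else rec.record("normalize_range", x)
    divide_lines = None
    if ch.watershed_enabled:
        # Dividing lines come from the intensity landscape of the input
        # channel (bright spots = basins), not from the edge-magnitude
        # image: the edge image walls every interior in by its own
        # outline, so its basin structure cannot separate two touching
        # spots whose outlines are connected.
        divide_lines = morphology.watershed_divide_lines(
            img8, ch.watershed_h, invert=True)
        xw = x.copy()
        xw[divide_lines] = 0
        x = rec.record("watershed", xw)
    else:
        rec.record("watershed", x)
    x = rec.record("rolling_ball", filters.rolling_ball_subtract(x, ch.rolling_ball_radius))
    try:
        result = thresholding.threshold_renyi_entropy(compute_histogram(x))
    except DegenerateHistogramError:
        # Featureless channel: no Pax-7 signal anywhere.
        rec.record("threshold_renyi_entropy", np.zeros(x.shape, dtype=bool))
        for name in ("close", "outline", "fill_holes", "erode", "remove_small_objects"):
            rec.record(name, np.zeros(x.shape, dtype=bool))
        return np.zeros(x.shape, dtype=bool)
    rec.record_threshold("pax7", result)
    mask = rec.record("threshold_renyi_entropy", thresholding.apply_threshold(x, result))
    mask = rec.record("close", morphology.close(mask))
    mask = rec.record("outline", morphology.outline(mask))
    mask = rec.record("fill_holes", morphology.fill_holes(mask))
    if divide_lines is not None:
        # Cavity filling must not undo a watershed separation: the outer
        # edge contour of two touching spots encloses both, so the lines
        # dividing their interiors are re-excluded after the fill.
        mask = mask & ~divide_lines
    mask = rec.record("erode", morphology.erode(mask, ch.erode_iterations))
    mask = rec.record("remove_small_objects",
                      morphology.remove_small_objects(mask, ch.min_object_size))
    return mask


def process_brdu(image: np.ndarray, cfg: PipelineConfig | None = None,
                 recorder: StageRecorder | None = None) -> np.ndarray:
    """BrdU chain: proliferation marker mask.

    Raises :class:`ChannelProcessingError` when the Intermodes threshold
    is undefined (e.g. a blank channel, whose histogram never becomes
    bimodal) — surfaced explicitly rather than silently returning zero.
    """
    cfg = cfg or PipelineConfig()
    ch = cfg.brdu
    rec = _null_recorder(recorder)
    x = as_gray8(image)
    x = rec.record("to_gray8", to_gray8(x))
    x = rec.record("sharpen", filters.sharpen(x))
    x = rec.record("rolling_ball", filters.rolling_ball_subtract(x, ch.rolling_ball_radius))
    x = rec.record("convolve_kernel", filters.convolve_kernel(
        x, ch.convolution_kernel, normalize=ch.kernel_normalize))
    if ch.watershed_enabled:
        x = rec.record("watershed", morphology.watershed_split(x, ch.watershed_h))
    else:
        rec.record("watershed", x)
    try:
        result = thresholding.threshold_intermodes(compute_histogram(x))
    except NotBimodalError as exc:
        raise ChannelProcessingError("brdu", str(exc)) from exc
    rec.record_threshold("brdu", result)
    mask = rec.record("threshold_intermodes", thresholding.apply_threshold(x, result))
    mask = rec.record("remove_small_objects",
                      morphology.remove_small_objects(mask, ch.min_object_size))
    return mask


def count_copositive(mask_a: np.ndarray, mask_b: np.ndarray,
                     cfg: PipelineConfig | None = None,
                     median_first: bool = False) -> int:
    """Count locations where both masks carry signal.

    The intersection is optionally median-filtered (majority vote over the
    (2r+1)^2 window — used for the BrdU/DAPI overlay to drop background
    hits), then dilated so that separate fragments of marker signal inside
    one nucleus merge into a single counted object.
    """
    cfg = cfg or PipelineConfig()
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise DimensionError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = a & b
    if median_first:
        filtered = filters.median_filter(
            inter.astype(np.uint8) * 255, cfg.copositivity.median_radius)
        inter = filtered > 127
    if inter.any():
        inter = morphology.dilate(inter, cfg.copositivity.dilation_iterations)
    return morphology.label_components(inter, connectivity=8).n


@dataclass(frozen=True)
class SectionQuantification:
    """Per-section counts and nucleus-normalized ratios."""

    n_nuclei: int
    n_pax7: int
    n_brdu: int
    n_copositive: int
    ratio_pax7: float
    ratio_brdu: float
    ratio_copositive: float
    ratios_defined: bool
    thresholds: dict
    config_used: PipelineConfig
    channel_errors: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flat record for tabular export."""
        return {
            "n_nuclei": self.n_nuclei,
            "n_pax7": self.n_pax7,
            "n_brdu": self.n_brdu,
            "n_copositive": self.n_copositive,
            "ratio_pax7": self.ratio_pax7,
            "ratio_brdu": self.ratio_brdu,
            "ratio_copositive": self.ratio_copositive,
        }


def quantify_section(dapi: np.ndarray, pax7: np.ndarray, brdu: np.ndarray,
                     cfg: PipelineConfig | None = None,
                     recorders: dict | None = None) -> SectionQuantification:
    """Quantify one three-channel section.

    Channels must be co-registered images of identical dimensions
    (acquired from the same frame); a size mismatch is an error, never a
    resample.  Ratios use the total DAPI nucleus count of the same
    section as denominator; with zero nuclei they are reported as NaN
    with ``ratios_defined=False`` rather than failing.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    d, p, b = as_gray8(dapi), as_gray8(pax7), as_gray8(brdu)
    if not (d.shape == p.shape == b.shape):
        raise DimensionError(
            f"channel dimensions differ: dapi {d.shape}, pax7 {p.shape}, brdu {b.shape}")
    recorders = recorders if recorders is not None else {}
    rec_d = recorders.setdefault("dapi", StageRecorder())
    rec_p = recorders.setdefault("pax7", StageRecorder())
    rec_b = recorders.setdefault("brdu", StageRecorder())

    dapi_mask = process_dapi(d, cfg, rec_d)
    # Nuclei below the minimum plausible area are debris; drop them before
    # both counting and gating.
    dapi_mask = morphology.remove_small_objects(dapi_mask, cfg.dapi.min_object_size)
    n_nuclei = morphology.label_components(dapi_mask, connectivity=8).n

    pax7_mask = process_pax7(p, cfg, rec_p)
    channel_errors: dict = {}
    try:
        brdu_mask = process_brdu(b, cfg, rec_b)
    except ChannelProcessingError as exc:
        # A featureless BrdU channel leaves Intermodes undefined; at the
        # section level that simply means no BrdU-positive cells.
        channel_errors["brdu"] = str(exc)
        brdu_mask = np.zeros(b.shape, dtype=bool)

    n_pax7 = count_copositive(pax7_mask, dapi_mask, cfg)
    n_brdu = count_copositive(brdu_mask, dapi_mask, cfg, median_first=True)
    n_copositive = count_copositive(brdu_mask, pax7_mask, cfg)

    thresholds = {}
    for rec in (rec_d, rec_p, rec_b):
        thresholds.update(rec.thresholds)

    if n_nuclei > 0:
        ratios = (n_pax7 / n_nuclei, n_brdu / n_nuclei, n_copositive / n_nuclei)
        defined = True
    else:
        ratios = (math.nan, math.nan, math.nan)
        defined = False
    return SectionQuantification(
        n_nuclei=n_nuclei, n_pax7=n_pax7, n_brdu=n_brdu, n_copositive=n_copositive,
        ratio_pax7=ratios[0], ratio_brdu=ratios[1], ratio_copositive=ratios[2],
        ratios_defined=defined, thresholds=thresholds, config_used=cfg,
        channel_errors=channel_errors,
    )


@dataclass(frozen=True)
class ValidationFit:
    """OLS agreement between paired semi-automatic and manual counts."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def validate_against_manual(auto, manual) -> ValidationFit:
    """Ordinary least squares of automatic on manual paired values.

    Returns slope, intercept and the coefficient of determination
    R^2 = 1 - SS_res / SS_tot.  Works equally for raw counts or ratios;
    report which was used alongside the statistic.
    """
    a = np.asarray(auto, dtype=np.float64)
    m = np.asarray(manual, dtype=np.float64)
    if a.shape != m.shape or a.ndim != 1:
        raise DimensionError("auto and manual must be equal-length 1-D sequences")
    if a.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {a.size}")
    if np.ptp(m) == 0:
        raise UndefinedFitError("manual values have zero variance; OLS slope undefined")
    fit = stats.linregress(m, a)
    return ValidationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=int(a.size),
    )
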