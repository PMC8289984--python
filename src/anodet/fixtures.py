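"""Synthetic pseudo-radiograph phantoms with injected anomalies.

A "normal" phantom is a dark background carrying two brighter elliptical
lung fields and a bright central mediastinal band, with mild per-seed jitter
of positions, sizes, and intensities plus low-amplitude pixel noise.  The
geometry is a deliberately crude stand-in for a frontal chest radiograph:
its purpose is to give every downstream module a deterministic, shippable
data source, not anatomical realism.

Anomalous variants are transforms of the normal phantom generated from the
same seed:

==================== ====================================================
kind                 transform (label)
==================== ====================================================
focal_blob           bright truncated-Gaussian nodule in one lung (Opacity)
basal_fill           opacification of the lower lung fields (Opacity)
central_enlargement  widened mediastinal band (NoOpacityNotNormal)
lr_flip              exact horizontal mirror (NoOpacityNotNormal)
inversion            intensity negation x -> -x (NoOpacityNotNormal)
rotation             rotation by a multiple of 90 deg (NoOpacityNotNormal)
==================== ====================================================

The three additive kinds carry a ground-truth boolean mask of the altered
region in ``record.metadata["mask"]`` so error-map localization can be
tested quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (LABEL_NORMAL, LABEL_NOT_NORMAL, LABEL_OPACITY,
                      ImageRecord, Manifest, denormalize_to_uint16)
from .exceptions import InvalidSpecError

ANOMALY_KINDS = ("none", "focal_blob", "central_enlargement", "basal_fill",
                 "lr_flip", "inversion", "rotation")

LABEL_FOR_KIND = {
    "none": LABEL_NORMAL,
    "focal_blob": LABEL_OPACITY,
    "basal_fill": LABEL_OPACITY,
    "central_enlargement": LABEL_NOT_NORMAL,
    "lr_flip": LABEL_NOT_NORMAL,
    "inversion": LABEL_NOT_NORMAL,
    "rotation": LABEL_NOT_NORMAL,
}

# Phantom geometry constants (fractions of the image side).
BACKGROUND = -0.85
NOISE_STD = 0.02
LUNG_CENTERS = ((0.30, 0.48), (0.70, 0.48))  # (x, y), origin top-left
LUNG_AXES = (0.16, 0.27)                     # (semi-x, semi-y)
LUNG_INTENSITY = 0.55
BAND_CENTER = (0.50, 0.52)
BAND_AXES = (0.105, 0.30)
BAND_INTENSITY = 0.75
JITTER_POS = 0.02        # center jitter, +/- fraction of side
JITTER_SCALE = 0.10      # axis/intensity jitter, +/- relative fraction
EDGE_SOFTNESS = 12.0     # soft-edge steepness of the ellipse masks

# Anomaly defaults.
DEFAULT_BLOB_RADIUS = 0.12       # mask radius as a fraction of the side
DEFAULT_BLOB_INTENSITY = 1.2     # dense mass; saturates toward white at center
DEFAULT_ENLARGEMENT = 1.6        # mediastinal axis scale factor
DEFAULT_FILL_HEIGHT = 0.40       # fraction of the lung's vertical extent
DEFAULT_FILL_INTENSITY = 0.55
DEFAULT_ROTATION_DEG = 90


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic recipe for one phantom image."""

    resolution: int
    seed: int
    anomaly_kind: str = "none"
    anomaly_params: dict = field(default_factory=dict)

    def __post_init__(self):
        res = self.resolution
        if res < 4 or (res & (res - 1)) != 0:
            raise InvalidSpecError(
                f"resolution must be a power of two >= 4, got {res}")
        if self.anomaly_kind not in ANOMALY_KINDS:
            raise InvalidSpecError(f"unknown anomaly kind {self.anomaly_kind!r}")


def _soft_ellipse(xx: np.ndarray, yy: np.ndarray, center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    """Soft-edged ellipse membership in [0, 1]."""
    r = np.sqrt(((xx - center[0]) / axes[0]) ** 2 +
                ((yy - center[1]) / axes[1]) ** 2)
    return 1.0 / (1.0 + np.exp(EDGE_SOFTNESS * (r - 1.0)))


def _base_geometry(rng: np.random.Generator):
    """Draw jittered geometry parameters; consumes a fixed number of variates."""
    jp, js = JITTER_POS, JITTER_SCALE
    lungs = []
    for cx, cy in LUNG_CENTERS:
        center = (cx + rng.uniform(-jp, jp), cy + rng.uniform(-jp, jp))
        axes = (LUNG_AXES[0] * (1 + rng.uniform(-js, js)),
                LUNG_AXES[1] * (1 + rng.uniform(-js, js)))
        intensity = LUNG_INTENSITY * (1 + rng.uniform(-js, js))
        lungs.append((center, axes, intensity))
    band_center = (BAND_CENTER[0] + rng.uniform(-jp, jp),
                   BAND_CENTER[1] + rng.uniform(-jp, jp))
    band_axes = (BAND_AXES[0] * (1 + rng.uniform(-js, js)),
                 BAND_AXES[1] * (1 + rng.uniform(-js, js)))
    band_intensity = BAND_INTENSITY * (1 + rng.uniform(-js, js))
    return lungs, (band_center, band_axes, band_intensity)


def _render_base(res: int, rng: np.random.Generator):
    """Render the normal phantom; returns (pixels, geometry, grids)."""
    coords = (np.arange(res) + 0.5) / res
    xx, yy = np.meshgrid(coords, coords)   # xx: column coord, yy: row coord
    lungs, band = _base_geometry(rng)
    canvas = np.full((res, res), BACKGROUND)
    for center, axes, intensity in lungs:
        canvas += intensity * _soft_ellipse(xx, yy, center, axes)
    b_center, b_axes, b_intensity = band
    canvas += b_intensity * _soft_ellipse(xx, yy, b_center, b_axes)
    canvas += rng.normal(0.0, NOISE_STD, (res, res))
    return np.clip(canvas, -1.0, 1.0), (lungs, band), (xx, yy)


def generate_phantom(spec: PhantomSpec) -> ImageRecord:
    """Generate a phantom image; bit-identical for identical specs."""
    res = spec.resolution
    rng = np.random.default_rng(spec.seed)
    base, (lungs, band), (xx, yy) = _render_base(res, rng)
    params = spec.anomaly_params
    kind = spec.anomaly_kind
    mask: np.ndarray | None = None

    if kind == "none":
        pixels = base
    elif kind == "focal_blob":
        radius = float(params.get("radius", DEFAULT_BLOB_RADIUS))
        intensity = float(params.get("intensity", DEFAULT_BLOB_INTENSITY))
        center, axes, _ = lungs[int(rng.integers(0, 2))]
        # place the blob inside the chosen lung field
        bx = center[0] + rng.uniform(-0.4, 0.4) * axes[0]
        by = center[1] + rng.uniform(-0.4, 0.4) * axes[1]
        r2 = (xx - bx) ** 2 + (yy - by) ** 2
        sigma = radius / 2.5
        bump = np.exp(-r2 / (2 * sigma**2)) - np.exp(-radius**2 / (2 * sigma**2))
        bump = np.clip(bump, 0.0, None) / (1 - np.exp(-radius**2 / (2 * sigma**2)))
        pixels = np.clip(base + intensity * bump, -1.0, 1.0)
        mask = r2 <= radius**2
    elif kind == "central_enlargement":
        factor = float(params.get("factor", DEFAULT_ENLARGEMENT))
        if factor <= 0:
            raise InvalidSpecError("enlargement factor must be positive")
        b_center, b_axes, b_intensity = band
        big_axes = (b_axes[0] * factor, b_axes[1] * min(factor, 1.15))
        delta = (_soft_ellipse(xx, yy, b_center, big_axes)
                 - _soft_ellipse(xx, yy, b_center, b_axes))
        pixels = np.clip(base + b_intensity * np.clip(delta, 0.0, None), -1.0, 1.0)
        mask = delta > 0.05
    elif kind == "basal_fill":
        height = float(params.get("height", DEFAULT_FILL_HEIGHT))
        intensity = float(params.get("intensity", DEFAULT_FILL_INTENSITY))
        if not 0 < height <= 1:
            raise InvalidSpecError("fill height must be in (0, 1]")
        add = np.zeros_like(base)
        mask = np.zeros(base.shape, dtype=bool)
        for center, axes, _ in lungs:
            member = _soft_ellipse(xx, yy, center, axes)
            y_top = center[1] + axes[1] * (1.0 - 2.0 * height)
            basal = member * (yy >= y_top)
            add += intensity * basal
            mask |= basal > 0.5
        pixels = np.clip(base + add, -1.0, 1.0)
    elif kind == "lr_flip":
        pixels = base[:, ::-1].copy()
    elif kind == "inversion":
        pixels = -base
    elif kind == "rotation":
        degrees = int(params.get("degrees", DEFAULT_ROTATION_DEG))
        if degrees % 90 != 0 or degrees % 360 == 0:
            raise InvalidSpecError(
                "rotation degrees must be a nonzero multiple of 90")
        pixels = np.rot90(base, k=(degrees // 90) % 4).copy()
    else:  # pragma: no cover - guarded by PhantomSpec
        raise InvalidSpecError(kind)

    record_id = f"{kind}-r{res}-s{spec.seed}"
    metadata = {"anomaly_kind": kind, "seed": int(spec.seed)}
    if mask is not None:
        metadata["mask"] = mask
    return ImageRecord(id=record_id, pixels=pixels.astype(np.float64),
                       label=LABEL_FOR_KIND[kind], metadata=metadata)


# Cycles used to assign anomaly kinds to abnormal manifest entries.
_OPACITY_CYCLE = ("focal_blob", "basal_fill")
_NOT_NORMAL_CYCLE = ("central_enlargement", "lr_flip", "inversion", "rotation")


def generate_manifest(counts: dict[str, int], resolution: int, seed: int,
                      materialize: bool = False) -> Manifest:
    """Build a manifest of phantom records with the requested per-label counts.

    Records are unmaterialized by default (pixels=None); call
    ``materialize_record`` or pass materialize=True to render them.  Record
    seeds, anomaly kinds, and demographic metadata derive deterministically
    from the master seed.
    """
    for label, count in counts.items():
        if label not in LABEL_FOR_KIND.values():
            raise InvalidSpecError(f"unknown label {label!r}")
        if count < 0:
            raise InvalidSpecError(f"negative count for {label!r}")
    rng = np.random.default_rng(seed)
    records: list[ImageRecord] = []
    index = 0
    for label in (LABEL_NORMAL, LABEL_OPACITY, LABEL_NOT_NORMAL):
        cycle = (("none",) if label == LABEL_NORMAL
                 else _OPACITY_CYCLE if label == LABEL_OPACITY
                 else _NOT_NORMAL_CYCLE)
        for k in range(counts.get(label, 0)):
            kind = cycle[k % len(cycle)]
            record_seed = int(rng.integers(0, 2**31))
            metadata = {
                "anomaly_kind": kind,
                "seed": record_seed,
                "resolution": int(resolution),
                "view": "PA" if rng.random() < 0.55 else "AP",
                "sex": "M" if rng.random() < 0.57 else "F",
                "age": int(rng.integers(2, 93)),
            }
            records.append(ImageRecord(id=f"p{index:06d}-{kind}", pixels=None,
                                       label=label, metadata=metadata))
            index += 1
    manifest = Manifest(records)
    if materialize:
        for record in manifest:
            materialize_record(record)
    return manifest


def spec_for_record(record: ImageRecord) -> PhantomSpec:
    meta = record.metadata
    return PhantomSpec(resolution=int(meta["resolution"]), seed=int(meta["seed"]),
                       anomaly_kind=meta["anomaly_kind"])


def materialize_record(record: ImageRecord) -> ImageRecord:
    """Render a manifest record's pixels in place (no-op if already present)."""
    if record.pixels is None:
        phantom = generate_phantom(spec_for_record(record))
        record.pixels = phantom.pixels
        if "mask" in phantom.metadata:
            record.metadata["mask"] = phantom.metadata["mask"]
    return record


def write_fixture_dir(manifest: Manifest, out_dir) -> Path:
    """Write phantoms as 16-bit grayscale PNGs plus a manifest CSV.

    Ground-truth anomaly masks are written alongside as 8-bit PNGs.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for record in manifest:
        materialize_record(record)
        path = out_dir / "images" / f"{record.id}.png"
        iio.imwrite(path, denormalize_to_uint16(record.pixels))
        record.metadata["path"] = str(path)
        mask = record.metadata.get("mask")
        if mask is not None:
            iio.imwrite(out_dir / "masks" / f"{record.id}.png",
                        (mask.astype(np.uint8) * 255))
    manifest.to_csv(out_dir / "manifest.csv")
    return out_dir
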