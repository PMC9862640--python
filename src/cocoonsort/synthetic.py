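"""Synthetic cocoon fixtures with exact ground truth.

No image or sensor data accompanies the sorting machine, so every station is
exercised against generated inputs: cocoon silhouettes parameterized in
elliptic-Fourier space (ovoid "good" shapes; waisted, peanut-like "bad"
shapes with extra power in harmonics 3-5), composited onto a neutral cradle
background with optional surface stains of controlled area and HSB color,
and two-class photodiode frames drawn from per-channel normal distributions
with a controllable mean separation.

A master seed fans out to per-cocoon seeds through ``SeedSequence`` keyed on
the cocoon id, so any subset of a benchmark regenerates identically.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import disk as _draw_disk
from skimage.draw import polygon as _draw_polygon

from .errors import SpecError, ValidationError
from .imaging import hsb_to_rgb
from .morphometrics import EFADescriptor, efa_reconstruct
from .sensor import ADC_MAX, N_CHANNELS, N_COLS, N_ROWS, SensorFrame

# Default palette (RGB 0-255).  The cocoon is a warm off-white (saturation
# ~11, below both stain profiles); the cradle background is a neutral dark
# gray so the log-luminance edge map cleanly separates the silhouette.
COCOON_RGB = (235, 232, 225)
BACKGROUND_RGB = (45, 45, 45)
#: Orange stain in HSB (0-255 per channel): inside the top profile's hue
#: band and above the bottom profile's saturation floor.
STAIN_HSB = (18.0, 235.0, 200.0)


# ---------------------------------------------------------------------------
# Shape specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StainSpec:
    """One planted stain: offset of its center from the cocoon center (px),
    requested area in px^2, and HSB color."""

    offset: tuple[float, float]
    area_px2: float
    hsb: tuple[float, float, float] = STAIN_HSB


@dataclass(frozen=True)
class CocoonSpec:
    """Everything needed to render one cocoon image deterministically.

    ``efa_coefficients`` describe a unit-scale silhouette; ``scale_px``
    multiplies it into pixel units.  ``rotation`` (radians) and ``center``
    place it in the frame.  ``noise_sd`` adds Gaussian surface texture
    (0 = perfectly flat study conditions).
    """

    efa_coefficients: np.ndarray  # (n, 4) unit-scale
    scale_px: float
    center: tuple[float, float] | None = None  # (x, y); None = frame center
    rotation: float = 0.0
    stains: tuple[StainSpec, ...] = ()
    image_size: tuple[int, int] = (120, 160)  # (height, width)
    cocoon_rgb: tuple[int, int, int] = COCOON_RGB
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB
    noise_sd: float = 0.0
    seed: int = 0


def good_shape_coefficients(rng: np.random.Generator) -> np.ndarray:
    """Ovoid silhouette: dominant ellipse plus a mild egg asymmetry."""
    coeff = np.zeros((6, 4))
    coeff[0] = [1.0, 0.0, 0.0, rng.uniform(0.60, 0.72)]  # a1, b1, c1, d1
    coeff[1, 0] = rng.uniform(0.02, 0.06)  # slight tip asymmetry
    coeff[2:, :] = rng.normal(0.0, 0.004, size=(4, 4))
    return coeff


def bad_shape_coefficients(rng: np.random.Generator) -> np.ndarray:
    """Waisted / malformed silhouette: strong odd harmonics pinch the middle."""
    coeff = np.zeros((6, 4))
    coeff[0] = [1.0, 0.0, 0.0, rng.uniform(0.60, 0.72)]
    coeff[1, 0] = rng.uniform(0.02, 0.06)
    coeff[2, 3] = rng.uniform(0.12, 0.20) * rng.choice([-1.0, 1.0])  # d3: waist
    coeff[3:5, :] = rng.normal(0.0, 0.02, size=(2, 4))
    return coeff


def outline_from_spec(spec: CocoonSpec, n_points: int = 720) -> np.ndarray:
    """Analytic silhouette polygon of a spec, in pixel coordinates."""
    coeff = np.asarray(spec.efa_coefficients, dtype=np.float64)
    desc = EFADescriptor(
        coefficients=coeff, a0=0.0, c0=0.0, n_points=max(n_points, 2 * coeff.shape[0])
    )
    pts = efa_reconstruct(desc, n_points=n_points).points * spec.scale_px
    rot = np.array(
        [
            [np.cos(spec.rotation), -np.sin(spec.rotation)],
            [np.sin(spec.rotation), np.cos(spec.rotation)],
        ]
    )
    pts = pts @ rot.T
    h, w = spec.image_size
    cx, cy = spec.center if spec.center is not None else (w / 2.0, h / 2.0)
    return pts + np.array([cx, cy])


def polygon_area(pts: np.ndarray) -> float:
    """Shoelace area of a closed polygon (centered first for stability)."""
    centered = pts - pts.mean(axis=0)
    x, y = centered[:, 0], centered[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def render_cocoon(spec: CocoonSpec) -> tuple[np.ndarray, dict]:
    """Rasterize a cocoon spec into an RGB image plus a ground-truth record.

    The record carries the analytic outline, the rendered silhouette pixel
    count, and per-stain rendered areas.  Raises ``SpecError`` when a stain
    center falls outside the silhouette.
    """
    pts = outline_from_spec(spec)
    h, w = spec.image_size
    if pts[:, 0].min() < 0 or pts[:, 0].max() >= w or pts[:, 1].min() < 0 or pts[:, 1].max() >= h:
        raise SpecError("silhouette does not fit inside the image")
    rng = np.random.default_rng(spec.seed)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_rgb

    rr, cc = _draw_polygon(pts[:, 1], pts[:, 0], shape=(h, w))
    silhouette = np.zeros((h, w), dtype=bool)
    silhouette[rr, cc] = True
    img[silhouette] = spec.cocoon_rgb
    if spec.noise_sd > 0:
        img[silhouette] += rng.normal(0.0, spec.noise_sd, size=(int(silhouette.sum()), 3))

    cx, cy = pts.mean(axis=0)
    stain_records = []
    for st in spec.stains:
        sx, sy = cx + st.offset[0], cy + st.offset[1]
        ix, iy = int(round(sx)), int(round(sy))
        if not (0 <= iy < h and 0 <= ix < w) or not silhouette[iy, ix]:
            raise SpecError(f"stain center ({sx:.1f}, {sy:.1f}) outside the silhouette")
        radius = float(np.sqrt(st.area_px2 / np.pi))
        srr, scc = _draw_disk((sy, sx), radius, shape=(h, w))
        keep = silhouette[srr, scc]
        srr, scc = srr[keep], scc[keep]
        img[srr, scc] = hsb_to_rgb(
            np.asarray(st.hsb, dtype=np.float64).reshape(1, 1, 3)
        )[0, 0]
        stain_records.append(
            {
                "center": (float(sx), float(sy)),
                "requested_area_px2": float(st.area_px2),
                "rendered_area_px2": int(srr.size),
                "hsb": tuple(float(v) for v in st.hsb),
            }
        )

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = {
        "outline": pts,
        "analytic_area_px2": polygon_area(pts),
        "area_px2": int(silhouette.sum()),
        "stains": stain_records,
        "seed": spec.seed,
    }
    return image, truth


# ---------------------------------------------------------------------------
# Sensor specs
# ---------------------------------------------------------------------------

def default_sensor_means() -> np.ndarray:
    """Baseline transmission profile: the cocoon shadows the matrix center."""
    rows = np.abs(np.arange(N_ROWS) - (N_ROWS - 1) / 2.0) / ((N_ROWS - 1) / 2.0)
    cols = np.abs(np.arange(N_COLS) - (N_COLS - 1) / 2.0) / ((N_COLS - 1) / 2.0)
    dip = 1.0 - 0.55 * np.outer(1.0 - rows, 1.0 - cols)
    return (350.0 + 400.0 * dip).reshape(N_CHANNELS)


@dataclass(frozen=True)
class SensorSpec:
    """Two-class photodiode signal model.

    Dead pupae dry out and transmit more light, so the dead-class mean is
    shifted upward by ``separation`` pooled standard deviations on every
    channel.  The default separation (0.3 SD/channel) puts a 35-channel
    logistic classifier in the ~80% accuracy regime observed for real
    cocoons.
    """

    class_label: str  # "alive" or "dead"
    means: np.ndarray = field(default_factory=default_sensor_means)
    sd: float = 40.0
    separation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in ("alive", "dead"):
            raise ValidationError("class_label must be 'alive' or 'dead'")
        m = np.asarray(self.means, dtype=np.float64)
        if m.shape != (N_CHANNELS,):
            raise ValidationError(f"means must have length {N_CHANNELS}")
        object.__setattr__(self, "means", m)

    @property
    def class_means(self) -> np.ndarray:
        shift = 0.5 * self.separation * self.sd
        return self.means + (shift if self.class_label == "dead" else -shift)


def render_sensor_frames(
    spec: SensorSpec, n: int, start_id: int = 0, timestamp: str = ""
) -> list[SensorFrame]:
    """Draw n frames from the spec's class distribution, clipped to the ADC."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    raw = rng.normal(spec.class_means, spec.sd, size=(n, N_CHANNELS))
    counts = np.clip(np.rint(raw), 0, ADC_MAX).astype(np.int64)
    return [
        SensorFrame(
            values=counts[i].reshape(N_ROWS, N_COLS),
            timestamp=timestamp,
            cocoon_id=start_id + i,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Benchmark set
# ---------------------------------------------------------------------------

#: The six sample categories used to assemble the evaluation lots:
#: (shape fit for reeling?, stain state, pupa state); "mixed" = coin flip.
CATEGORIES = (
    ("good", "mixed", "mixed"),
    ("bad", "mixed", "mixed"),
    ("good", "stained", "mixed"),
    ("good", "white", "mixed"),
    ("good", "mixed", "alive"),
    ("good", "mixed", "dead"),
)

CAMERA_NAMES = ("camera_shape", "camera_top", "camera_bottom")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions for the synthetic benchmark.

    Sizes and thresholds are expressed at the render scale (default 160 x 120
    frames).  Margins are wide by construction: the typical cocoon sits well
    inside the size gate, undersized/oversized cocoons sit well outside, and
    planted stains clearly exceed the per-object area rule.
    """

    n_per_category: int = 100
    image_size: tuple[int, int] = (120, 160)
    size_min_px2: int = 1000
    size_max_px2: int = 2700
    good_area_range: tuple[float, float] = (1500.0, 2100.0)
    undersized_area: float = 600.0
    oversized_area: float = 3200.0
    undersized_fraction: float = 0.1
    oversized_fraction: float = 0.1
    stain_area_range: tuple[float, float] = (170.0, 400.0)
    max_rotation: float = 0.2  # rad; cradles keep cocoons nearly axis-aligned
    noise_sd: float = 0.0
    sensor_separation: float = 2.0  # wide-margin alive/dead classes
    sensor_sd: float = 40.0


def _timestamp(cocoon_id: int) -> str:
    base = _dt.datetime(2023, 1, 12, 0, 0, 0)
    return (base + _dt.timedelta(seconds=cocoon_id)).strftime("%Y%m%dT%H%M%S")


def _cocoon_spec_for(
    cid: int,
    shape_class: str,
    size_class: str,
    stain_views: tuple[str, ...],
    cfg: BenchmarkConfig,
    rng: np.random.Generator,
) -> dict:
    """Build the per-view CocoonSpecs and the scalar ground truth for one id."""
    coeff = (
        good_shape_coefficients(rng)
        if shape_class == "good"
        else bad_shape_coefficients(rng)
    )
    if size_class == "undersized":
        target_area = cfg.undersized_area
    elif size_class == "oversized":
        target_area = cfg.oversized_area
    else:
        target_area = rng.uniform(*cfg.good_area_range)
    unit_pts = outline_from_spec(
        CocoonSpec(efa_coefficients=coeff, scale_px=1.0, image_size=(10_000, 10_000))
    )
    unit_area = polygon_area(unit_pts)
    scale = float(np.sqrt(target_area / unit_area))
    rotation = float(rng.uniform(-cfg.max_rotation, cfg.max_rotation))
    minor_semi = scale * float(np.abs(coeff[0, 3]))

    def stain_for_view() -> StainSpec:
        lo, hi = cfg.stain_area_range
        max_fit = np.pi * (0.8 * minor_semi) ** 2
        area = float(rng.uniform(lo, max(lo + 10.0, min(hi, max_fit))))
        radius = np.sqrt(area / np.pi)
        slack = max(0.0, minor_semi - radius - 2.0)
        off = rng.uniform(-slack / 2.0, slack / 2.0, size=2)
        return StainSpec(offset=(float(off[0]), float(off[1])), area_px2=area)

    specs = {}
    for view in CAMERA_NAMES:
        short = view.removeprefix("camera_")
        stains = (stain_for_view(),) if short in stain_views else ()
        specs[view] = CocoonSpec(
            efa_coefficients=coeff,
            scale_px=scale,
            rotation=rotation,
            stains=stains,
            image_size=cfg.image_size,
            noise_sd=cfg.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return {"specs": specs, "scale": scale, "target_area": target_area}


def make_benchmark_set(
    out_dir, config: BenchmarkConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Generate the full benchmark tree and return its manifest.

    Layout mirrors the machine's acquisition storage: one folder of BMP
    images per camera, the photodiode CSV in its own folder, plus a
    ``manifest.csv`` holding the ground truth for every cocoon.  File names
    embed the acquisition timestamp, the camera name and the progressive
    cocoon number.
    """
    from .sensor import write_sensor_csv  # local import avoids a cycle

    cfg = config or BenchmarkConfig()
    out = Path(out_dir)
    for cam in CAMERA_NAMES:
        (out / cam).mkdir(parents=True, exist_ok=True)
    (out / "sensor").mkdir(parents=True, exist_ok=True)

    records = []
    frames = []
    cid = 0
    for cat_idx, (shape_c, stain_c, vital_c) in enumerate(CATEGORIES):
        for _ in range(cfg.n_per_category):
            rng = np.random.default_rng(np.random.SeedSequence((seed, cid)))
            u = rng.uniform()
            if u < cfg.undersized_fraction:
                size_class = "undersized"
            elif u < cfg.undersized_fraction + cfg.oversized_fraction:
                size_class = "oversized"
            else:
                size_class = "ok"
            stained = stain_c == "stained" or (stain_c == "mixed" and rng.uniform() < 0.5)
            vital = vital_c if vital_c != "mixed" else ("dead" if rng.uniform() < 0.5 else "alive")
            stain_views: tuple[str, ...] = ()
            if stained:
                stain_views = (("top",), ("bottom",), ("top", "bottom"))[
                    int(rng.integers(0, 3))
                ]

            built = _cocoon_spec_for(cid, shape_c, size_class, stain_views, cfg, rng)
            ts = _timestamp(cid)
            row = {
                "id": cid,
                "timestamp": ts,
                "category": cat_idx + 1,
                "true_shape_class": shape_c,
                "true_size_class": size_class,
                "true_stain": bool(stain_views),
                "true_stain_top": "top" in stain_views,
                "true_stain_bottom": "bottom" in stain_views,
                "true_vital_state": vital,
            }
            for cam in CAMERA_NAMES:
                image, truth = render_cocoon(built["specs"][cam])
                fname = f"{ts}_{cam}_{cid:06d}.bmp"
                Image.fromarray(image).save(out / cam / fname, format="BMP")
                row[f"{cam.removeprefix('camera_')}_image"] = f"{cam}/{fname}"
                if cam == "camera_shape":
                    row["true_area_px2"] = truth["area_px2"]

            sframe = render_sensor_frames(
                SensorSpec(
                    class_label=vital,
                    sd=cfg.sensor_sd,
                    separation=cfg.sensor_separation,
                    seed=int(rng.integers(0, 2**31 - 1)),
                ),
                n=1,
                start_id=cid,
                timestamp=ts,
            )[0]
            frames.append(sframe)
            records.append(row)
            cid += 1

    write_sensor_csv(out / "sensor" / "sensor.csv", frames)
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
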