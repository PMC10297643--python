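"""Synthetic sagittal knee phantoms with known labels and lesion masks.

On a sagittal T2 slice the meniscus appears as one or two dark triangular
wedges ("horns") against brighter joint tissue, and a tear shows up as a
thin bright streak inside the dark wedge. The generator emulates exactly
these three elements — noisy bright background, dark wedge(s), optional
bright streak — with analytic geometry rendered independently at each of
the three pyramid resolutions, so higher levels are crisp renderings of
the same scene rather than blurry upsamplings, and the pixel-level ground
truth (label, lesion mask, host horn) is known by construction.

Geometry lives in normalized coordinates (unit height, width 2 for the
2:1 sagittal crop). Shapes are drawn from signed-distance fields with a
one-pixel anti-aliasing band at every level. Noise is additive Gaussian,
clipped to [0, 1] — no claim of MR physics realism.

Each case draws from its own counter-based random stream keyed by
``(seed, case_index)``, so any case is reproducible in isolation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .imageio import PyramidImage, save_png

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_case",
    "generate_dataset",
    "write_dataset",
]

_LEVEL_SCALES = (1, 2, 4)

# Wedge templates in normalized (x, y) coordinates: unit height, width 2.
# Apexes point toward the joint center, as the horns do in a sagittal view.
_ANTERIOR = np.array([(0.30, 0.35), (0.30, 0.75), (0.78, 0.55)])
_POSTERIOR = np.array([(1.70, 0.35), (1.70, 0.75), (1.22, 0.55)])
_VERTEX_JITTER = 0.04  # uniform, normalized units


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; intensities are in [0, 1] display units."""

    base_resolution: tuple[int, int] = (640, 320)  # (width, height), 2:1
    background_mean: float = 0.60
    background_sd: float = 0.05
    wedge_count: int = 2
    wedge_intensity: float = 0.20
    lesion_probability: float = 0.5
    lesion_intensity: float = 0.95
    lesion_thickness_px: float = 2.0
    seed: int = 0

    def __post_init__(self):
        w, h = self.base_resolution
        if w != 2 * h:
            raise ValueError(
                f"base_resolution must have 2:1 aspect (width = 2 x height), got {self.base_resolution}"
            )
        if not (self.wedge_intensity < self.background_mean < self.lesion_intensity):
            raise ValueError(
                "intensity ordering violated: need wedge_intensity < "
                f"background_mean < lesion_intensity, got {self.wedge_intensity}, "
                f"{self.background_mean}, {self.lesion_intensity}"
            )
        for name in ("background_mean", "wedge_intensity", "lesion_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.wedge_count not in (1, 2):
            raise ValueError(f"wedge_count must be 1 or 2, got {self.wedge_count}")
        if not 0.0 <= self.lesion_probability <= 1.0:
            raise ValueError(
                f"lesion_probability must be in [0, 1], got {self.lesion_probability}"
            )
        if self.lesion_thickness_px <= 0 or self.background_sd < 0:
            raise ValueError("lesion_thickness_px must be > 0 and background_sd >= 0")


@dataclass
class PhantomCase:
    """One synthetic case: resolution pyramid, label, and ground truth."""

    pyramid: PyramidImage
    label: int
    lesion_mask: np.ndarray  # bool, base resolution (H, W)
    horn: str | None  # "anterior" / "posterior" for injured cases
    case_index: int = 0
    wedge_mask: np.ndarray | None = None  # bool, base resolution; ground
    # truth of the dark meniscus region, for contrast checks and scoring

    def __post_init__(self):
        if (self.label == 1) != bool(self.lesion_mask.any()):
            raise ValueError(
                "label/mask inconsistency: label=1 iff lesion_mask is nonempty"
            )


# ---------------------------------------------------------------------------
# distance-field rendering
# ---------------------------------------------------------------------------

def _pixel_grid(height: int, width: int):
    """Pixel-center coordinates in normalized units (unit image height)."""
    ys = (np.arange(height, dtype=np.float64) + 0.5) / height
    xs = (np.arange(width, dtype=np.float64) + 0.5) / height
    return np.meshgrid(xs, ys)  # X (H,W), Y (H,W)


def _triangle_signed_distance(x, y, verts: np.ndarray):
    """Signed distance (positive inside) to a triangle, via the minimum of
    the three inward half-plane distances. Exact inside; a lower bound of
    the true distance outside, which is fine for a 1-px AA band."""
    d = None
    v = verts
    # orient consistently (counter-clockwise)
    e1, e2 = v[1] - v[0], v[2] - v[0]
    area = e1[0] * e2[1] - e1[1] * e2[0]
    if area < 0:
        v = v[::-1]
    for i in range(3):
        p0, p1 = v[i], v[(i + 1) % 3]
        e = p1 - p0
        n = np.array([-e[1], e[0]])  # inward normal for CCW
        n = n / np.hypot(*n)
        di = (x - p0[0]) * n[0] + (y - p0[1]) * n[1]
        d = di if d is None else np.minimum(d, di)
    return d


def _segment_distance(x, y, p0, p1):
    """Euclidean distance from pixel centers to segment p0-p1."""
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0.0:
        return np.hypot(x - p0[0], y - p0[1])
    t = ((x - p0[0]) * d[0] + (y - p0[1]) * d[1]) / dd
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(x - (p0[0] + t * d[0]), y - (p0[1] + t * d[1]))


def _coverage(signed_dist_px):
    """Map a signed distance in pixels to [0,1] coverage with 1-px AA."""
    return np.clip(signed_dist_px + 0.5, 0.0, 1.0)


@dataclass
class _Scene:
    wedges: list[np.ndarray]
    horns: list[str]
    lesion_segment: tuple[np.ndarray, np.ndarray] | None
    lesion_host: int


def _sample_scene(spec: PhantomSpec, rng: np.random.Generator, injured: bool) -> _Scene:
    templates = [("anterior", _ANTERIOR), ("posterior", _POSTERIOR)]
    if spec.wedge_count == 1:
        keep = int(rng.integers(0, 2))
        templates = [templates[keep]]
    horns, wedges = [], []
    for name, verts in templates:
        jitter = rng.uniform(-_VERTEX_JITTER, _VERTEX_JITTER, verts.shape)
        horns.append(name)
        wedges.append(verts + jitter)
    segment, host = None, -1
    if injured:
        host = int(rng.integers(0, len(wedges)))
        v = wedges[host]
        centroid = v.mean(axis=0)
        apex = v[2]
        axis = apex - centroid
        theta = rng.uniform(-np.pi / 6, np.pi / 6)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        direction = rot @ axis
        direction = direction / np.hypot(*direction)
        reach = 0.38 * np.hypot(*axis)
        p0 = centroid - 0.6 * reach * direction
        p1 = centroid + reach * direction
        segment = (p0, p1)
    return _Scene(wedges, horns, segment, host)


def _render_level(spec: PhantomSpec, scene: _Scene, scale: int,
                  rng: np.random.Generator) -> np.ndarray:
    w0, h0 = spec.base_resolution
    h, w = h0 * scale, w0 * scale
    x, y = _pixel_grid(h, w)
    img = spec.background_mean + rng.normal(0.0, spec.background_sd, (h, w))
    for i, verts in enumerate(scene.wedges):
        aw = _coverage(_triangle_signed_distance(x, y, verts) * h)
        img += aw * (spec.wedge_intensity - spec.background_mean)
        if scene.lesion_segment is not None and i == scene.lesion_host:
            p0, p1 = scene.lesion_segment
            half_px = 0.5 * spec.lesion_thickness_px * scale
            dl = _segment_distance(x, y, p0, p1) * h
            al = _coverage(half_px - dl) * aw
            img += al * (spec.lesion_intensity - spec.wedge_intensity)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def _wedge_mask(spec: PhantomSpec, scene: _Scene) -> np.ndarray:
    w0, h0 = spec.base_resolution
    x, y = _pixel_grid(h0, w0)
    mask = np.zeros((h0, w0), dtype=bool)
    for verts in scene.wedges:
        mask |= _coverage(_triangle_signed_distance(x, y, verts) * h0) > 0.5
    return mask


def _lesion_mask(spec: PhantomSpec, scene: _Scene) -> np.ndarray:
    w0, h0 = spec.base_resolution
    x, y = _pixel_grid(h0, w0)
    if scene.lesion_segment is None:
        return np.zeros((h0, w0), dtype=bool)
    verts = scene.wedges[scene.lesion_host]
    aw = _coverage(_triangle_signed_distance(x, y, verts) * h0)
    p0, p1 = scene.lesion_segment
    half_px = 0.5 * spec.lesion_thickness_px
    al = _coverage(half_px - _segment_distance(x, y, p0, p1) * h0) * aw
    mask = al > 0.5
    if not mask.any():
        # guarantee label/mask consistency: mark the in-wedge pixel nearest
        # to the streak (sub-pixel streaks at very small base resolutions)
        score = np.where(aw > 0.5, -_segment_distance(x, y, p0, p1), -np.inf)
        mask.flat[int(score.argmax())] = True
    return mask


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_case(spec: PhantomSpec, case_index: int) -> PhantomCase:
    """Render one phantom case, deterministic given ``(spec.seed, case_index)``."""
    if case_index < 0:
        raise ValueError(f"case_index must be >= 0, got {case_index}")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, case_index)))
    injured = bool(rng.random() < spec.lesion_probability)
    scene = _sample_scene(spec, rng, injured)
    levels = [_render_level(spec, scene, s, rng) for s in _LEVEL_SCALES]
    mask = _lesion_mask(spec, scene)
    case_id = f"case_{case_index:05d}"
    pyramid = PyramidImage(low=levels[0], mid=levels[1], high=levels[2],
                           case_id=case_id)
    horn = scene.horns[scene.lesion_host] if injured else None
    return PhantomCase(pyramid=pyramid, label=int(injured), lesion_mask=mask,
                       horn=horn, case_index=case_index,
                       wedge_mask=_wedge_mask(spec, scene))


def generate_dataset(spec: PhantomSpec, n_cases: int) -> list[PhantomCase]:
    """Generate ``n_cases`` phantoms indexed ``0..n_cases-1``."""
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    return [generate_case(spec, i) for i in range(n_cases)]


def write_dataset(cases: list[PhantomCase], out_dir) -> Path:
    """Write PNGs per pyramid level plus mask and a manifest CSV.

    Returns the manifest path. Layout: ``<case_id>_{low,mid,high,mask}.png``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "label", "horn", "low", "mid", "high", "mask"])
        for case in cases:
            cid = case.pyramid.case_id
            paths = {}
            for name in ("low", "mid", "high"):
                p = out / f"{cid}_{name}.png"
                save_png(p, getattr(case.pyramid, name))
                paths[name] = p.name
            mask_path = out / f"{cid}_mask.png"
            save_png(mask_path, case.lesion_mask.astype(np.float32))
            writer.writerow([
                cid, case.label, case.horn or "", paths["low"], paths["mid"],
                paths["high"], mask_path.name,
            ])
    return manifest
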