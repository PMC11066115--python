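"""Synthetic UHF-like B-mode cine loops with known vessel geometry.

The simulator reproduces the contrast mechanism that virtual
angiography exploits: a *static* speckled background (the tissue) with
*moving* bright scatterers (flowing erythrocytes) confined to vessel
lumens.  It makes no attempt at acoustically accurate speckle — no
point-spread function, attenuation or out-of-plane motion — but it
generates exactly the ingredients the pipeline is sensitive to, together
with analytic ground truth (vessel mask, centerlines, branch count) for
recovery tests.

Scene model
-----------
* Background: ``clip(mean + Rayleigh(sigma) speckle, 0, 1)``, optionally
  Gaussian-blurred to give the speckle a grain size; frozen across
  frames, apart from optional additive Gaussian frame jitter.
* Vessels: tubes of constant half-width around polyline centerlines.
  Scatterers are seeded by a Poisson process in each tube, advected
  ``flow_px_per_frame`` along the centerline every frame (wrapping at
  the tube ends — a conveyor, so density is stationary), and rendered
  as Gaussian blobs (sd = half_width / 2, amplitude 0.5, truncated at
  3 sd) added to the background and clipped to [0, 1].
* Randomness: one seed per scene, split deterministically between
  speckle, per-vessel scatterers and jitter, so e.g. changing
  ``n_frames`` does not change the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .annotation import CenterlineSet
from .cine_io import CineLoop, RoiMask
from .exceptions import ValidationError
from .vessel_metrics import _count_branch_points_from_endpoints, polyline_length

__all__ = [
    "VesselSpec",
    "SpeckleSpec",
    "SynthScene",
    "GroundTruth",
    "render_scene",
    "default_benchmark_scene",
    "BENCHMARK_KINDS",
]

BLOB_AMPLITUDE = 0.5
BLOB_TRUNCATION_SD = 3.0


@dataclass
class VesselSpec:
    """One tubular vessel: centerline polyline plus flow parameters."""

    centerline: np.ndarray  # (K, 2) (row, col) points
    half_width_px: float = 4.0
    flow_px_per_frame: float = 2.0
    scatterer_density: float = 4.0  # scatterers per 100 px^2 of lumen

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=np.float64)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValidationError("vessel centerline needs >= 2 (row, col) points")
        if self.half_width_px <= 0:
            raise ValidationError("half_width_px must be > 0")
        if self.flow_px_per_frame < 0 or self.scatterer_density < 0:
            raise ValidationError("flow and scatterer density must be >= 0")

    @property
    def length_px(self) -> float:
        return polyline_length(self.centerline)


@dataclass
class SpeckleSpec:
    """Static background speckle: mean level plus Rayleigh grain."""

    mean: float = 0.25
    rayleigh_sigma: float = 0.08
    blur_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.mean < 1:
            raise ValidationError("speckle mean must be in (0, 1)")
        if self.rayleigh_sigma <= 0 or self.blur_sigma_px < 0:
            raise ValidationError("rayleigh_sigma > 0 and blur_sigma_px >= 0 required")


@dataclass
class SynthScene:
    """Parametric ground-truth description of a synthetic cine loop."""

    shape: Tuple[int, int] = (256, 256)
    vessels: List[VesselSpec] = field(default_factory=list)
    speckle: SpeckleSpec = field(default_factory=SpeckleSpec)
    background_jitter_sd: float = 0.0
    n_frames: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.background_jitter_sd < 0:
            raise ValidationError("background_jitter_sd must be >= 0")
        m, n = self.shape
        for v in self.vessels:
            w = v.half_width_px
            r, c = v.centerline[:, 0], v.centerline[:, 1]
            if (r.min() - w < 0 or r.max() + w > m - 1
                    or c.min() - w < 0 or c.max() + w > n - 1):
                raise ValidationError("vessel tube extends outside the frame")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> Dict:
        return {
            "shape": list(self.shape),
            "n_frames": self.n_frames,
            "seed": self.seed,
            "background_jitter_sd": self.background_jitter_sd,
            "speckle": {
                "mean": self.speckle.mean,
                "rayleigh_sigma": self.speckle.rayleigh_sigma,
                "blur_sigma_px": self.speckle.blur_sigma_px,
            },
            "vessels": [
                {
                    "centerline": [[float(r), float(c)] for r, c in v.centerline],
                    "half_width_px": v.half_width_px,
                    "flow_px_per_frame": v.flow_px_per_frame,
                    "scatterer_density": v.scatterer_density,
                }
                for v in self.vessels
            ],
        }

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, doc: Dict) -> "SynthScene":
        return cls(
            shape=tuple(doc.get("shape", (256, 256))),
            vessels=[
                VesselSpec(
                    centerline=np.asarray(v["centerline"], dtype=np.float64),
                    half_width_px=float(v.get("half_width_px", 4.0)),
                    flow_px_per_frame=float(v.get("flow_px_per_frame", 2.0)),
                    scatterer_density=float(v.get("scatterer_density", 4.0)),
                )
                for v in doc.get("vessels", [])
            ],
            speckle=SpeckleSpec(**doc.get("speckle", {})),
            background_jitter_sd=float(doc.get("background_jitter_sd", 0.0)),
            n_frames=int(doc.get("n_frames", 64)),
            seed=int(doc.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SynthScene":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Analytic truth derived from the scene, for recovery tests."""

    vessel_mask: np.ndarray  # bool (M, N); pixels within half_width of a centerline
    centerlines: CenterlineSet
    branch_count: int

    def roi(self, label: str = "microvessel") -> RoiMask:
        return RoiMask(mask=self.vessel_mask, label=label)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _arclength_param(centerline: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s, seg


def _points_at(centerline: np.ndarray, s_values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Positions and unit normals at arc lengths along a polyline."""
    s, seg = _arclength_param(centerline)
    total = s[-1]
    sv = np.clip(s_values, 0.0, total)
    rows = np.interp(sv, s, centerline[:, 0])
    cols = np.interp(sv, s, centerline[:, 1])
    idx = np.clip(np.searchsorted(s, sv, side="right") - 1, 0, len(seg) - 1)
    tang = np.diff(centerline, axis=0)[idx]
    tang = tang / np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return np.column_stack([rows, cols]), normals


def _distance_to_polyline(shape: Tuple[int, int], centerline: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance to a polyline (exact point-segment)."""
    m, n = shape
    rr, cc = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    pts = np.stack([rr, cc], axis=-1).astype(np.float64)  # (M, N, 2)
    dist = np.full((m, n), np.inf)
    for a, b in zip(centerline[:-1], centerline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            proj = np.zeros(pts.shape[:2])
        else:
            proj = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
        closest = a + proj[..., None] * ab
        dist = np.minimum(dist, np.linalg.norm(pts - closest, axis=-1))
    return dist


def _render_blobs(image: np.ndarray, centers: np.ndarray, sd: float) -> None:
    """Add truncated Gaussian blobs (in place) at sub-pixel centers."""
    m, n = image.shape
    radius = BLOB_TRUNCATION_SD * sd
    for r0, c0 in centers:
        r_lo = max(int(np.floor(r0 - radius)), 0)
        r_hi = min(int(np.ceil(r0 + radius)), m - 1)
        c_lo = max(int(np.floor(c0 - radius)), 0)
        c_hi = min(int(np.ceil(c0 + radius)), n - 1)
        if r_hi < r_lo or c_hi < c_lo:
            continue
        rr = np.arange(r_lo, r_hi + 1)[:, None] - r0
        cc = np.arange(c_lo, c_hi + 1)[None, :] - c0
        d2 = rr ** 2 + cc ** 2
        blob = BLOB_AMPLITUDE * np.exp(-d2 / (2.0 * sd ** 2))
        blob[d2 > radius ** 2] = 0.0  # hard truncation keeps support bounded
        image[r_lo:r_hi + 1, c_lo:c_hi + 1] += blob


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_scene(scene: SynthScene) -> Tuple[CineLoop, GroundTruth]:
    """Render a scene to a cine loop plus its analytic ground truth.

    Identical scenes (including seed) render bit-identically.
    """
    m, n = scene.shape
    bg_rng = np.random.default_rng([scene.seed, 0])
    jitter_rng = np.random.default_rng([scene.seed, 2])

    background = scene.speckle.mean + bg_rng.rayleigh(
        scale=scene.speckle.rayleigh_sigma, size=(m, n)
    )
    if scene.speckle.blur_sigma_px > 0:
        background = gaussian_filter(background, sigma=scene.speckle.blur_sigma_px)
    background = np.clip(background, 0.0, 1.0)

    # seed scatterers per vessel: (arc length, lateral offset) pairs
    scatterers = []
    for i, vessel in enumerate(scene.vessels):
        rng = np.random.default_rng([scene.seed, 1, i])
        lumen_area = vessel.length_px * 2.0 * vessel.half_width_px
        count = rng.poisson(lumen_area * vessel.scatterer_density / 100.0)
        s0 = rng.uniform(0.0, vessel.length_px, size=count)
        offsets = rng.uniform(-vessel.half_width_px, vessel.half_width_px, size=count)
        scatterers.append((vessel, s0, offsets))

    frames = np.empty((scene.n_frames, m, n), dtype=np.float64)
    for t in range(scene.n_frames):
        frame = background.copy()
        for vessel, s0, offsets in scatterers:
            if len(s0) == 0:
                continue
            s_t = np.mod(s0 + t * vessel.flow_px_per_frame, vessel.length_px)
            positions, normals = _points_at(vessel.centerline, s_t)
            centers = positions + offsets[:, None] * normals
            _render_blobs(frame, centers, sd=vessel.half_width_px / 2.0)
        frame = np.clip(frame, 0.0, 1.0)
        if scene.background_jitter_sd > 0:
            frame = np.clip(
                frame + jitter_rng.normal(0.0, scene.background_jitter_sd, size=(m, n)),
                0.0, 1.0,
            )
        frames[t] = frame

    # analytic ground truth
    mask = np.zeros((m, n), dtype=bool)
    gt_curves = []
    for vessel in scene.vessels:
        mask |= _distance_to_polyline((m, n), vessel.centerline) <= vessel.half_width_px
        s_samples = np.arange(0.0, vessel.length_px + 0.5, 1.0)
        s_samples[-1] = vessel.length_px
        positions, _ = _points_at(vessel.centerline, s_samples)
        gt_curves.append(positions)
    truth = GroundTruth(
        vessel_mask=mask,
        centerlines=CenterlineSet(curves=gt_curves, source="manual"),
        branch_count=_count_branch_points_from_endpoints(
            [v.centerline for v in scene.vessels]
        ),
    )
    return CineLoop(frames=frames), truth


# ---------------------------------------------------------------------------
# Frozen benchmark scenes
# ---------------------------------------------------------------------------

BENCHMARK_KINDS = ("single_tube", "bifurcation", "tree3")


def default_benchmark_scene(
    kind: str, seed: int = 0, background_jitter_sd: float = 0.0
) -> SynthScene:
    """One of three frozen 256x256, 64-frame benchmark scenes.

    * ``single_tube``: one straight horizontal tube of half-width 4 px,
      centerline length 200 px, flow 2 px/frame; 0 branch points.
    * ``bifurcation``: a Y of three tubes meeting at one point;
      1 branch point.
    * ``tree3``: a binary tree of seven tubes; 3 branch points.

    All tubes use half-width 4 px, flow 2 px/frame and scatterer density
    4 per 100 px^2; speckle mean 0.25, Rayleigh sigma 0.08, blur 1 px.
    """
    def tube(points) -> VesselSpec:
        return VesselSpec(
            centerline=np.asarray(points, dtype=np.float64),
            half_width_px=4.0,
            flow_px_per_frame=2.0,
            scatterer_density=4.0,
        )

    if kind == "single_tube":
        vessels = [tube([(128, 28), (128, 228)])]
    elif kind == "bifurcation":
        vessels = [
            tube([(40, 128), (120, 128)]),
            tube([(120, 128), (210, 78)]),
            tube([(120, 128), (210, 178)]),
        ]
    elif kind == "tree3":
        vessels = [
            tube([(25, 128), (75, 128)]),
            tube([(75, 128), (140, 73)]),
            tube([(75, 128), (140, 183)]),
            tube([(140, 73), (215, 43)]),
            tube([(140, 73), (215, 103)]),
            tube([(140, 183), (215, 153)]),
            tube([(140, 183), (215, 213)]),
        ]
    else:
        raise ValidationError(
            f"unknown benchmark scene kind {kind!r}; expected one of {BENCHMARK_KINDS}"
        )
    return SynthScene(
        shape=(256, 256),
        vessels=vessels,
        speckle=SpeckleSpec(mean=0.25, rayleigh_sigma=0.08, blur_sigma_px=1.0),
        background_jitter_sd=background_jitter_sd,
        n_frames=64,
        seed=seed,
    )
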