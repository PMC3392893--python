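"""Parametric synthetic fundus scenes with known ground truth.

Renders the features the OD detector relies on: a circular illuminated field
of view, a bright vertical-oval optic disc, dark vessels with Gaussian
intensity cross-sections in two width classes (thick arcades, thin branches)
converging at the disc, optionally one bright vessel-free "exudate" blob, and
additive Gaussian noise.  Vessels follow arcade paths whose direction bends
away from vertical with arc length, phi(t) = phi_max * (1 - exp(-t / tau)):
parabolic near the disc (where the VDMF's convergence model is valid) and
straightening toward a near-horizontal run far from it, as real temporal
arcades do.

Pixel-accurate ground truth (disc center, 1-px vessel centerlines, and the
orientation bin of each centerline pixel) is returned with every scene, so
each pipeline stage and the end-to-end detector can be tested without
patient data.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.morphology import thin as _thin

from .vdmf import _angle_to_bin

__all__ = ["VesselSpec", "SceneSpec", "GroundTruth", "generate", "default_scene", "random_scene"]

# cross-section standard deviations of the two vessel width classes (px).
# Chosen so thick vessels are ~3.5 px wider than thin at half depth
# (full width at half depth = 2*sqrt(2 ln 2)*sigma).
THIN_STD = 1.4
THICK_STD = 2.9


@dataclass(frozen=True)
class VesselSpec:
    """One arcade vessel leaving the disc center.

    ``vertical_sign`` -1 runs upward (decreasing row), +1 downward;
    ``side_sign`` +1 bends toward increasing columns.  ``phi_max`` (radians)
    is the asymptotic angle from vertical, approached with e-folding arc
    length ``tau`` (px).  ``width`` is 'thin' or 'thick'.
    """

    vertical_sign: int
    side_sign: int
    phi_max: float
    tau: float
    length: float
    width: str = "thin"

    @property
    def sigma(self) -> float:
        return THICK_STD if self.width == "thick" else THIN_STD


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int] = (644, 968)
    fov_radius: float = 300.0
    od_center: tuple[int, int] = (322, 340)
    od_radii: tuple[float, float] = (62.0, 50.0)  # (vertical, horizontal)
    od_brightness: float = 115.0  # amplitude above background
    background: float = 140.0
    vessel_depth: float = 12.0
    # relative contrast of thin vessels (thin depth = fraction * vessel_depth)
    thin_depth_fraction: float = 1.0
    vessels: tuple[VesselSpec, ...] = ()
    exudate_center: tuple[int, int] | None = None
    exudate_radius: float = 12.0
    noise_std: float = 2.0
    seed: int = 0


@dataclass
class GroundTruth:
    od_center: tuple[int, int]
    centerline_mask: np.ndarray
    orientation_field: np.ndarray
    vessel_centerlines: list[np.ndarray]
    exudate_center: tuple[int, int] | None


DEFAULT_VESSELS: tuple[VesselSpec, ...] = (
    VesselSpec(-1, +1, math.radians(80), 90.0, 300.0, "thick"),
    VesselSpec(+1, +1, math.radians(80), 90.0, 300.0, "thick"),
    VesselSpec(-1, -1, math.radians(55), 120.0, 220.0, "thin"),
    VesselSpec(+1, -1, math.radians(55), 120.0, 220.0, "thin"),
    VesselSpec(-1, +1, math.radians(70), 60.0, 160.0, "thin"),
    VesselSpec(+1, +1, math.radians(70), 60.0, 160.0, "thin"),
)


def default_scene(seed: int = 0) -> SceneSpec:
    """The reference scene: disc nasal of center, two thick temporal arcades,
    four thin branches, one exudate blob temporal-inferior of the disc."""
    return SceneSpec(vessels=DEFAULT_VESSELS, exudate_center=(382, 560), seed=seed)


def random_scene(seed: int) -> SceneSpec:
    """A seeded variant of the default scene: jittered disc position, vessel
    geometry, and exudate placement."""
    rng = np.random.default_rng(seed)
    base = default_scene(seed)
    od = (
        int(base.od_center[0] + rng.integers(-25, 26)),
        int(base.od_center[1] + rng.integers(-25, 26)),
    )
    vessels = tuple(
        replace(
            v,
            phi_max=float(v.phi_max * rng.uniform(0.85, 1.15)),
            tau=float(v.tau * rng.uniform(0.85, 1.15)),
            length=float(v.length * rng.uniform(0.9, 1.1)),
        )
        for v in base.vessels
    )
    ang = rng.uniform(0, 2 * math.pi)
    dist = rng.uniform(160, 240)
    fr, fc = base.shape[0] / 2.0, base.shape[1] / 2.0
    ex = (od[0] + dist * math.sin(ang), od[1] + dist * math.cos(ang))
    # keep the exudate well inside the FOV
    d_fov = math.hypot(ex[0] - fr, ex[1] - fc)
    limit = base.fov_radius - 2 * base.exudate_radius - 10
    if d_fov > limit:
        ex = (fr + (ex[0] - fr) * limit / d_fov, fc + (ex[1] - fc) * limit / d_fov)
    return replace(base, od_center=od, vessels=vessels,
                   exudate_center=(int(round(ex[0])), int(round(ex[1]))), seed=seed)


def _trace_vessel(
    spec: VesselSpec, start: tuple[int, int], fov_center: tuple[float, float],
    fov_radius: float, step: float = 0.35
) -> np.ndarray:
    """Integrate the arcade path; returns an (n, 3) array of (row, col, angle)
    samples, where angle is the tangent direction from vertical."""
    pts = []
    r, c = float(start[0]), float(start[1])
    t = 0.0
    while t <= spec.length:
        phi = spec.phi_max * (1.0 - math.exp(-t / spec.tau))
        dr = spec.vertical_sign * math.cos(phi)
        dc = spec.side_sign * math.sin(phi)
        pts.append((r, c, math.atan2(dc, dr) % math.pi))
        r += step * dr
        c += step * dc
        t += step
        if math.hypot(r - fov_center[0], c - fov_center[1]) > fov_radius - 4.0:
            break
    return np.array(pts)


def _stamp_depth(depth_field: np.ndarray, samples: np.ndarray, sigma: float,
                 depth: float) -> None:
    """Max-accumulate the Gaussian cross-section profile of a traced vessel."""
    w = int(math.ceil(4.0 * sigma))
    H, W = depth_field.shape
    for r, c, _ in samples:
        r0, c0 = int(round(r)), int(round(c))
        ra, rb = max(0, r0 - w), min(H, r0 + w + 1)
        ca, cb = max(0, c0 - w), min(W, c0 + w + 1)
        if ra >= rb or ca >= cb:
            continue
        rr = np.arange(ra, rb, dtype=np.float64) - r
        cc = np.arange(ca, cb, dtype=np.float64) - c
        d2 = rr[:, None] ** 2 + cc[None, :] ** 2
        np.maximum(
            depth_field[ra:rb, ca:cb],
            depth * np.exp(-d2 / (2.0 * sigma**2)),
            out=depth_field[ra:rb, ca:cb],
        )


def generate(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the scene to an 8-bit RGB image plus pixel-accurate ground truth."""
    H, W = spec.shape
    fr, fc = H / 2.0, W / 2.0
    if math.hypot(spec.od_center[0] - fr, spec.od_center[1] - fc) > spec.fov_radius - max(spec.od_radii):
        raise ValueError("OD must lie entirely inside the field of view")

    rows, cols = np.meshgrid(np.arange(H, dtype=np.float64),
                             np.arange(W, dtype=np.float64), indexing="ij")
    fov = (rows - fr) ** 2 + (cols - fc) ** 2 <= spec.fov_radius**2

    # bright vertical-oval disc with a flat core and a smooth logistic edge
    rv, rh = spec.od_radii
    e = np.sqrt(((rows - spec.od_center[0]) / rv) ** 2
                + ((cols - spec.od_center[1]) / rh) ** 2)
    od_bump = spec.od_brightness / (1.0 + np.exp((e - 1.0) / 0.06))

    exu_bump = np.zeros_like(od_bump)
    if spec.exudate_center is not None:
        e2 = np.hypot(rows - spec.exudate_center[0], cols - spec.exudate_center[1])
        exu_bump = spec.od_brightness / (1.0 + np.exp((e2 / spec.exudate_radius - 1.0) / 0.15))

    depth_field = np.zeros((H, W))
    centerlines: list[np.ndarray] = []
    orient_field = np.zeros((H, W), dtype=np.int32)
    combined = np.zeros((H, W), dtype=bool)
    for v in spec.vessels:
        samples = _trace_vessel(v, spec.od_center, (fr, fc), spec.fov_radius)
        if samples.size == 0:
            continue
        depth = spec.vessel_depth * (1.0 if v.width == "thick" else spec.thin_depth_fraction)
        _stamp_depth(depth_field, samples, v.sigma, depth)
        mask = np.zeros((H, W), dtype=bool)
        rr = np.clip(np.rint(samples[:, 0]).astype(int), 0, H - 1)
        cc = np.clip(np.rint(samples[:, 1]).astype(int), 0, W - 1)
        bins = _angle_to_bin(samples[:, 2])
        mask[rr, cc] = True
        # rasterizing dense samples leaves staircase doublets; thin to 1 px
        mask = _thin(mask)
        orient_field[rr, cc] = np.where(mask[rr, cc], bins, orient_field[rr, cc])
        centerlines.append(mask)
        combined |= mask
    orient_field[~combined] = 0

    green = np.where(fov, spec.background + od_bump + exu_bump - depth_field, 0.0)
    red = np.where(fov, 175.0 + 0.55 * od_bump + 0.4 * exu_bump - 0.3 * depth_field, 0.0)
    blue = np.where(fov, 35.0 + 0.2 * od_bump, 0.0)

    rng = np.random.default_rng(spec.seed)
    rgb = np.stack([red, green, blue], axis=-1)
    if spec.noise_std > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_std, rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        od_center=spec.od_center,
        centerline_mask=combined,
        orientation_field=orient_field,
        vessel_centerlines=centerlines,
        exudate_center=spec.exudate_center,
    )
    return rgb, truth
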