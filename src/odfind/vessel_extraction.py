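"""Stage 1: vessel map and vessels' directional map.

Pipeline: normalized green channel -> per-scale maximal oriented matched-filter
responses -> scale production (product of responses at two scales, which
reinforces structure present at both scales and quadratically suppresses
single-scale noise) -> double (hysteresis) thresholding per scale pair ->
logical-OR combination of the pair maps -> morphological thinning to
one-pixel-wide centerlines -> per-pixel orientation of the globally maximal
response, masked to the centerlines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage.morphology import thin as _skimage_thin

from .kernels import FilterKernel

__all__ = [
    "NormalizedImage",
    "ResponseStack",
    "DirectionalMap",
    "normalize_green",
    "respond",
    "scale_production",
    "double_threshold",
    "combine_pairs",
    "thin",
    "directional_map",
]


@dataclass
class NormalizedImage:
    """Green channel min-max normalized to [0, 1] inside the circular FOV."""

    values: np.ndarray
    fov_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.fov_mask.shape:
            raise ValueError("values and fov_mask must share a shape")


@dataclass
class ResponseStack:
    """Per-scale orientation-maximal filter response.

    ``response``: max over orientations of the (sign-corrected) convolution
    response.  ``orientation``: argmax orientation index in 1..n_orientations.
    """

    response: np.ndarray
    orientation: np.ndarray
    scale: float = 0.0


@dataclass
class DirectionalMap:
    """Per-pixel orientation index (1..n) on vessel centerlines, 0 elsewhere."""

    orientation_index: np.ndarray
    centerline_mask: np.ndarray


def estimate_fov_mask(channel: np.ndarray, rel_threshold: float = 0.1) -> np.ndarray:
    """Circular field-of-view mask: bright pixels of `channel`, largest
    connected component, holes filled."""
    thr = rel_threshold * float(channel.max())
    rough = channel > thr
    if not rough.any():
        raise ValueError("empty field of view: no pixels above the FOV threshold")
    labels, n = ndi.label(rough)
    if n > 1:
        sizes = ndi.sum_labels(rough, labels, index=np.arange(1, n + 1))
        rough = labels == (1 + int(np.argmax(sizes)))
    return ndi.binary_fill_holes(rough)


def normalize_green(rgb_image: np.ndarray) -> NormalizedImage:
    """Extract the green channel, estimate the FOV, min-max rescale to [0, 1].

    The FOV is estimated from the red channel (brightest, most uniform inside
    the illuminated circle).  Outside-FOV pixels are set to 0.  A constant
    green channel inside the FOV maps to all zeros.  Grayscale input is
    accepted with a warning and treated as the green channel itself.
    """
    img = np.asarray(rgb_image)
    if img.ndim == 2:
        warnings.warn(
            "grayscale input: treating the single channel as the green channel",
            stacklevel=2,
        )
        green = img.astype(np.float64)
        fov_src = green
    elif img.ndim == 3 and img.shape[2] >= 3:
        green = img[:, :, 1].astype(np.float64)
        fov_src = img[:, :, 0].astype(np.float64)
    else:
        raise ValueError(f"expected an RGB or grayscale image, got shape {img.shape}")

    fov = estimate_fov_mask(fov_src)
    vals = np.zeros_like(green)
    inside = green[fov]
    lo, hi = float(inside.min()), float(inside.max())
    if hi > lo:
        vals[fov] = (green[fov] - lo) / (hi - lo)
    return NormalizedImage(values=vals, fov_mask=fov)


def _group_by_scale(bank: list[FilterKernel]) -> list[list[FilterKernel]]:
    groups: list[list[FilterKernel]] = []
    for k in bank:
        if groups and groups[-1][0].spec.s == k.spec.s and groups[-1][0].spec.L == k.spec.L:
            groups[-1].append(k)
        else:
            groups.append([k])
    return groups


def respond(
    im: NormalizedImage, bank: list[FilterKernel], vessels_dark: bool = True
) -> list[ResponseStack]:
    """Orientation-maximal matched-filter response per scale.

    Border handling: the image is reflect-padded by each scale's kernel radius
    before convolution, and responses within one kernel radius of the FOV rim
    (or outside the FOV) are zeroed to suppress rim artifacts.  With
    ``vessels_dark`` the response sign is flipped so that dark-on-bright
    vessels give positive responses.
    """
    out: list[ResponseStack] = []
    # distance to the FOV boundary, for rim erosion
    dist = ndi.distance_transform_edt(im.fov_mask)
    sign = -1.0 if vessels_dark else 1.0
    for group in _group_by_scale(bank):
        rad = max(k.radius for k in group)
        padded = np.pad(im.values, rad, mode="reflect")
        best = None
        best_orient = None
        for idx, kern in enumerate(group, start=1):
            resp = sign * fftconvolve(padded, kern.weights, mode="same")
            resp = resp[rad:-rad, rad:-rad]
            if best is None:
                best = resp
                best_orient = np.full(resp.shape, idx, dtype=np.int32)
            else:
                better = resp > best
                best = np.where(better, resp, best)
                best_orient[better] = idx
        interior = dist > rad
        best[~interior] = 0.0
        out.append(
            ResponseStack(response=best, orientation=best_orient, scale=group[0].spec.s)
        )
    return out


def scale_production(Ri, Rj) -> np.ndarray:
    """Scale production: elementwise product of two scale responses."""
    a = Ri.response if isinstance(Ri, ResponseStack) else np.asarray(Ri)
    b = Rj.response if isinstance(Rj, ResponseStack) else np.asarray(Rj)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a * b


def double_threshold(
    P: np.ndarray,
    t_high_quantile: float = 0.975,
    t_low_fraction: float = 0.5,
    fov_mask: np.ndarray | None = None,
    connectivity: int = 2,
) -> np.ndarray:
    """Hysteresis binarization of a (scale-product) response map.

    Strong pixels: ``P >= Qh`` where ``Qh`` is the ``t_high_quantile``
    quantile of P over the FOV.  Weak pixels: ``P >= t_low_fraction * Qh``.
    The output keeps strong pixels plus weak pixels 8-connected (transitively)
    to a strong pixel.  A degenerate (constant) map yields all background.
    """
    if not (0.0 < t_high_quantile < 1.0):
        raise ValueError("t_high_quantile must be in (0, 1)")
    if not (0.0 < t_low_fraction < 1.0):
        raise ValueError("t_low_fraction must be in (0, 1)")
    P = np.asarray(P, dtype=np.float64)
    fov = np.ones(P.shape, bool) if fov_mask is None else fov_mask
    inside = P[fov]
    if inside.size == 0 or inside.max() == inside.min():
        return np.zeros(P.shape, bool)
    qh = float(np.quantile(inside, t_high_quantile))
    strong = (P >= qh) & fov
    weak = (P >= t_low_fraction * qh) & fov
    if not strong.any():
        return np.zeros(P.shape, bool)
    structure = ndi.generate_binary_structure(2, connectivity)
    labels, _ = ndi.label(weak, structure=structure)
    keep = np.unique(labels[strong])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def combine_pairs(binary_a: np.ndarray, binary_b: np.ndarray) -> np.ndarray:
    """Logical OR of two binary vessel maps (e.g. the (s1,s2) and (s3,s4)
    scale-product maps)."""
    if binary_a.shape != binary_b.shape:
        raise ValueError("shape mismatch")
    return binary_a | binary_b


def thin(binary: np.ndarray) -> np.ndarray:
    """Topology-preserving morphological thinning to a 1-px-wide skeleton."""
    return _skimage_thin(np.asarray(binary, bool))


def directional_map(
    stacks: list[ResponseStack], centerline: np.ndarray
) -> DirectionalMap:
    """Vessels' directional map: at each centerline pixel, the orientation of
    the globally maximal response across all scales; 0 off the centerline."""
    if not stacks:
        raise ValueError("at least one response stack is required")
    responses = np.stack([s.response for s in stacks])
    orients = np.stack([s.orientation for s in stacks])
    winner = np.argmax(responses, axis=0)
    chosen = np.take_along_axis(orients, winner[None], axis=0)[0]
    centerline = np.asarray(centerline, bool)
    return DirectionalMap(
        orientation_index=np.where(centerline, chosen, 0).astype(np.int32),
        centerline_mask=centerline,
    )
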