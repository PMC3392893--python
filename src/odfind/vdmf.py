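"""Stage 2: Vessels' Directional Matched Filter (VDMF).

At the optic disc the retinal vessels exit roughly vertically and bend
horizontally with distance — the classic vascular arch.  The VDMF encodes the
expected vessel orientation around the disc center as a 9x9 grid of
orientation codes (1..8, eight equally spaced orientation bins over [0, pi)),
generated here from a parabolic convergence model: the vessel through offset
(dr, dc) from the center belongs to the parabola family ``dc = k*dr**2`` and
has tangent direction proportional to ``(dr, 2*curvature*dc)``.

The base grid is bilinearly resized (corner-aligned) to one or more working
dimensions — 61x21 and 121x41 by default, covering small and medium-to-large
disc vessel maps.  Each candidate pixel is scored by the accumulated circular
orientation difference between the templates centered on it and the vessels'
directional map; the candidate with the least accumulated difference is the
detected OD center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .od_candidates import Candidate, CandidateSet
from .vessel_extraction import DirectionalMap

__all__ = [
    "VDMFTemplate",
    "MatchScore",
    "DetectionResult",
    "ODNotFoundError",
    "build_base_template",
    "resize_template",
    "build_templates",
    "orientation_distance",
    "score_candidate",
    "score_candidates",
    "select_center",
]

N_BINS = 8
BIN_WIDTH = math.pi / N_BINS


class ODNotFoundError(RuntimeError):
    """No candidate with a finite match score (empty or vessel-free set)."""


@dataclass
class VDMFTemplate:
    """Base 9x9 orientation-code grid plus its resized real-valued instances."""

    base: np.ndarray
    resized: list[np.ndarray] = field(default_factory=list)


@dataclass
class MatchScore:
    center: tuple[int, int]
    per_template: list[float]
    total: float
    n_compared: int


@dataclass
class DetectionResult:
    od_center: tuple[int, int]
    scores: list[MatchScore]
    best: MatchScore


def _angle_to_bin(theta: np.ndarray) -> np.ndarray:
    """Map angles (radians, measured from the vertical axis) to bins 1..8."""
    k = np.rint(np.mod(theta, math.pi) / BIN_WIDTH).astype(int) % N_BINS
    return k + 1


def build_base_template(arch_curvature: float = 1.0, size: int = 9) -> np.ndarray:
    """9x9 orientation-code grid from the parabolic vascular-arch model.

    The center cell and the central column are vertical (bin 1: vessels exit
    the disc vertically); cells on the horizontal midline are horizontal; in
    between, the tangent of the parabola through the cell sets the bin.
    ``arch_curvature`` scales how quickly vessels bend away from vertical.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("template size must be an odd positive integer")
    half = size // 2
    dr, dc = np.meshgrid(
        np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij"
    )
    theta = np.arctan2(2.0 * arch_curvature * dc, dr)
    return _angle_to_bin(theta)


def resize_template(base: np.ndarray, target_dims: tuple[int, int]) -> np.ndarray:
    """Corner-aligned bilinear resize of the orientation-code grid.

    Cells are treated as samples at cell centers; the four corner values are
    preserved for any target shape.  Output values are reals in [1, 8].
    """
    rows, cols = target_dims
    if rows < 1 or cols < 1:
        raise ValueError(f"target dims must be positive, got {target_dims}")
    base = np.asarray(base, dtype=np.float64)
    if (rows, cols) == base.shape:
        return base.copy()
    rr = np.linspace(0.0, base.shape[0] - 1.0, rows)
    cc = np.linspace(0.0, base.shape[1] - 1.0, cols)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    return map_coordinates(base, [grid_r, grid_c], order=1, mode="nearest")


def build_templates(
    arch_curvature: float = 1.0,
    dims: tuple[tuple[int, int], ...] = ((61, 21), (121, 41)),
    base: np.ndarray | None = None,
) -> VDMFTemplate:
    """Build the base template (or accept one, e.g. loaded from CSV) and its
    resized instances."""
    if base is None:
        base = build_base_template(arch_curvature)
    base = np.asarray(base)
    if base.ndim != 2 or not np.isin(base, np.arange(1, N_BINS + 1)).all():
        raise ValueError("base template must be a 2-D grid of codes in 1..8")
    return VDMFTemplate(
        base=base.astype(int), resized=[resize_template(base, d) for d in dims]
    )


def orientation_distance(a, b) -> np.ndarray:
    """Circular distance between orientation codes on the 8-bin circle,
    in radians: d(a, b) = min(|a-b|, 8-|a-b|) * pi/8.

    Codes are angles modulo pi, so bins 1 and 8 are adjacent (d = pi/8), not
    maximally distant as a raw absolute difference would make them.
    """
    d = np.abs(np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64))
    return np.minimum(d, N_BINS - d) * BIN_WIDTH


def score_candidate(
    candidate: Candidate | tuple[int, int],
    templates: VDMFTemplate,
    dmap: DirectionalMap,
) -> MatchScore:
    """Mean circular orientation difference between each template, centered on
    the candidate, and the directional map.

    Only template cells coinciding with vessel centerline pixels
    (orientation index > 0) are compared; cells off the image are ignored.
    A template with zero compared pixels scores +inf, so bright vessel-free
    blobs (exudates) are never selected.  ``total`` sums the per-template
    means.
    """
    r, c = candidate.center if isinstance(candidate, Candidate) else candidate
    omap = dmap.orientation_index
    per: list[float] = []
    n_total = 0
    for tmpl in templates.resized:
        th, tw = tmpl.shape
        hr, hc = th // 2, tw // 2
        r0, r1 = max(0, r - hr), min(omap.shape[0], r + hr + 1)
        c0, c1 = max(0, c - hc), min(omap.shape[1], c + hc + 1)
        sub = omap[r0:r1, c0:c1]
        tsub = tmpl[r0 - (r - hr) : th - ((r + hr + 1) - r1),
                    c0 - (c - hc) : tw - ((c + hc + 1) - c1)]
        valid = sub > 0
        n = int(valid.sum())
        n_total += n
        if n == 0:
            per.append(math.inf)
        else:
            per.append(float(orientation_distance(tsub[valid], sub[valid]).mean()))
    return MatchScore(
        center=(int(r), int(c)),
        per_template=per,
        total=float(sum(per)),
        n_compared=n_total,
    )


def score_candidates(
    cset: CandidateSet, templates: VDMFTemplate, dmap: DirectionalMap
) -> list[MatchScore]:
    return [score_candidate(c, templates, dmap) for c in cset.candidates]


def select_center(scores: list[MatchScore]) -> DetectionResult:
    """Pick the candidate with least accumulated difference as the OD center.

    Ties are broken by lexicographic (row, col) order for determinism.
    """
    finite = [s for s in scores if math.isfinite(s.total)]
    if not finite:
        raise ODNotFoundError(
            f"no OD found: {len(scores)} candidate(s), none with vessels under "
            "the matching templates"
        )
    best = min(finite, key=lambda s: (s.total, s.center))
    return DetectionResult(od_center=best.center, scores=scores, best=best)
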