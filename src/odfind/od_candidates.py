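"""Optic-disc vessel candidates.

The optic disc is brighter than the surrounding retina, so vessel centerline
pixels that are also bright (normalized intensity >= 0.9 by default) are kept
as OD vessel candidates.  Each candidate carries a 51x51 window of the
directional map around it, zero-padded at image borders; the window is the
feature matched against the vessels' directional template in stage 2.

Bright vessel-free lesions (hard exudates) may pass the intensity gate only
if a centerline pixel falls inside them; candidates with no vessels under the
matching templates score infinitely badly downstream, so such blobs are
rejected by the matcher rather than by an explicit lesion detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vessel_extraction import DirectionalMap, NormalizedImage

__all__ = ["Candidate", "CandidateSet", "gate_by_intensity"]


@dataclass
class Candidate:
    center: tuple[int, int]
    window: np.ndarray = field(repr=False)


@dataclass
class CandidateSet:
    candidates: list[Candidate]
    image_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.candidates)

    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.candidates], dtype=int).reshape(-1, 2)


def gate_by_intensity(
    im: NormalizedImage,
    dmap: DirectionalMap,
    threshold: float = 0.9,
    window: int = 51,
) -> CandidateSet:
    """Keep centerline pixels whose normalized intensity is >= ``threshold``.

    Returns candidates in lexicographic (row, col) order, each with its
    ``window`` x ``window`` directional-map neighborhood (0-padded beyond the
    image borders).  An empty result is returned as-is; the caller decides
    the fallback.
    """
    if im.values.shape != dmap.orientation_index.shape:
        raise ValueError("image and directional map must share a shape")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd positive integer")
    keep = dmap.centerline_mask & im.fov_mask & (im.values >= threshold)
    rows, cols = np.nonzero(keep)
    half = window // 2
    padded = np.pad(dmap.orientation_index, half, mode="constant")
    cands = [
        Candidate(
            center=(int(r), int(c)),
            window=padded[r : r + window, c : c + window].copy(),
        )
        for r, c in zip(rows, cols)
    ]
    return CandidateSet(candidates=cands, image_shape=im.values.shape)
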