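"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: hysteresis linking is done
by breadth-first flood fill, and thinning by a literal Zhang-Suen two-pass
sweep.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy import ndimage as ndi


def hysteresis_flood_fill(P: np.ndarray, t_high_quantile: float, t_low_fraction: float) -> np.ndarray:
    """Brute-force double thresholding: BFS from strong pixels over the weak
    mask with 8-connectivity."""
    P = np.asarray(P, dtype=float)
    if P.max() == P.min():
        return np.zeros(P.shape, bool)
    qh = np.quantile(P, t_high_quantile)
    strong = P >= qh
    weak = P >= t_low_fraction * qh
    out = np.zeros(P.shape, bool)
    q = deque(zip(*np.nonzero(strong)))
    out[strong] = True
    H, W = P.shape
    while q:
        r, c = q.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and weak[rr, cc] and not out[rr, cc]:
                    out[rr, cc] = True
                    q.append((rr, cc))
    return out


def zhang_suen(img: np.ndarray) -> np.ndarray:
    """Classic two-subiteration Zhang-Suen thinning."""
    img = np.asarray(img, bool).copy()
    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            p = np.pad(img, 1)
            P2 = p[:-2, 1:-1]; P3 = p[:-2, 2:]; P4 = p[1:-1, 2:]; P5 = p[2:, 2:]
            P6 = p[2:, 1:-1]; P7 = p[2:, :-2]; P8 = p[1:-1, :-2]; P9 = p[:-2, :-2]
            seq = [P2, P3, P4, P5, P6, P7, P8, P9, P2]
            B = sum(x.astype(int) for x in seq[:8])
            A = sum(((~seq[i]) & seq[i + 1]).astype(int) for i in range(8))
            if step == 0:
                cond = ~(P2 & P4 & P6) & ~(P4 & P6 & P8)
            else:
                cond = ~(P2 & P4 & P8) & ~(P2 & P6 & P8)
            removable = img & (B >= 2) & (B <= 6) & (A == 1) & cond
            if removable.any():
                img[removable] = False
                changed = True
    return img


def skeletons_match_up_to_endpoints(a: np.ndarray, b: np.ndarray, max_extra: int = 4) -> bool:
    """True when two skeletons differ only by a few pixels, each adjacent to
    the common part (endpoint-erosion differences between thinning variants)."""
    diff = a ^ b
    if diff.sum() > max_extra:
        return False
    common_grown = ndi.binary_dilation(a & b, structure=np.ones((3, 3), bool))
    return bool((diff <= common_grown).all())


def make_vessel_image(size: int = 201, depth: float = 0.5, sigma: float = 1.5,
                      background: float = 0.8) -> np.ndarray:
    """Dark vertical vessel of Gaussian cross-section through the image center."""
    cols = np.arange(size, dtype=float)[None, :]
    center = (size - 1) / 2.0
    return background - depth * np.exp(-((cols - center) ** 2) / (2 * sigma**2)) * np.ones((size, 1))


def equivariance_bin_shifts(bank, rotation_deg: float = 22.5, size: int = 201):
    """Rotate a vertical synthetic vessel and return (bins before, bins after)
    on the (rotated) centerline, for the argmax orientation of the bank."""
    from scipy import ndimage as sndi

    from odfind.vessel_extraction import NormalizedImage, respond

    im0 = make_vessel_image(size)
    fov = np.ones((size, size), bool)
    center = (size - 1) // 2
    mask0 = np.zeros((size, size), bool)
    mask0[30:-30, center] = True

    def argmax_bins(values, mask):
        stacks = respond(NormalizedImage(values, fov), bank)
        resp = np.stack([s.response for s in stacks])
        oris = np.stack([s.orientation for s in stacks])
        w = np.argmax(resp, axis=0)
        chosen = np.take_along_axis(oris, w[None], axis=0)[0]
        return chosen[mask]

    before = argmax_bins(im0, mask0)
    im_rot = sndi.rotate(im0, rotation_deg, reshape=False, order=3, mode="nearest")
    mask_rot = sndi.rotate(mask0.astype(float), rotation_deg, reshape=False, order=1) > 0.5
    rows, colsg = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    interior = (rows > 40) & (rows < size - 40) & (colsg > 40) & (colsg < size - 40)
    after = argmax_bins(im_rot, mask_rot & interior)
    return before, after
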