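"""Independent brute-force oracles used to validate the implementation.

Everything here is written with explicit Python loops and exact Fraction
arithmetic, deliberately avoiding the vectorized code paths under test.
"""

from __future__ import annotations

import math
from fractions import Fraction


def round_half_away(u: float) -> int:
    """Nearest integer, halves away from zero."""
    if u >= 0:
        return int(math.floor(u + 0.5))
    return int(math.ceil(u - 0.5))


def bin_focus(coord, origin, spacing, shape):
    """Voxel index of a focus, or None if outside the grid."""
    idx = []
    for c, o, n in zip(coord, origin, shape):
        i = round_half_away((c - o) / spacing)
        if i < 0 or i >= n:
            return None
        idx.append(i)
    return tuple(idx)


def profile_by_hand(foci_by_subdomain, roi_voxels, brain_voxels, origin, spacing, shape):
    """Brute-force behavior statistics for a toy grid.

    ``foci_by_subdomain``: {subdomain_id: [(x, y, z), ...]} in mm.
    ``roi_voxels`` / ``brain_voxels``: sets of voxel index triples.
    Returns {subdomain_id: (p_o, p_e, z)} with p_o, p_e exact Fractions and
    z a float computed from them; the ROI is clipped to the brain.
    """
    roi = set(roi_voxels) & set(brain_voxels)
    p_e = Fraction(len(roi), len(brain_voxels))
    out = {}
    for sid, coords in foci_by_subdomain.items():
        in_grid = 0
        in_roi = 0
        for c in coords:
            v = bin_focus(c, origin, spacing, shape)
            if v is None:
                continue
            in_grid += 1
            if v in roi:
                in_roi += 1
        if in_grid == 0:
            out[sid] = (Fraction(0), p_e, float("nan"))
            continue
        p_o = Fraction(in_roi, in_grid)
        effect = p_o - p_e
        var = (p_o * (1 - p_o) + p_e * (1 - p_e)) / in_grid
        if var == 0:
            z = 0.0 if effect == 0 else math.copysign(float("inf"), float(effect))
        else:
            z = float(effect) / math.sqrt(float(var))
        out[sid] = (p_o, p_e, z)
    return out


def dilate_by_hand(voxels, shape, iterations):
    """Brute-force 3x3x3 dilation of a set of voxel index triples."""
    current = set(voxels)
    for _ in range(iterations):
        grown = set()
        for (i, j, k) in current:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        a, b, c = i + di, j + dj, k + dk
                        if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2]:
                            grown.add((a, b, c))
        current = grown
    return current


def lateralization_z_by_hand(n_left: int, n_right: int) -> float:
    """One-sample proportion z with exact rational intermediates."""
    n = n_left + n_right
    f = Fraction(n_left, n)
    num = f - Fraction(1, 2)
    var = f * (1 - f) / n
    return float(num) / math.sqrt(float(var))
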