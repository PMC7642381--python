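"""Numba kernels for the Monte-Carlo random walks.

The RNG is counter-based: every walk owns an independent xorshift64* stream
whose state is derived by SplitMix64 mixing from ``(base_seed, global seed
index, walk index)``.  Hit accumulation is therefore independent of the
order in which seeds or walks are processed, and identical whether the
volume is walked in one piece or in z-blocks (as long as the clip bounds
coincide).

Two kernels share the same walk logic: an 8-bit kernel that precomputes a
256-entry weight lookup table per seed, and a float kernel that evaluates
the Gaussian weight directly.  A walk deposits one hit at its start
position and one after every step; a step towards a voxel outside the clip
bounds has weight 0 and can never be taken, so no hit is ever lost.
"""

from __future__ import annotations

import numba as nb
import numpy as np

U64 = np.uint64
_GOLDEN = U64(0x9E3779B97F4A7C15)
_MIX1 = U64(0xBF58476D1CE4E5B9)
_MIX2 = U64(0x94D049BB133111EB)
_STAR = U64(0x2545F4914F6CDD1D)
_K_SEED = U64(0xD6E8FEB86659FD93)
_K_WALK = U64(0xA5CB3D8E61F8E2A7)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@nb.njit(nb.uint64(nb.uint64), cache=True, inline="always")
def _splitmix64(x):
    x = x + _GOLDEN
    x = (x ^ (x >> U64(30))) * _MIX1
    x = (x ^ (x >> U64(27))) * _MIX2
    return x ^ (x >> U64(31))


@nb.njit(nb.uint64(nb.uint64, nb.int64, nb.int64), cache=True, inline="always")
def _walk_state(base, seed_index, walk_index):
    s = _splitmix64(base ^ (U64(seed_index) * _K_SEED))
    s = _splitmix64(s ^ (U64(walk_index) * _K_WALK))
    if s == U64(0):
        s = _GOLDEN
    return s


@nb.njit(nb.uint64(nb.uint64), cache=True, inline="always")
def _xorshift_next(s):
    s ^= s >> U64(12)
    s ^= s << U64(25)
    s ^= s >> U64(27)
    if s == U64(0):
        s = _GOLDEN
    return s


@nb.njit(nb.float64(nb.uint64), cache=True, inline="always")
def _to_unit(s):
    return ((s * _STAR) >> U64(11)) * _INV53


@nb.njit(cache=True)
def walk_hits_u8(img, pos, gidx, lab_idx, i0, sigma, nwalks, sorw,
                 base_seed, counts, zlo, zhi):
    """Accumulate hits for uint8 images via a per-seed weight LUT.

    ``counts`` has shape (n_labels, Z, Y, X) and is incremented in place.
    ``zlo``/``zhi`` bound the walkable z-range [zlo, zhi) — the full volume
    for a single-block run, an extended slab for block decomposition.
    """
    Z, Y, X = img.shape
    lut = np.empty(256, np.float64)
    for s in range(pos.shape[0]):
        inv2s2 = 1.0 / (2.0 * sigma[s] * sigma[s])
        v0 = i0[s]
        for k in range(256):
            d = v0 - k
            lut[k] = np.exp(-d * d * inv2s2)
        li = lab_idx[s]
        z0 = pos[s, 0]
        y0 = pos[s, 1]
        x0 = pos[s, 2]
        gi = gidx[s]
        for w in range(nwalks[s]):
            state = _walk_state(base_seed, gi, w)
            z = z0
            y = y0
            x = x0
            counts[li, z, y, x] += 1
            for _ in range(sorw):
                w0 = lut[img[z - 1, y, x]] if z > zlo else 0.0
                w1 = lut[img[z + 1, y, x]] if z + 1 < zhi else 0.0
                w2 = lut[img[z, y - 1, x]] if y > 0 else 0.0
                w3 = lut[img[z, y + 1, x]] if y + 1 < Y else 0.0
                w4 = lut[img[z, y, x - 1]] if x > 0 else 0.0
                w5 = lut[img[z, y, x + 1]] if x + 1 < X else 0.0
                total = w0 + w1 + w2 + w3 + w4 + w5
                state = _xorshift_next(state)
                r = _to_unit(state) * total
                # cumulative selection; float round-off falls back to the
                # last positive-weight direction
                if w0 > 0.0 and r < w0:
                    z -= 1
                else:
                    r -= w0
                    if w1 > 0.0 and r < w1:
                        z += 1
                    else:
                        r -= w1
                        if w2 > 0.0 and r < w2:
                            y -= 1
                        else:
                            r -= w2
                            if w3 > 0.0 and r < w3:
                                y += 1
                            else:
                                r -= w3
                                if w4 > 0.0 and (r < w4 or w5 <= 0.0):
                                    x -= 1
                                elif w5 > 0.0:
                                    x += 1
                                elif w3 > 0.0:
                                    y += 1
                                elif w2 > 0.0:
                                    y -= 1
                                elif w1 > 0.0:
                                    z += 1
                                elif w0 > 0.0:
                                    z -= 1
                counts[li, z, y, x] += 1


@nb.njit(cache=True)
def walk_hits_f32(img, pos, gidx, lab_idx, i0, sigma, nwalks, sorw,
                  base_seed, counts, zlo, zhi):
    """Float-image twin of :func:`walk_hits_u8` (direct weight evaluation)."""
    Z, Y, X = img.shape
    for s in range(pos.shape[0]):
        inv2s2 = 1.0 / (2.0 * sigma[s] * sigma[s])
        v0 = i0[s]
        li = lab_idx[s]
        z0 = pos[s, 0]
        y0 = pos[s, 1]
        x0 = pos[s, 2]
        gi = gidx[s]
        for w in range(nwalks[s]):
            state = _walk_state(base_seed, gi, w)
            z = z0
            y = y0
            x = x0
            counts[li, z, y, x] += 1
            for _ in range(sorw):
                if z > zlo:
                    d = v0 - img[z - 1, y, x]
                    w0 = np.exp(-d * d * inv2s2)
                else:
                    w0 = 0.0
                if z + 1 < zhi:
                    d = v0 - img[z + 1, y, x]
                    w1 = np.exp(-d * d * inv2s2)
                else:
                    w1 = 0.0
                if y > 0:
                    d = v0 - img[z, y - 1, x]
                    w2 = np.exp(-d * d * inv2s2)
                else:
                    w2 = 0.0
                if y + 1 < Y:
                    d = v0 - img[z, y + 1, x]
                    w3 = np.exp(-d * d * inv2s2)
                else:
                    w3 = 0.0
                if x > 0:
                    d = v0 - img[z, y, x - 1]
                    w4 = np.exp(-d * d * inv2s2)
                else:
                    w4 = 0.0
                if x + 1 < X:
                    d = v0 - img[z, y, x + 1]
                    w5 = np.exp(-d * d * inv2s2)
                else:
                    w5 = 0.0
                total = w0 + w1 + w2 + w3 + w4 + w5
                state = _xorshift_next(state)
                r = _to_unit(state) * total
                if w0 > 0.0 and r < w0:
                    z -= 1
                else:
                    r -= w0
                    if w1 > 0.0 and r < w1:
                        z += 1
                    else:
                        r -= w1
                        if w2 > 0.0 and r < w2:
                            y -= 1
                        else:
                            r -= w2
                            if w3 > 0.0 and r < w3:
                                y += 1
                            else:
                                r -= w3
                                if w4 > 0.0 and (r < w4 or w5 <= 0.0):
                                    x -= 1
                                elif w5 > 0.0:
                                    x += 1
                                elif w3 > 0.0:
                                    y += 1
                                elif w2 > 0.0:
                                    y -= 1
                                elif w1 > 0.0:
                                    z += 1
                                elif w0 > 0.0:
                                    z -= 1
                counts[li, z, y, x] += 1
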