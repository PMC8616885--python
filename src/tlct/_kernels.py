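"""Numba kernels for the ray-driven weighted projector.

All kernels share one discretization so that forward, adjoint and row norms
describe literally the same system matrix: rays are sampled at unit steps (in
pixel units) along the beam direction, each sample reads/writes the image with
bilinear interpolation, and each sample is multiplied by the sensitivity
weight of its position along the beam axis.  Samples whose bilinear footprint
lies outside the grid contribute nothing (zero padding).

The sample position for angle ``theta``, detector bin ``t`` and step ``s`` is

    (x, y) = center + sigma * (cos, sin) + tau * (-sin, cos)

with ``sigma = s - (L-1)/2`` and ``tau`` the signed detector coordinate in
pixel units.  Because the interferometer is fixed in the laboratory frame, the
sensitivity weight depends only on ``sigma`` and is passed in as a
precomputed vector over steps, identical for every angle and detector bin.
"""

import math

import numpy as np
from numba import njit


@njit(inline="always")
def _clip_axis(b, d, n, lo, hi):
    """Intersect the sigma-interval [lo, hi] with b + sigma*d in [-1, n]."""
    if abs(d) > 1e-12:
        t0 = (-1.0 - b) / d
        t1 = (n - b) / d
        if t0 > t1:
            t0, t1 = t1, t0
        if t0 > lo:
            lo = t0
        if t1 < hi:
            hi = t1
    elif b < -1.0 or b > n:
        lo, hi = 1.0, 0.0  # empty
    return lo, hi


@njit(fastmath=True)
def forward_angle(img, cos_t, sin_t, weights, n_det, tau_scale, spacing, out_row):
    """Weighted line integrals for one angle into ``out_row`` (n_det,)."""
    n = img.shape[0]
    c = 0.5 * (n - 1)
    L = weights.shape[0]
    shalf = 0.5 * (L - 1)
    for t in range(n_det):
        tau = (t - 0.5 * (n_det - 1)) * tau_scale
        bx = c - tau * sin_t
        by = c + tau * cos_t
        lo, hi = _clip_axis(bx, cos_t, float(n), -shalf, shalf)
        lo, hi = _clip_axis(by, sin_t, float(n), lo, hi)
        acc = 0.0
        s0 = int(math.ceil(lo + shalf))
        s1 = int(math.floor(hi + shalf))
        if s0 < 0:
            s0 = 0
        if s1 > L - 1:
            s1 = L - 1
        for s in range(s0, s1 + 1):
            sig = s - shalf
            x = bx + sig * cos_t
            y = by + sig * sin_t
            x0 = int(math.floor(x))
            y0 = int(math.floor(y))
            fx = x - x0
            fy = y - y0
            v = 0.0
            if 0 <= y0 < n:
                if 0 <= x0 < n:
                    v += (1.0 - fx) * (1.0 - fy) * img[y0, x0]
                if 0 <= x0 + 1 < n:
                    v += fx * (1.0 - fy) * img[y0, x0 + 1]
            if 0 <= y0 + 1 < n:
                if 0 <= x0 < n:
                    v += (1.0 - fx) * fy * img[y0 + 1, x0]
                if 0 <= x0 + 1 < n:
                    v += fx * fy * img[y0 + 1, x0 + 1]
            acc += weights[s] * v
        out_row[t] = acc * spacing


@njit(fastmath=True)
def backproject_angle(row, cos_t, sin_t, weights, tau_scale, spacing, out_img):
    """Exact adjoint of :func:`forward_angle`; accumulates into ``out_img``."""
    n = out_img.shape[0]
    n_det = row.shape[0]
    c = 0.5 * (n - 1)
    L = weights.shape[0]
    shalf = 0.5 * (L - 1)
    for t in range(n_det):
        g = row[t] * spacing
        if g == 0.0:
            continue
        tau = (t - 0.5 * (n_det - 1)) * tau_scale
        bx = c - tau * sin_t
        by = c + tau * cos_t
        lo, hi = _clip_axis(bx, cos_t, float(n), -shalf, shalf)
        lo, hi = _clip_axis(by, sin_t, float(n), lo, hi)
        s0 = int(math.ceil(lo + shalf))
        s1 = int(math.floor(hi + shalf))
        if s0 < 0:
            s0 = 0
        if s1 > L - 1:
            s1 = L - 1
        for s in range(s0, s1 + 1):
            sig = s - shalf
            x = bx + sig * cos_t
            y = by + sig * sin_t
            x0 = int(math.floor(x))
            y0 = int(math.floor(y))
            fx = x - x0
            fy = y - y0
            gw = g * weights[s]
            if 0 <= y0 < n:
                if 0 <= x0 < n:
                    out_img[y0, x0] += (1.0 - fx) * (1.0 - fy) * gw
                if 0 <= x0 + 1 < n:
                    out_img[y0, x0 + 1] += fx * (1.0 - fy) * gw
            if 0 <= y0 + 1 < n:
                if 0 <= x0 < n:
                    out_img[y0 + 1, x0] += (1.0 - fx) * fy * gw
                if 0 <= x0 + 1 < n:
                    out_img[y0 + 1, x0 + 1] += fx * fy * gw


@njit(fastmath=True)
def sart_sweep(x, sino, order, cos_a, sin_a, weights, row_norms, tau_scale, spacing, step):
    """One full pass of the relaxed per-angle (SART-like) update, in place.

    For each angle ``i`` (in the given order): forward-project the current
    image, normalize the residual by the exact squared row norms and scatter
    it back through the weighted adjoint scaled by ``step``.  Returns the sum
    of squared residuals streamed over the sweep (each angle's residual is
    measured against the image state at the time that angle is visited).
    """
    n_det = sino.shape[1]
    row = np.empty(n_det)
    corr = np.empty(n_det)
    total = 0.0
    for k in range(order.shape[0]):
        i = order[k]
        forward_angle(x, cos_a[i], sin_a[i], weights, n_det, tau_scale, spacing, row)
        for t in range(n_det):
            r = sino[i, t] - row[t]
            total += r * r
            corr[t] = step * r / row_norms[i, t]
        backproject_angle(corr, cos_a[i], sin_a[i], weights, tau_scale, spacing, x)
    return total


@njit(fastmath=True)
def row_norms_angle(cos_t, sin_t, weights, n_det, tau_scale, spacing, n, buf, out):
    """Exact squared row norms ``||b_i W||^2`` for every detector bin of one angle.

    Bilinear footprints of consecutive samples along a ray overlap, so the
    squared row norm is computed by first accumulating the true matrix-row
    entry per touched voxel in ``buf`` (an n*n scratch array, zeroed between
    rays via a touched-index list), then summing its squares.
    """
    c = 0.5 * (n - 1)
    L = weights.shape[0]
    shalf = 0.5 * (L - 1)
    touched = np.empty(4 * (L + 2), dtype=np.int64)
    for t in range(n_det):
        tau = (t - 0.5 * (n_det - 1)) * tau_scale
        bx = c - tau * sin_t
        by = c + tau * cos_t
        lo, hi = _clip_axis(bx, cos_t, float(n), -shalf, shalf)
        lo, hi = _clip_axis(by, sin_t, float(n), lo, hi)
        s0 = int(math.ceil(lo + shalf))
        s1 = int(math.floor(hi + shalf))
        if s0 < 0:
            s0 = 0
        if s1 > L - 1:
            s1 = L - 1
        ntouch = 0
        for s in range(s0, s1 + 1):
            sig = s - shalf
            x = bx + sig * cos_t
            y = by + sig * sin_t
            x0 = int(math.floor(x))
            y0 = int(math.floor(y))
            fx = x - x0
            fy = y - y0
            w = weights[s] * spacing
            for dy in range(2):
                yy = y0 + dy
                if yy < 0 or yy >= n:
                    continue
                cy = fy if dy == 1 else 1.0 - fy
                for dx in range(2):
                    xx = x0 + dx
                    if xx < 0 or xx >= n:
                        continue
                    cx = fx if dx == 1 else 1.0 - fx
                    j = yy * n + xx
                    if buf[j] == 0.0:
                        touched[ntouch] = j
                        ntouch += 1
                    buf[j] += cx * cy * w
        acc = 0.0
        for k in range(ntouch):
            j = touched[k]
            acc += buf[j] * buf[j]
            buf[j] = 0.0
        out[t] = acc
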