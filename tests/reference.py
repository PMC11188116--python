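"""Naive, explicit-loop reference implementation of the profile chain.

Deliberately unvectorized: every stage is written as plain Python loops so
it serves as an independent oracle for the production implementation.
"""

from __future__ import annotations

import math

import numpy as np


def naive_percentile(values, q):
    """Linear-interpolation percentile of a flat sequence (loop/sort based)."""
    v = sorted(float(x) for x in values)
    n = len(v)
    h = (n - 1) * q / 100.0
    f = int(math.floor(h))
    c = min(f + 1, n - 1)
    return v[f] + (v[c] - v[f]) * (h - f)


def naive_average_frames(frames, window):
    start, stop = window
    T, ny, nx = frames.shape
    out = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            s = 0.0
            for t in range(start, stop):
                s += float(frames[t, i, j])
            out[i, j] = s / (stop - start)
    return out


def naive_subtract(peak_avg, base_avg):
    ny, nx = peak_avg.shape
    out = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            out[i, j] = float(peak_avg[i, j]) - float(base_avg[i, j])
    return out


def naive_stalk_mask(peak_avg, percentile, dilation_iters, exclude=None):
    ny, nx = peak_avg.shape
    vals = []
    for i in range(ny):
        for j in range(nx):
            if exclude is None or not exclude[i, j]:
                vals.append(float(peak_avg[i, j]))
    thr = naive_percentile(vals, 100.0 - percentile)
    mask = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            mask[i, j] = float(peak_avg[i, j]) > thr
    for _ in range(dilation_iters):
        grown = mask.copy()
        for i in range(ny):
            for j in range(nx):
                if mask[i, j]:
                    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < ny and 0 <= jj < nx:
                            grown[ii, jj] = True
        mask = grown
    return mask, thr


def naive_apply_mask(field, mask):
    ny, nx = field.shape
    out = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            out[i, j] = np.nan if mask[i, j] else float(field[i, j])
    return out


def _interp(su, s, vals):
    # manual linear interpolation (np.interp semantics on increasing s)
    if su <= s[0]:
        return vals[0]
    if su >= s[-1]:
        return vals[-1]
    k = 0
    while s[k + 1] < su:
        k += 1
    w = (su - s[k]) / (s[k + 1] - s[k])
    return vals[k] * (1 - w) + vals[k + 1] * w


def naive_resample_centerline(pts, step_px=1.0):
    n = len(pts)
    s = [0.0]
    for k in range(1, n):
        dr = pts[k][0] - pts[k - 1][0]
        dc = pts[k][1] - pts[k - 1][1]
        s.append(s[-1] + math.hypot(dr, dc))
    m = int(math.floor(s[-1] / step_px)) + 1
    p = []
    for k in range(m):
        su = k * step_px
        p.append((_interp(su, s, [q[0] for q in pts]), _interp(su, s, [q[1] for q in pts])))
    tangents = []
    for k in range(m):
        if k == 0:
            t = (p[1][0] - p[0][0], p[1][1] - p[0][1])
        elif k == m - 1:
            t = (p[-1][0] - p[-2][0], p[-1][1] - p[-2][1])
        else:
            t = (p[k + 1][0] - p[k - 1][0], p[k + 1][1] - p[k - 1][1])
        norm = math.hypot(*t)
        tangents.append((t[0] / norm, t[1] / norm))
    normals = [(-t[1], t[0]) for t in tangents]
    return p, normals


def naive_bilinear(field, r, c):
    """Bilinear sample; stencil pixels with zero weight do not contaminate."""
    ny, nx = field.shape
    r0, c0 = math.floor(r), math.floor(c)
    fr, fc = r - r0, c - c0
    total = 0.0
    for dr in (0, 1):
        for dc in (0, 1):
            w = (fr if dr else 1 - fr) * (fc if dc else 1 - fc)
            if w == 0:
                continue
            rr, cc = r0 + dr, c0 + dc
            if not (0 <= rr < ny and 0 <= cc < nx):
                return np.nan
            v = field[rr, cc]
            if not np.isfinite(v):
                return np.nan
            total += w * float(v)
    return total


def naive_straighten(field, centerline, radius_um, halfwidth_um, pixel_size_um):
    p, normals = naive_resample_centerline([tuple(q) for q in centerline], 1.0)
    w = int(math.ceil((halfwidth_um + radius_um) / pixel_size_um))
    offsets = list(range(-w, w + 1))
    data = np.zeros((len(p), len(offsets)))
    for k in range(len(p)):
        for j, off in enumerate(offsets):
            r = p[k][0] + off * normals[k][0]
            c = p[k][1] + off * normals[k][1]
            data[k, j] = naive_bilinear(field, r, c)
    d_um = np.array([off * pixel_size_um for off in offsets])
    return data, d_um


def naive_collapse(data):
    nrow, ncol = data.shape
    raw = np.zeros(ncol)
    n_valid = np.zeros(ncol, dtype=int)
    for j in range(ncol):
        s, n = 0.0, 0
        for i in range(nrow):
            if np.isfinite(data[i, j]):
                s += data[i, j]
                n += 1
        raw[j] = s / n if n else np.nan
        n_valid[j] = n
    return raw, n_valid


def naive_zscore(d_um, raw, background_min_um):
    bg = [raw[j] for j in range(len(raw))
          if abs(d_um[j]) >= background_min_um and np.isfinite(raw[j])]
    mu = sum(bg) / len(bg)
    var = sum((x - mu) ** 2 for x in bg) / (len(bg) - 1)
    sd = math.sqrt(var)
    return np.array([(x - mu) / sd for x in raw]), mu, sd


def naive_sheath_peak(d_um, z, radius_um, search_um):
    best = {}
    for side, sign in (("left", -1), ("right", 1)):
        cand = [
            (z[j], d_um[j])
            for j in range(len(z))
            if np.sign(d_um[j]) == sign
            and radius_um < abs(d_um[j]) <= radius_um + search_um
            and np.isfinite(z[j])
        ]
        best[side] = max(cand, key=lambda t: t[0])
    return (best["left"][0] + best["right"][0]) / 2.0, best


def naive_chain(
    calcium, centerline, diameter_um, pixel_size_um, cfg, base_window, peak_window, lumen
):
    """Full reference chain; returns intermediate stages and the statistic."""
    base_avg = naive_average_frames(calcium, base_window)
    peak_avg = naive_average_frames(calcium, peak_window)
    mask, thr = naive_stalk_mask(
        peak_avg, cfg.stalk_percentile, cfg.dilation_iters, exclude=lumen
    )
    dfield = naive_apply_mask(naive_subtract(peak_avg, base_avg), mask)
    data, d_um = naive_straighten(
        dfield, centerline, diameter_um / 2.0, cfg.profile_halfwidth_um, pixel_size_um
    )
    raw, n_valid = naive_collapse(data)
    z, mu, sd = naive_zscore(d_um, raw, cfg.background_min_um)
    peak_z_mean, sides = naive_sheath_peak(
        d_um, z, diameter_um / 2.0, cfg.sheath_search_um
    )
    return {
        "base_avg": base_avg,
        "peak_avg": peak_avg,
        "mask": mask,
        "threshold": thr,
        "dfield": dfield,
        "straightened": data,
        "d_um": d_um,
        "raw": raw,
        "z": z,
        "bg_mean": mu,
        "bg_sd": sd,
        "peak_z_mean": peak_z_mean,
    }
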