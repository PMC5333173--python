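"""Independent naive reference implementations used as oracles.

Everything here is deliberately written as plain Python loops or closed-form
arithmetic, independent of the package's vectorized code paths.
"""

import math

import numpy as np


def naive_coloc_metrics(a, b, roi, low_a, high_a, low_b, high_b):
    """Triple-loop evaluation of every colocalization metric.

    Returns a dict with m1, m2, moc, pcc, pct_a, pct_b, n_coloc, n_a, n_b,
    n_considered; undefined metrics are NaN.
    """
    nz, ny, nx = a.shape
    sum_a_above = sum_b_above = 0.0
    sum_a_both = sum_b_both = 0.0
    s_pairs = []
    n_a = n_b = n_coloc = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not roi[z, y, x]:
                    continue
                av, bv = float(a[z, y, x]), float(b[z, y, x])
                in_a = low_a <= av <= high_a
                in_b = low_b <= bv <= high_b
                if in_a:
                    n_a += 1
                if in_b:
                    n_b += 1
                if in_a and in_b:
                    n_coloc += 1
                above_a = av >= low_a
                above_b = bv >= low_b
                if above_a:
                    sum_a_above += av
                if above_b:
                    sum_b_above += bv
                if above_a and above_b:
                    sum_a_both += av
                    sum_b_both += bv
                if above_a or above_b:
                    s_pairs.append((av, bv))

    m1 = sum_a_both / sum_a_above if sum_a_above > 0 else math.nan
    m2 = sum_b_both / sum_b_above if sum_b_above > 0 else math.nan

    sum_ab = sum(av * bv for av, bv in s_pairs)
    sum_aa = sum(av * av for av, _ in s_pairs)
    sum_bb = sum(bv * bv for _, bv in s_pairs)
    denom = math.sqrt(sum_aa * sum_bb)
    moc = sum_ab / denom if denom > 0 else math.nan

    n_s = len(s_pairs)
    if n_s >= 2:
        mean_a = sum(av for av, _ in s_pairs) / n_s
        mean_b = sum(bv for _, bv in s_pairs) / n_s
        cov = sum((av - mean_a) * (bv - mean_b) for av, bv in s_pairs)
        var_a = sum((av - mean_a) ** 2 for av, _ in s_pairs)
        var_b = sum((bv - mean_b) ** 2 for _, bv in s_pairs)
        d = math.sqrt(var_a * var_b)
        pcc = cov / d if d > 0 else math.nan
    else:
        pcc = math.nan

    pct_a = 100.0 * n_coloc / n_a if n_a else math.nan
    pct_b = 100.0 * n_coloc / n_b if n_b else math.nan
    return {
        "m1": m1, "m2": m2, "moc": moc, "pcc": pcc,
        "pct_a": pct_a, "pct_b": pct_b,
        "n_coloc": n_coloc, "n_a": n_a, "n_b": n_b, "n_considered": n_s,
    }


def naive_point_in_polygon(px, py, vertices):
    """Crossing-number test for one point: count edge crossings of a +x ray."""
    crossings = 0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) == (y2 > py):
            continue
        x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        if x_cross > px:
            crossings += 1
    return crossings % 2 == 1


def rotation_matrix_axis_angle(axis, angle_rad):
    """Rodrigues rotation matrix, written out explicitly (independent of scipy)."""
    ux, uy, uz = axis / np.linalg.norm(np.asarray(axis, dtype=float))
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    cc = 1.0 - c
    return np.array([
        [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
        [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
        [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
    ])


def naive_shape_contains(shape, point_xyz):
    """Containment of one world point, rebuilt from the shape description."""
    rotvec = np.asarray(shape.rotvec, dtype=float)
    angle = np.linalg.norm(rotvec)
    rot = np.eye(3) if angle == 0 else rotation_matrix_axis_angle(rotvec / angle, angle)
    center = np.asarray(shape.center, dtype=float) + np.asarray(shape.translation, dtype=float)
    local = np.linalg.solve(rot @ np.diag(shape.scale), np.asarray(point_xyz, float) - center)
    if shape.kind == "box":
        hx, hy, hz = shape.params["half_extents"]
        return abs(local[0]) <= hx and abs(local[1]) <= hy and abs(local[2]) <= hz
    if shape.kind == "cylinder":
        r = shape.params["radius"]
        hl = shape.params["half_length"]
        return local[0] ** 2 + local[1] ** 2 <= r * r and abs(local[2]) <= hl
    verts = np.asarray(shape.params["vertices"], dtype=float)
    hd = shape.params["half_depth"]
    return abs(local[2]) <= hd and naive_point_in_polygon(local[0], local[1], verts)


def naive_rasterize(shape, stack):
    """Exhaustive voxel-center rasterization: footprint = any-z containment."""
    nz, ny, nx = stack.shape
    dz, dy, dx = stack.spacing
    footprint = np.zeros((ny, nx), dtype=bool)
    contained_z = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                p = ((x + 0.5) * dx, (y + 0.5) * dy, (z + 0.5) * dz)
                if naive_shape_contains(shape, p):
                    footprint[y, x] = True
                    contained_z.append(z)
    return footprint, contained_z


def back_to_front_composite(samples_rgba, background=(0.0, 0.0, 0.0)):
    """Back-to-front *over* composition of straight-color RGBA samples."""
    rgb = np.asarray(background, dtype=float).copy()
    alpha = 0.0
    for sample in reversed(list(samples_rgba)):
        c = np.asarray(sample[:3], dtype=float)
        a = float(sample[3])
        rgb = a * c + (1.0 - a) * rgb
        alpha = a + (1.0 - a) * alpha
    return rgb, alpha
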