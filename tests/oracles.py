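"""Independent brute-force reference implementations of the radiomic
features, written with explicit loops and no shared code with the package.

These exist purely as a test surface: every feature value produced by
``scarpipe.radiomics`` must agree with these to near machine precision on
small random regions.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1)]
NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def oracle_discretize(x: np.ndarray, mask: np.ndarray, bw: float) -> np.ndarray:
    lo = min(x[r][c] for r in range(x.shape[0]) for c in range(x.shape[1]) if mask[r][c])
    g = np.zeros(x.shape, dtype=int)
    for r in range(x.shape[0]):
        for c in range(x.shape[1]):
            if mask[r][c]:
                g[r][c] = int(math.floor((x[r][c] - lo) / bw)) + 1
    return g


def oracle_first_order(samples, levels, pixel_volume=1.0) -> dict:
    xs = sorted(float(v) for v in samples)
    n = len(xs)
    mean = sum(xs) / n
    m2 = sum((v - mean) ** 2 for v in xs) / n
    m3 = sum((v - mean) ** 3 for v in xs) / n
    m4 = sum((v - mean) ** 4 for v in xs) / n
    p10, p25, p75, p90 = np.percentile(xs, [10, 25, 75, 90])
    robust = [v for v in xs if p10 <= v <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    counts: dict[int, int] = {}
    for lv in levels:
        counts[lv] = counts.get(lv, 0) + 1
    probs = [c / n for c in counts.values()]
    energy = sum(v * v for v in xs)
    out = {
        "energy": energy,
        "total_energy": pixel_volume * energy,
        "entropy": -sum(p * math.log2(p) for p in probs if p > 0),
        "minimum": xs[0],
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "maximum": xs[-1],
        "mean": mean,
        "median": float(np.median(xs)),
        "interquartile_range": float(p75 - p25),
        "range": xs[-1] - xs[0],
        "mean_absolute_deviation": sum(abs(v - mean) for v in xs) / n,
        "robust_mean_absolute_deviation": (
            sum(abs(v - rmean) for v in robust) / len(robust) if robust else 0.0
        ),
        "root_mean_squared": math.sqrt(energy / n),
        "variance": m2,
        "uniformity": sum(p * p for p in probs),
    }
    if m2 > 0:
        out["skewness"] = m3 / m2**1.5
        out["kurtosis"] = m4 / m2**2
    else:
        out["skewness"] = float("nan")
        out["kurtosis"] = float("nan")
    return out


def oracle_glcm_matrix(g: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    rows, cols = g.shape
    P = np.zeros((ng, ng))
    for r in range(rows):
        for c in range(cols):
            if not mask[r][c]:
                continue
            for dr, dc in OFFSETS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and mask[rr][cc]:
                    P[g[r][c] - 1][g[rr][cc] - 1] += 1
                    P[g[rr][cc] - 1][g[r][c] - 1] += 1
    total = P.sum()
    return P / total if total > 0 else P


def oracle_glcm_features(P: np.ndarray) -> dict:
    ng = P.shape[0]
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum(px[i] * (i + 1 - mu_x) ** 2 for i in range(ng)))
    sig_y = math.sqrt(sum(py[j] * (j + 1 - mu_y) ** 2 for j in range(ng)))
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += P[i][j]
            p_sum[i + j] += P[i][j]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    da = sum(k * p_diff[k] for k in range(ng))
    hxy = ent(P.ravel())
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if P[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = ent([px[i] * py[j] for i in range(ng) for j in range(ng)])
    hx, hy = ent(px), ent(py)
    out = {
        "autocorrelation": sum(
            P[i][j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)
        ),
        "joint_average": mu_x,
        "cluster_prominence": sum(
            P[i][j] * (i + j + 2 - mu_x - mu_y) ** 4 for i in range(ng) for j in range(ng)
        ),
        "cluster_shade": sum(
            P[i][j] * (i + j + 2 - mu_x - mu_y) ** 3 for i in range(ng) for j in range(ng)
        ),
        "cluster_tendency": sum(
            P[i][j] * (i + j + 2 - mu_x - mu_y) ** 2 for i in range(ng) for j in range(ng)
        ),
        "contrast": sum(P[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng)),
        "difference_average": da,
        "difference_entropy": ent(p_diff),
        "difference_variance": sum(p_diff[k] * (k - da) ** 2 for k in range(ng)),
        "joint_energy": sum(P[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "joint_entropy": hxy,
        "idm": sum(p_diff[k] / (1 + k * k) for k in range(ng)),
        "idmn": sum(p_diff[k] / (1 + (k / ng) ** 2) for k in range(ng)),
        "id": sum(p_diff[k] / (1 + k) for k in range(ng)),
        "idn": sum(p_diff[k] / (1 + k / ng) for k in range(ng)),
        "inverse_variance": sum(p_diff[k] / k**2 for k in range(1, ng)),
        "maximum_probability": max(P[i][j] for i in range(ng) for j in range(ng)),
        "sum_average": sum((k + 2) * p_sum[k] for k in range(2 * ng - 1)),
        "sum_entropy": ent(p_sum),
        "sum_of_squares": sum(
            P[i][j] * (i + 1 - mu_x) ** 2 for i in range(ng) for j in range(ng)
        ),
    }
    if sig_x > 0 and sig_y > 0:
        corr_num = sum(
            P[i][j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)
        )
        out["correlation"] = (corr_num - mu_x * mu_y) / (sig_x * sig_y)
    else:
        out["correlation"] = float("nan")
    if max(hx, hy) > 0:
        out["imc1"] = (hxy - hxy1) / max(hx, hy)
        out["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2 * (hxy2 - hxy))))
    else:
        out["imc1"] = float("nan")
        out["imc2"] = float("nan")
    present = [i for i in range(ng) if px[i] > 0]
    if len(present) >= 2:
        m = len(present)
        Q = np.zeros((m, m))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a][b] = sum(
                    P[i][k] * P[j][k] / (px[i] * py[k])
                    for k in range(ng)
                    if py[k] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)))
        out["mcc"] = math.sqrt(max(0.0, eig[-2]))
    else:
        out["mcc"] = float("nan")
    return out


def oracle_gldm_matrix(g: np.ndarray, mask: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    rows, cols = g.shape
    P = np.zeros((ng, 9))
    for r in range(rows):
        for c in range(cols):
            if not mask[r][c]:
                continue
            d = 0
            for dr, dc in NEIGH8:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and mask[rr][cc]:
                    if abs(int(g[r][c]) - int(g[rr][cc])) <= alpha:
                        d += 1
            P[g[r][c] - 1][d] += 1
    used = max(
        d
        for d in range(9)
        if P[:, d].sum() > 0
    )
    return P[:, : used + 1]


def _oracle_dependence_style(P: np.ndarray) -> dict:
    """GLDM-style features from a (level, size) matrix with size = col + 1."""
    ng, nd = P.shape
    nz = P.sum()
    out = {}
    out["small"] = sum(
        P[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / nz
    out["large"] = sum(
        P[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / nz
    out["gln"] = sum(sum(P[i]) ** 2 for i in range(ng)) / nz
    out["sn"] = sum(P[:, j].sum() ** 2 for j in range(nd)) / nz
    out["snn"] = out["sn"] / nz
    out["glnn"] = out["gln"] / nz
    mu_g = sum((i + 1) * P[i].sum() / nz for i in range(ng))
    mu_s = sum((j + 1) * P[:, j].sum() / nz for j in range(nd))
    out["glv"] = sum(P[i].sum() / nz * (i + 1 - mu_g) ** 2 for i in range(ng))
    out["sv"] = sum(P[:, j].sum() / nz * (j + 1 - mu_s) ** 2 for j in range(nd))
    out["ent"] = -sum(
        P[i][j] / nz * math.log2(P[i][j] / nz)
        for i in range(ng)
        for j in range(nd)
        if P[i][j] > 0
    )
    out["lgl"] = sum(P[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nd)) / nz
    out["hgl"] = sum(P[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nd)) / nz
    out["slgl"] = sum(
        P[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nd)
    ) / nz
    out["shgl"] = sum(
        P[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / nz
    out["llgl"] = sum(
        P[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / nz
    out["lhgl"] = sum(
        P[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / nz
    out["nz"] = nz
    return out


def oracle_gldm_features(g, mask, ng, alpha=0) -> dict:
    P = oracle_gldm_matrix(g, mask, ng, alpha)
    r = _oracle_dependence_style(P)
    return {
        "small_dependence_emphasis": r["small"],
        "large_dependence_emphasis": r["large"],
        "gray_level_non_uniformity": r["gln"],
        "dependence_non_uniformity": r["sn"],
        "dependence_non_uniformity_normalized": r["snn"],
        "gray_level_variance": r["glv"],
        "dependence_variance": r["sv"],
        "dependence_entropy": r["ent"],
        "low_gray_level_emphasis": r["lgl"],
        "high_gray_level_emphasis": r["hgl"],
        "small_dependence_low_gray_level_emphasis": r["slgl"],
        "small_dependence_high_gray_level_emphasis": r["shgl"],
        "large_dependence_low_gray_level_emphasis": r["llgl"],
        "large_dependence_high_gray_level_emphasis": r["lhgl"],
    }


def oracle_glszm_zones(g: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """Flood-fill zones of equal gray level, 8-connected."""
    rows, cols = g.shape
    seen = np.zeros(g.shape, dtype=bool)
    zones = []
    for r in range(rows):
        for c in range(cols):
            if not mask[r][c] or seen[r][c]:
                continue
            level = g[r][c]
            stack = [(r, c)]
            seen[r][c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in NEIGH8:
                    r2, c2 = rr + dr, cc + dc
                    if (
                        0 <= r2 < rows
                        and 0 <= c2 < cols
                        and mask[r2][c2]
                        and not seen[r2][c2]
                        and g[r2][c2] == level
                    ):
                        seen[r2][c2] = True
                        stack.append((r2, c2))
            zones.append((int(level), size))
    return zones


def oracle_glszm_features(g, mask, ng) -> dict:
    zones = oracle_glszm_zones(g, mask)
    max_s = max(s for _, s in zones)
    P = np.zeros((ng, max_s))
    for level, size in zones:
        P[level - 1][size - 1] += 1
    r = _oracle_dependence_style(P)
    np_pixels = int(mask.sum())
    return {
        "small_area_emphasis": r["small"],
        "large_area_emphasis": r["large"],
        "gray_level_non_uniformity": r["gln"],
        "gray_level_non_uniformity_normalized": r["glnn"],
        "size_zone_non_uniformity": r["sn"],
        "size_zone_non_uniformity_normalized": r["snn"],
        "zone_percentage": r["nz"] / np_pixels,
        "gray_level_variance": r["glv"],
        "zone_variance": r["sv"],
        "zone_entropy": r["ent"],
        "low_gray_level_zone_emphasis": r["lgl"],
        "high_gray_level_zone_emphasis": r["hgl"],
        "small_area_low_gray_level_emphasis": r["slgl"],
        "small_area_high_gray_level_emphasis": r["shgl"],
        "large_area_low_gray_level_emphasis": r["llgl"],
        "large_area_high_gray_level_emphasis": r["lhgl"],
    }


def oracle_glrlm_runs(g: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """Run scanning along the four directions; mask gaps break runs."""
    rows, cols = g.shape
    z = np.where(mask, g, 0)
    runs = []
    for dr, dc in OFFSETS:
        starts = []
        for r in range(rows):
            for c in range(cols):
                rp, cp = r - dr, c - dc
                if not (0 <= rp < rows and 0 <= cp < cols):
                    starts.append((r, c))
        for r0, c0 in starts:
            r, c = r0, c0
            current, length = 0, 0
            while 0 <= r < rows and 0 <= c < cols:
                v = int(z[r][c])
                if v == current:
                    length += 1
                else:
                    if current > 0:
                        runs.append((current, length))
                    current, length = v, 1
                r, c = r + dr, c + dc
            if current > 0:
                runs.append((current, length))
    return runs


def oracle_glrlm_features(g, mask, ng) -> dict:
    runs = oracle_glrlm_runs(g, mask)
    max_l = max(l for _, l in runs)
    P = np.zeros((ng, max_l))
    for level, length in runs:
        P[level - 1][length - 1] += 1
    r = _oracle_dependence_style(P)
    np_pixels = int(mask.sum())
    return {
        "short_run_emphasis": r["small"],
        "long_run_emphasis": r["large"],
        "gray_level_non_uniformity": r["gln"],
        "gray_level_non_uniformity_normalized": r["glnn"],
        "run_length_non_uniformity": r["sn"],
        "run_length_non_uniformity_normalized": r["snn"],
        "run_percentage": r["nz"] / (np_pixels * len(OFFSETS)),
        "gray_level_variance": r["glv"],
        "run_variance": r["sv"],
        "run_entropy": r["ent"],
        "low_gray_level_run_emphasis": r["lgl"],
        "high_gray_level_run_emphasis": r["hgl"],
        "short_run_low_gray_level_emphasis": r["slgl"],
        "short_run_high_gray_level_emphasis": r["shgl"],
        "long_run_low_gray_level_emphasis": r["llgl"],
        "long_run_high_gray_level_emphasis": r["lhgl"],
    }


def oracle_ngtdm_features(g, mask, ng) -> dict:
    rows, cols = g.shape
    n = [0.0] * ng
    s = [0.0] * ng
    for r in range(rows):
        for c in range(cols):
            if not mask[r][c]:
                continue
            nb = [
                int(g[r + dr][c + dc])
                for dr, dc in NEIGH8
                if 0 <= r + dr < rows and 0 <= c + dc < cols and mask[r + dr][c + dc]
            ]
            if not nb:
                continue
            lvl = int(g[r][c])
            n[lvl - 1] += 1
            s[lvl - 1] += abs(lvl - sum(nb) / len(nb))
    nvp = sum(n)
    if nvp == 0:
        return {k: float("nan") for k in ("coarseness", "contrast", "busyness", "complexity", "strength")}
    p = [v / nvp for v in n]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    denom = sum(p[i] * s[i] for i in present)
    out = {"coarseness": 1.0 / denom if denom > 0 else 1e6}
    if ngp > 1:
        out["contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
            * (sum(s) / nvp)
        )
        busy_den = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        out["busyness"] = denom / busy_den if busy_den > 0 else 0.0
        out["complexity"] = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / nvp
        )
        s_total = sum(s)
        out["strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        out["contrast"] = 0.0
        out["busyness"] = 0.0
        out["complexity"] = 0.0
        out["strength"] = 0.0
    return out


def oracle_all_features(x: np.ndarray, mask: np.ndarray, bin_width: float, pixel_volume: float = 1.0) -> dict:
    """All 93 features on one region, fully brute force."""
    g = oracle_discretize(x, mask, bin_width)
    ng = int(g.max())
    samples = [x[r][c] for r in range(x.shape[0]) for c in range(x.shape[1]) if mask[r][c]]
    levels = [g[r][c] for r in range(x.shape[0]) for c in range(x.shape[1]) if mask[r][c]]
    out = {}
    for k, v in oracle_first_order(samples, levels, pixel_volume).items():
        out[f"firstorder.{k}"] = v
    P = oracle_glcm_matrix(g, mask, ng)
    for k, v in oracle_glcm_features(P).items():
        out[f"glcm.{k}"] = v
    for k, v in oracle_gldm_features(g, mask, ng).items():
        out[f"gldm.{k}"] = v
    for k, v in oracle_glszm_features(g, mask, ng).items():
        out[f"glszm.{k}"] = v
    for k, v in oracle_glrlm_features(g, mask, ng).items():
        out[f"glrlm.{k}"] = v
    for k, v in oracle_ngtdm_features(g, mask, ng).items():
        out[f"ngtdm.{k}"] = v
    return out


def ray_cast_contains(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Watertight-mesh point containment by x-axis ray casting
    (vectorized Moller-Trumbore per ray), independent of any spatial index.

    Points sharing a (y, z) line reuse one ray.
    """
    tri = vertices[faces]  # (m, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    d = np.array([1.0, 0.0, 0.0])
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

    pts = np.asarray(points, dtype=float)
    yz = np.round(pts[:, 1:], 9)
    inside = np.zeros(len(pts), dtype=bool)
    x0 = pts[:, 0].min() - 10.0
    for key in np.unique(yz, axis=0):
        sel = np.all(yz == key, axis=1)
        origin = np.array([x0, key[0], key[1]])
        tvec = origin - v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)
        v = np.einsum("j,ij->i", d, qvec) * inv_det
        t = np.einsum("ij,ij->i", e2, qvec) * inv_det
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
        xs = np.sort(x0 + t[hit])
        crossings = np.searchsorted(xs, pts[sel, 0])
        inside[sel] = crossings % 2 == 1
    return inside
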