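"""Independent brute-force oracles for texture matrices and features.

Everything here is written as plain Python loops over dictionaries,
deliberately sharing no code with the package: exhaustive pair/run
enumeration for the matrices and explicit-summation evaluation of every
feature formula.  Gray levels enter formulas 1-based; logs are base 2
with log(0) := 0.
"""

import math

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(vals, mask, angle, distance=1, levels=None):
    """Symmetric normalized GLCM as a dense list-of-lists."""
    H = len(vals)
    W = len(vals[0])
    G = levels if levels is not None else max(max(row) for row in vals) + 1
    dr, dc = OFFSETS[angle]
    dr *= distance
    dc *= distance
    counts = {}
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and mask[r][c] and mask[r2][c2]:
                i, j = vals[r][c], vals[r2][c2]
                counts[(i, j)] = counts.get((i, j), 0) + 1
                counts[(j, i)] = counts.get((j, i), 0) + 1
    total = sum(counts.values())
    P = [[0.0] * G for _ in range(G)]
    for (i, j), n in counts.items():
        P[i][j] = n / total
    return P


def _log2(x):
    return math.log2(x) if x > 0 else 0.0


def glcm_features_bruteforce(P):
    """All 22 co-occurrence features by explicit double summation."""
    G = len(P)
    px = [sum(P[i][j] for j in range(G)) for i in range(G)]
    py = [sum(P[i][j] for i in range(G)) for j in range(G)]
    mu_x = sum((i + 1) * px[i] for i in range(G))
    mu_y = sum((j + 1) * py[j] for j in range(G))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(G)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(G)))

    p_sum = {}   # distribution of (i+1)+(j+1)
    p_diff = {}  # distribution of |i-j|
    for i in range(G):
        for j in range(G):
            if P[i][j] > 0:
                p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + P[i][j]
                p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i][j]

    out = {}
    out["autocorrelation"] = sum((i + 1) * (j + 1) * P[i][j]
                                 for i in range(G) for j in range(G))
    for name, power in (("cluster_prominence", 4), ("cluster_shade", 3),
                        ("cluster_tendency", 2)):
        out[name] = sum((i + 1 + j + 1 - mu_x - mu_y) ** power * P[i][j]
                        for i in range(G) for j in range(G))
    out["contrast"] = sum((i - j) ** 2 * P[i][j]
                          for i in range(G) for j in range(G))
    if sig_x > 0 and sig_y > 0:
        out["correlation"] = (out["autocorrelation"] - mu_x * mu_y) / (sig_x * sig_y)
    else:
        out["correlation"] = 0.0
    out["difference_entropy"] = -sum(v * _log2(v) for v in p_diff.values())
    out["dissimilarity"] = sum(abs(i - j) * P[i][j]
                               for i in range(G) for j in range(G))
    out["energy"] = sum(P[i][j] ** 2 for i in range(G) for j in range(G))
    HXY = -sum(P[i][j] * _log2(P[i][j]) for i in range(G) for j in range(G))
    out["entropy"] = HXY
    out["homogeneity_1"] = sum(P[i][j] / (1 + abs(i - j))
                               for i in range(G) for j in range(G))
    out["homogeneity_2"] = sum(P[i][j] / (1 + (i - j) ** 2)
                               for i in range(G) for j in range(G))
    HX = -sum(v * _log2(v) for v in px)
    HY = -sum(v * _log2(v) for v in py)
    HXY1 = -sum(P[i][j] * _log2(px[i] * py[j])
                for i in range(G) for j in range(G) if P[i][j] > 0)
    HXY2 = -sum(px[i] * py[j] * _log2(px[i] * py[j])
                for i in range(G) for j in range(G) if px[i] * py[j] > 0)
    denom = max(HX, HY)
    out["informational_measure_of_correlation_1"] = (
        (HXY - HXY1) / denom if denom > 0 else 0.0)
    out["informational_measure_of_correlation_2"] = math.sqrt(
        max(0.0, 1.0 - math.exp(-2.0 * (HXY2 - HXY))))
    out["inverse_difference_moment_normalized"] = sum(
        P[i][j] / (1 + (i - j) ** 2 / G ** 2)
        for i in range(G) for j in range(G))
    out["inverse_difference_normalized"] = sum(
        P[i][j] / (1 + abs(i - j) / G) for i in range(G) for j in range(G))
    out["inverse_variance"] = sum(P[i][j] / (i - j) ** 2
                                  for i in range(G) for j in range(G) if i != j)
    out["maximum_probability"] = max(P[i][j] for i in range(G) for j in range(G))
    sa = sum(k * v for k, v in p_sum.items())
    out["sum_average"] = sa
    out["sum_entropy"] = -sum(v * _log2(v) for v in p_sum.values())
    out["sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    out["variance"] = sum((i + 1 - mu_x) ** 2 * P[i][j]
                          for i in range(G) for j in range(G))
    return out


def glrlm_bruteforce(vals, mask, angle, levels=None):
    """Raw-count run-length matrix as a dict {(gray, length): count}."""
    H = len(vals)
    W = len(vals[0])
    if angle == 0:
        lines = [[(r, c) for c in range(W)] for r in range(H)]
    elif angle == 90:
        lines = [[(r, c) for r in range(H)] for c in range(W)]
    elif angle == 135:  # along (1, 1)
        lines = []
        for start in range(W):
            lines.append([(r, start + r) for r in range(H) if start + r < W])
        for start in range(1, H):
            lines.append([(start + k, k) for k in range(W) if start + k < H])
    elif angle == 45:  # along (-1, 1)
        lines = []
        for start in range(H):
            lines.append([(start - k, k) for k in range(W) if start - k >= 0])
        for start in range(1, W):
            lines.append([(H - 1 - k, start + k) for k in range(W)
                          if H - 1 - k >= 0 and start + k < W])
    runs = {}
    for line in lines:
        cur_val, cur_len = None, 0
        for (r, c) in line:
            if mask[r][c]:
                v = vals[r][c]
                if v == cur_val:
                    cur_len += 1
                else:
                    if cur_len:
                        runs[(cur_val, cur_len)] = runs.get((cur_val, cur_len), 0) + 1
                    cur_val, cur_len = v, 1
            else:
                if cur_len:
                    runs[(cur_val, cur_len)] = runs.get((cur_val, cur_len), 0) + 1
                cur_val, cur_len = None, 0
        if cur_len:
            runs[(cur_val, cur_len)] = runs.get((cur_val, cur_len), 0) + 1
    return runs


def glrlm_features_bruteforce(runs, n_pixels):
    """All 11 run-length features from a {(gray, length): count} dict."""
    nr = sum(runs.values())
    row = {}
    col = {}
    for (g, r), n in runs.items():
        row[g] = row.get(g, 0) + n
        col[r] = col.get(r, 0) + n
    out = {}
    out["short_run_emphasis"] = sum(n / r ** 2 for (g, r), n in runs.items()) / nr
    out["long_run_emphasis"] = sum(n * r ** 2 for (g, r), n in runs.items()) / nr
    out["gray_level_nonuniformity"] = sum(v ** 2 for v in row.values()) / nr
    out["run_length_nonuniformity"] = sum(v ** 2 for v in col.values()) / nr
    out["run_percentage"] = nr / n_pixels
    out["low_gray_level_run_emphasis"] = sum(
        n / (g + 1) ** 2 for (g, r), n in runs.items()) / nr
    out["high_gray_level_run_emphasis"] = sum(
        n * (g + 1) ** 2 for (g, r), n in runs.items()) / nr
    out["short_run_low_gray_level_emphasis"] = sum(
        n / ((g + 1) ** 2 * r ** 2) for (g, r), n in runs.items()) / nr
    out["short_run_high_gray_level_emphasis"] = sum(
        n * (g + 1) ** 2 / r ** 2 for (g, r), n in runs.items()) / nr
    out["long_run_low_gray_level_emphasis"] = sum(
        n * r ** 2 / (g + 1) ** 2 for (g, r), n in runs.items()) / nr
    out["long_run_high_gray_level_emphasis"] = sum(
        n * (g + 1) ** 2 * r ** 2 for (g, r), n in runs.items()) / nr
    return out


def ellipse_pixel_count(a, b, cy, cx, H, W):
    """Exhaustive point-in-ellipse lattice count."""
    n = 0
    for r in range(H):
        for c in range(W):
            if ((r - cy) / a) ** 2 + ((c - cx) / b) ** 2 <= 1.0:
                n += 1
    return n
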