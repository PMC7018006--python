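"""The 730-feature texture catalogue: first-order, GLCM and GLRLM features
on the original patch and its four one-level wavelet subbands.

Gray-level co-occurrence (GLCM) and run-length (GLRLM) matrices are built
directly from the masked patch — pairs/runs with any endpoint outside the
ROI mask are discarded, which is why scikit-image's rectangular
``graycomatrix`` is not used.  Feature formulas follow the classical
Haralick/Galloway definitions; gray levels enter the formulas 1-based
(quantized level g contributes as g+1), and entropy-type sums use log
base 2 with log(0) := 0.

Angles use the image convention with rows growing downward: 0 deg pairs
horizontally, 90 deg vertically, 45 deg along anti-diagonals and 135 deg
along main diagonals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pywt

from .catalogue import (
    ANGLES,
    CATALOGUE,
    FIRST_ORDER,
    GLCM,
    GLRLM,
    SUBBANDS,
)
from .roi import EmptyRoiError, RoiPatch, quantize

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class DegenerateMatrixError(ValueError):
    pass


class PatchTooSmallError(ValueError):
    pass


@dataclass
class TextureMatrix:
    kind: str                 # "glcm" | "glrlm"
    angle: int
    matrix: np.ndarray        # GLCM: normalized probabilities; GLRLM: raw counts
    normalized: bool
    n_pixels: Optional[int] = None  # masked pixel count (GLRLM)


@dataclass
class FeatureVector:
    """All 730 catalogue features for one lesion, in catalogue order."""

    lesion_id: str
    values: Dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values, name=self.lesion_id)


# --------------------------------------------------------------------------
# first-order statistics

def first_order(patch: RoiPatch, bins: Optional[int] = None) -> Dict[str, float]:
    """The 14 intensity-histogram statistics over masked pixels.

    ``bins`` defaults to the patch's quantization levels (256 bins of
    width 1 at the default).  With fewer than two distinct values the
    sample moments are undefined; skewness and kurtosis are returned as
    0 with a warning.
    """
    x = np.asarray(patch.masked_values, dtype=float)
    if x.size == 0:
        raise EmptyRoiError("empty ROI")
    if bins is None:
        bins = patch.levels
    n = x.size
    counts = np.bincount(x.astype(np.int64), minlength=bins)
    p = counts[counts > 0] / n

    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    if np.unique(x).size < 2:
        warnings.warn("fewer than 2 distinct values: skewness/kurtosis set to 0")
        skew = kurt = 0.0
    else:
        m3 = np.mean(dev**3)
        m4 = np.mean(dev**4)
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    return {
        "energy": float(np.sum(x**2)),
        "entropy": float(-np.sum(p * np.log2(p))),
        "kurtosis": float(kurt),
        "maximum": float(x.max()),
        "mean": float(mean),
        "mean_absolute_deviation": float(np.mean(np.abs(dev))),
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "range": float(x.max() - x.min()),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "skewness": float(skew),
        "standard_deviation": float(np.sqrt(m2)),
        "uniformity": float(np.sum(p**2)),
        "variance": float(m2),
    }


# --------------------------------------------------------------------------
# GLCM

def glcm(patch: RoiPatch, angle: int, distance: int = 1) -> TextureMatrix:
    """Symmetric, normalized co-occurrence matrix over in-mask pixel pairs."""
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_OFFSETS)}")
    vals = np.asarray(patch.values, dtype=np.int64)
    mask = np.asarray(patch.mask, dtype=bool)
    G = patch.levels
    H, W = vals.shape
    dr, dc = (d * distance for d in _OFFSETS[angle])
    ra = slice(max(0, -dr), H - max(0, dr))
    ca = slice(max(0, -dc), W - max(0, dc))
    rb = slice(max(0, dr), H - max(0, -dr))
    cb = slice(max(0, dc), W - max(0, -dc))
    mm = mask[ra, ca] & mask[rb, cb]
    if not mm.any():
        raise DegenerateMatrixError("degenerate matrix: no valid pixel pairs")
    i = vals[ra, ca][mm]
    j = vals[rb, cb][mm]
    # symmetric counts, built sparsely (pair codes, both directions)
    codes = np.concatenate((i * G + j, j * G + i))
    uniq, cnt = np.unique(codes, return_counts=True)
    prob = cnt / cnt.sum()
    P = np.zeros((G, G))
    P.flat[uniq] = prob
    tm = TextureMatrix(kind="glcm", angle=angle, matrix=P, normalized=True)
    tm._sparse = (uniq // G, uniq % G, prob)  # reused by glcm_features
    return tm


def glcm_features(m: TextureMatrix) -> Dict[str, float]:
    """The 22 co-occurrence features of a normalized GLCM.

    Degenerate conventions: correlation is 0 when either marginal has no
    variance; the informational measures are 0 when the marginal
    entropies vanish; inverse variance sums only off-diagonal terms.
    """
    if m.kind != "glcm" or not m.normalized:
        raise ValueError("expected a normalized GLCM")
    P = np.asarray(m.matrix, dtype=float)
    G = P.shape[0]
    sparse = getattr(m, "_sparse", None)
    if sparse is not None:
        ii, jj, p = sparse
    else:
        ii, jj = np.nonzero(P)
        p = P[ii, jj]
    gi = ii + 1.0  # 1-based gray levels
    gj = jj + 1.0

    levels = np.arange(1, G + 1, dtype=float)
    px = np.bincount(ii, weights=p, minlength=G)
    py = np.bincount(jj, weights=p, minlength=G)
    mu_x = float(levels @ px)
    mu_y = float(levels @ py)
    sig_x = float(np.sqrt(((levels - mu_x) ** 2) @ px))
    sig_y = float(np.sqrt(((levels - mu_y) ** 2) @ py))

    d = np.abs(gi - gj)
    s = gi + gj
    # p_{x+y}: distribution of i+j (values 2..2G); p_{x-y}: of |i-j|
    pxy_sum = np.bincount(ii + jj, weights=p, minlength=2 * G - 1)
    ks = np.arange(2 * G - 1, dtype=float) + 2.0
    pxy_diff = np.bincount(np.abs(ii - jj), weights=p, minlength=G)
    kd = np.arange(G, dtype=float)

    def ent(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q)))

    HXY = ent(p)
    HX = ent(px)
    HY = ent(py)
    HXY1 = float(-np.sum(p * np.log2(px[ii] * py[jj])))
    occ = np.nonzero(px)[0]
    q = np.outer(px[occ], py[occ])
    HXY2 = float(-np.sum(q * np.log2(q)))

    autocorr = float(np.sum(p * gi * gj))
    cshift = s - mu_x - mu_y
    contrast = float(np.sum(p * d**2))
    if sig_x * sig_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 0.0
    denom_imc = max(HX, HY)
    imc1 = (HXY - HXY1) / denom_imc if denom_imc > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))
    off = d > 0
    sa = float(ks @ pxy_sum)

    return {
        "autocorrelation": autocorr,
        "cluster_prominence": float(np.sum(p * cshift**4)),
        "cluster_shade": float(np.sum(p * cshift**3)),
        "cluster_tendency": float(np.sum(p * cshift**2)),
        "contrast": contrast,
        "correlation": float(correlation),
        "difference_entropy": ent(pxy_diff),
        "dissimilarity": float(np.sum(p * d)),
        "energy": float(np.sum(p**2)),
        "entropy": HXY,
        "homogeneity_1": float(np.sum(p / (1.0 + d))),
        "homogeneity_2": float(np.sum(p / (1.0 + d**2))),
        "informational_measure_of_correlation_1": float(imc1),
        "informational_measure_of_correlation_2": imc2,
        "inverse_difference_moment_normalized": float(np.sum(p / (1.0 + d**2 / G**2))),
        "inverse_difference_normalized": float(np.sum(p / (1.0 + d / G))),
        "inverse_variance": float(np.sum(p[off] / d[off] ** 2)),
        "maximum_probability": float(p.max()),
        "sum_average": sa,
        "sum_entropy": ent(pxy_sum),
        "sum_variance": float(((ks - sa) ** 2) @ pxy_sum),
        "variance": float(np.sum(p * (gi - mu_x) ** 2)),
    }


# --------------------------------------------------------------------------
# GLRLM

def _rle_lines(stream_vals: np.ndarray, stream_valid: np.ndarray, G: int, rmax: int):
    """Run-length-encode a concatenated stream of lines (invalid = break)."""
    v = stream_vals
    valid = stream_valid
    prev_valid = np.concatenate(([False], valid[:-1]))
    prev_val = np.concatenate(([-1], v[:-1]))
    starts = valid & (~prev_valid | (v != prev_val))
    if not starts.any():
        return np.zeros((G, rmax), dtype=np.int64)
    run_id = np.cumsum(starts) - 1
    lengths = np.bincount(run_id[valid])
    grays = v[starts]
    flat = np.bincount(grays * rmax + (lengths - 1), minlength=G * rmax)
    return flat.reshape(G, rmax)


def glrlm(patch: RoiPatch, angle: int) -> TextureMatrix:
    """Raw-count run-length matrix along the angle's direction.

    M[g, r-1] counts maximal runs of quantized level g with length r,
    runs wholly inside the mask (mask gaps break runs).
    """
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_OFFSETS)}")
    vals = np.asarray(patch.values, dtype=np.int64)
    mask = np.asarray(patch.mask, dtype=bool)
    npix = int(mask.sum())
    if npix == 0:
        raise EmptyRoiError("empty ROI")
    H, W = vals.shape
    G = patch.levels
    rmax = max(H, W)

    if angle == 0:
        lines_v = [vals[r, :] for r in range(H)]
        lines_m = [mask[r, :] for r in range(H)]
    elif angle == 90:
        lines_v = [vals[:, c] for c in range(W)]
        lines_m = [mask[:, c] for c in range(W)]
    elif angle == 135:  # along main diagonals (step (1, 1))
        offs = range(-(H - 1), W)
        lines_v = [vals.diagonal(k) for k in offs]
        lines_m = [mask.diagonal(k) for k in offs]
    else:  # 45: along anti-diagonals (step (-1, 1))
        fv, fm = np.flipud(vals), np.flipud(mask)
        offs = range(-(H - 1), W)
        lines_v = [fv.diagonal(k) for k in offs]
        lines_m = [fm.diagonal(k) for k in offs]

    sep_v = np.array([0], dtype=np.int64)
    sep_m = np.array([False])
    stream_v = np.concatenate([np.concatenate((lv, sep_v)) for lv in lines_v])
    stream_m = np.concatenate([np.concatenate((lm, sep_m)) for lm in lines_m])
    M = _rle_lines(stream_v, stream_m, G, rmax)
    return TextureMatrix(kind="glrlm", angle=angle, matrix=M, normalized=False,
                         n_pixels=npix)


def glrlm_features(m: TextureMatrix, n_pixels: Optional[int] = None) -> Dict[str, float]:
    """The 11 run-length features of a raw-count GLRLM."""
    if m.kind != "glrlm" or m.normalized:
        raise ValueError("expected a raw-count GLRLM")
    if n_pixels is None:
        n_pixels = m.n_pixels
    M = np.asarray(m.matrix, dtype=float)
    nr = M.sum()
    if nr == 0:
        raise DegenerateMatrixError("degenerate matrix: zero total runs")
    gi, ri = np.nonzero(M)
    n = M[gi, ri]
    g = gi + 1.0
    r = ri + 1.0
    row = M.sum(axis=1)
    col = M.sum(axis=0)
    return {
        "short_run_emphasis": float(np.sum(n / r**2) / nr),
        "long_run_emphasis": float(np.sum(n * r**2) / nr),
        "gray_level_nonuniformity": float(np.sum(row**2) / nr),
        "run_length_nonuniformity": float(np.sum(col**2) / nr),
        "run_percentage": float(nr / n_pixels),
        "low_gray_level_run_emphasis": float(np.sum(n / g**2) / nr),
        "high_gray_level_run_emphasis": float(np.sum(n * g**2) / nr),
        "short_run_low_gray_level_emphasis": float(np.sum(n / (g**2 * r**2)) / nr),
        "short_run_high_gray_level_emphasis": float(np.sum(n * g**2 / r**2) / nr),
        "long_run_low_gray_level_emphasis": float(np.sum(n * r**2 / g**2) / nr),
        "long_run_high_gray_level_emphasis": float(np.sum(n * g**2 * r**2) / nr),
    }


# --------------------------------------------------------------------------
# wavelet subbands

def dwt2_subbands(values: np.ndarray, wavelet: str = "haar") -> Dict[str, np.ndarray]:
    """Raw one-level 2-D DWT coefficients (zero-padded boundaries)."""
    cA, (cH, cV, cD) = pywt.dwt2(np.asarray(values, dtype=float), wavelet, mode="zero")
    return {"LL": cA, "LH": cH, "HL": cV, "HH": cD}


def _downsample_mask(mask: np.ndarray, shape: tuple) -> np.ndarray:
    """Subband pixel is in-mask iff any of its 2x2 source pixels is in-mask."""
    m = np.asarray(mask, dtype=bool)
    H, W = m.shape
    ph, pw = (H + 1) // 2 * 2, (W + 1) // 2 * 2
    padded = np.zeros((ph, pw), dtype=bool)
    padded[:H, :W] = m
    half = padded[0::2] | padded[1::2]
    half = half[:, 0::2] | half[:, 1::2]
    out = np.zeros(shape, dtype=bool)
    h = min(shape[0], half.shape[0])
    w = min(shape[1], half.shape[1])
    out[:h, :w] = half[:h, :w]
    return out


def wavelet_subbands(patch: RoiPatch, wavelet: str = "haar") -> Dict[str, RoiPatch]:
    """One-level DWT of the bounding-box patch, per-subband re-quantized.

    The rectangular bounding box is transformed (wavelets need a full
    grid) and the ROI mask is carried down to each subband; masked
    subband coefficients are then min-max re-normalized and re-quantized
    to the patch's gray-level count before texture analysis.
    """
    vals = np.asarray(patch.values, dtype=float)
    if min(vals.shape) < 4:
        raise PatchTooSmallError("patch too small")
    subs = dwt2_subbands(vals, wavelet=wavelet)
    out = {}
    for name, coeffs in subs.items():
        sub_mask = _downsample_mask(patch.mask, coeffs.shape)
        out[name] = quantize(coeffs, sub_mask, patch.levels)
    return out


# --------------------------------------------------------------------------
# the full catalogue

_POINT_MASS_GLCM = TextureMatrix(
    kind="glcm", angle=0, matrix=np.array([[1.0]]), normalized=True
)


def _degenerate_patch(levels: int) -> RoiPatch:
    return RoiPatch(values=np.zeros((1, 1)), mask=np.ones((1, 1), dtype=bool),
                    levels=levels, constant=True)


def _channel_features(patch: RoiPatch, distance: int) -> Dict[str, Dict]:
    """146 features for one channel, keyed by (family, angle)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fo = first_order(patch)
    glcm_by_angle = {}
    glrlm_by_angle = {}
    for angle in ANGLES:
        try:
            gm = glcm(patch, angle, distance=distance)
            glcm_by_angle[angle] = glcm_features(gm)
        except (DegenerateMatrixError, EmptyRoiError):
            # degenerate-limit: features of a point-mass (constant) GLCM
            glcm_by_angle[angle] = glcm_features(
                TextureMatrix("glcm", angle, np.array([[1.0]]), True)
            )
        try:
            rm = glrlm(patch, angle)
            glrlm_by_angle[angle] = glrlm_features(rm)
        except (DegenerateMatrixError, EmptyRoiError):
            # degenerate-limit: one run of length 1 at the lowest level
            glrlm_by_angle[angle] = glrlm_features(
                TextureMatrix("glrlm", angle, np.array([[1.0]]), False, n_pixels=1)
            )
    return {"first_order": fo, "glcm": glcm_by_angle, "glrlm": glrlm_by_angle}


_LONG = {
    "first_order": dict(FIRST_ORDER),
    "glcm": dict(GLCM),
    "glrlm": dict(GLRLM),
}


def extract_all(patch: RoiPatch, distance: int = 1,
                wavelet: str = "haar", lesion_id: str = "") -> FeatureVector:
    """Compute all 730 catalogue features for one lesion.

    Channels are the original patch plus its LL/LH/HL/HH subbands.  Any
    degenerate sub-computation falls back to its documented limit value,
    so the vector always contains exactly 730 finite entries.
    """
    channels: Dict[Optional[str], RoiPatch] = {None: patch}
    try:
        channels.update(wavelet_subbands(patch, wavelet=wavelet))
    except PatchTooSmallError:
        for sb in ("LL", "LH", "HL", "HH"):
            channels[sb] = _degenerate_patch(patch.levels)

    per_channel = {sb: _channel_features(ch, distance) for sb, ch in channels.items()}

    values: Dict[str, float] = {}
    for name in CATALOGUE:
        feats = per_channel[name.subband]
        long = _LONG[name.family][name.abbrev]
        if name.family == "first_order":
            v = feats["first_order"][long]
        else:
            v = feats[name.family][name.angle][long]
        if not np.isfinite(v):  # defensive: catalogue guarantees finiteness
            warnings.warn(f"non-finite value for {name}; set to 0")
            v = 0.0
        values[str(name)] = float(v)
    return FeatureVector(lesion_id=lesion_id or getattr(patch, "lesion_id", ""),
                         values=values)


def features_to_frame(vectors) -> "pandas.DataFrame":
    """Stack FeatureVectors into a (lesion x 730) DataFrame, catalogue order."""
    import pandas as pd

    rows = [fv.to_series() for fv in vectors]
    df = pd.DataFrame(rows)
    df.index.name = "lesion_id"
    return df
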