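"""GLCM texture features of spectral parametric maps.

The map values inside the tumour ROI are uniformly quantised to a small
number of gray levels, symmetric gray-level co-occurrence matrices (GLCMs)
are accumulated for pixel pairs at the four principal directions
(0/45/90/135 degrees; their opposites are covered by symmetry), and three
Haralick features summarise each matrix:

* contrast     = sum_ij P(i,j) (i - j)^2
* correlation  = sum_ij P(i,j) (i - mu_i)(j - mu_j) / (sigma_i sigma_j)
* homogeneity  = sum_ij P(i,j) / (1 + |i - j|)

Features are averaged over the four angles and then over the configured
pixel distances.  Pairs with either pixel outside the ROI are excluded from
the counts (no padding); correlation is reported as undefined (NaN) for
zero-variance maps instead of a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix
from sklearn.base import BaseEstimator, TransformerMixin

ANGLES_DEG = (0, 45, 90, 135)
_ANGLE_RAD = {0: 0.0, 45: np.pi / 4, 90: np.pi / 2, 135: 3 * np.pi / 4}


@dataclass
class QuantizedMap:
    """Integer gray-level image restricted to an ROI."""

    levels: np.ndarray  # int array, levels in [0, n_levels-1]; 0 outside ROI
    n_levels: int
    quantization_range: tuple  # (vmin, vmax) used for binning
    roi_mask: np.ndarray


@dataclass
class GLCM:
    """Normalised symmetric co-occurrence matrix for one offset."""

    matrix: np.ndarray  # (n_levels, n_levels), entries sum to 1
    distance: int
    angle: int  # degrees


@dataclass
class TextureFeatures:
    contrast: float
    correlation: float  # NaN when undefined
    homogeneity: float
    correlation_defined: bool = True
    note: str = ""


def quantize_map(
    values: np.ndarray,
    roi_mask: np.ndarray,
    n_levels: int = 16,
    range_policy: str = "per-map",
    fixed_range: tuple | None = None,
) -> QuantizedMap:
    """Uniformly bin in-ROI map values into ``n_levels`` gray levels.

    ``range_policy`` is ``"per-map"`` (min-max over the ROI; makes the
    features invariant to affine intensity changes) or ``"fixed"`` (a global
    ``fixed_range`` for cross-visit comparability).  Values exactly on a bin
    edge go to the lower bin; the maximum maps to the top level.  A constant
    map quantises to all-zero levels (downstream correlation is then
    undefined).
    """
    values = np.asarray(values, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if values.shape != roi_mask.shape:
        raise ValueError("map and ROI mask shapes differ")
    v = values[roi_mask]
    if v.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    if not np.all(np.isfinite(v)):
        raise ValueError("ROI contains non-finite map values")
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    if range_policy == "per-map":
        vmin, vmax = float(v.min()), float(v.max())
    elif range_policy == "fixed":
        if fixed_range is None:
            raise ValueError("fixed range_policy requires fixed_range=(min, max)")
        vmin, vmax = map(float, fixed_range)
        if vmax <= vmin:
            raise ValueError("fixed_range must be increasing")
    else:
        raise ValueError(f"unknown range_policy {range_policy!r}")

    levels = np.zeros(values.shape, dtype=np.int32)
    if vmax > vmin:
        edges = np.linspace(vmin, vmax, n_levels + 1)
        lv = np.searchsorted(edges, values[roi_mask], side="left") - 1
        levels[roi_mask] = np.clip(lv, 0, n_levels - 1)
    return QuantizedMap(
        levels=levels, n_levels=n_levels, quantization_range=(vmin, vmax), roi_mask=roi_mask
    )


def compute_glcm(quantized: QuantizedMap, distance: int = 1, angle: int = 0) -> GLCM:
    """Symmetric normalised GLCM for one (distance, angle) offset.

    Angle convention: 0 deg pairs along +lateral (columns), 90 deg along
    +axial (rows), 45/135 the diagonals; the symmetric construction also
    counts each opposite direction.  Out-of-ROI pixels are excluded via a
    sentinel gray level whose row/column are dropped before normalisation.
    """
    if angle not in ANGLES_DEG:
        raise ValueError(f"angle must be one of {ANGLES_DEG}")
    if distance < 1:
        raise ValueError("distance must be >= 1 pixel")
    n = quantized.n_levels
    img = quantized.levels.astype(np.uint16, copy=True)
    img[~quantized.roi_mask] = n  # sentinel level
    counts = graycomatrix(
        img, [distance], [_ANGLE_RAD[angle]], levels=n + 1, symmetric=True, normed=False
    )[:, :, 0, 0].astype(float)
    counts = counts[:n, :n]
    total = counts.sum()
    if total == 0:
        raise ValueError("degenerate ROI: no in-ROI pixel pair at this offset")
    return GLCM(matrix=counts / total, distance=distance, angle=angle)


def haralick_features(glcm: GLCM) -> TextureFeatures:
    """Contrast, correlation and homogeneity of a normalised GLCM."""
    P = np.asarray(glcm.matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    if np.any(P < 0) or not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalised (non-negative, summing to 1)")
    n = P.shape[0]
    i = np.arange(n)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum(P * (ii - jj) ** 2))
    homogeneity = float(np.sum(P / (1.0 + np.abs(ii - jj))))
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(np.sum(i * pi))
    mu_j = float(np.sum(i * pj))
    var_i = float(np.sum((i - mu_i) ** 2 * pi))
    var_j = float(np.sum((i - mu_j) ** 2 * pj))
    if var_i <= 0 or var_j <= 0:
        return TextureFeatures(
            contrast=contrast,
            correlation=float("nan"),
            homogeneity=homogeneity,
            correlation_defined=False,
            note="correlation undefined: zero marginal variance",
        )
    corr = float(np.sum(P * (ii - mu_i) * (jj - mu_j)) / np.sqrt(var_i * var_j))
    return TextureFeatures(contrast=contrast, correlation=corr, homogeneity=homogeneity)


class GLCMTexturizer(BaseEstimator, TransformerMixin):
    """Texture feature extractor over (map, ROI) pairs.

    Features are computed per (distance, angle), averaged over the four
    angles, then over distances.  Stateless; ``fit`` only validates
    parameters so the extractor composes with sklearn pipelines.
    """

    def __init__(
        self,
        n_levels: int = 16,
        distances: tuple = (1,),
        range_policy: str = "per-map",
        fixed_range: tuple | None = None,
    ):
        self.n_levels = n_levels
        self.distances = distances
        self.range_policy = range_policy
        self.fixed_range = fixed_range

    def fit(self, X=None, y=None) -> "GLCMTexturizer":
        if len(self.distances) == 0:
            raise ValueError("at least one pixel distance is required")
        return self

    def features(self, values: np.ndarray, roi_mask: np.ndarray) -> TextureFeatures:
        q = quantize_map(
            values, roi_mask, self.n_levels, self.range_policy, self.fixed_range
        )
        per_distance = []
        for d in self.distances:
            feats = [haralick_features(compute_glcm(q, d, a)) for a in ANGLES_DEG]
            contrast = float(np.mean([f.contrast for f in feats]))
            homogeneity = float(np.mean([f.homogeneity for f in feats]))
            corrs = [f.correlation for f in feats if f.correlation_defined]
            corr = float(np.mean(corrs)) if corrs else float("nan")
            per_distance.append((contrast, corr, homogeneity, bool(corrs)))
        contrast = float(np.mean([p[0] for p in per_distance]))
        homogeneity = float(np.mean([p[2] for p in per_distance]))
        defined = [p[1] for p in per_distance if p[3]]
        corr = float(np.mean(defined)) if defined else float("nan")
        return TextureFeatures(
            contrast=contrast,
            correlation=corr,
            homogeneity=homogeneity,
            correlation_defined=bool(defined),
            note="" if defined else "correlation undefined at every angle/distance",
        )

    def transform(self, X) -> np.ndarray:
        """X: iterable of ``(values, roi_mask)`` pairs -> (n, 3) feature array."""
        rows = []
        for values, roi in X:
            f = self.features(values, roi)
            rows.append([f.contrast, f.correlation, f.homogeneity])
        return np.asarray(rows)


def texture_of_map(
    values: np.ndarray,
    roi_mask: np.ndarray,
    distances: tuple = (1,),
    n_levels: int = 16,
    range_policy: str = "per-map",
    fixed_range: tuple | None = None,
) -> TextureFeatures:
    """Functional wrapper: angle- and distance-averaged Haralick features."""
    return (
        GLCMTexturizer(
            n_levels=n_levels,
            distances=distances,
            range_policy=range_policy,
            fixed_range=fixed_range,
        )
        .fit()
        .features(values, roi_mask)
    )
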