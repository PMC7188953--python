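"""Histogram-based global features and 3D texture-matrix features.

Per (volume version, Ng) block the pipeline emits 48 features:

* 8 global features from the within-mask intensity histogram
  (max, min, range, mean, entropy, variance, skewness, kurtosis);
* 9 gray-level co-occurrence (GLCM), 13 run-length (GLRLM), 13 size-zone
  (GLSZM) and 5 neighborhood gray-tone difference (NGTDM) features.

All four texture families merge the 13 unique 3D direction offsets at
distance 1 into a single matrix (not averaged per direction); zones use
26-connectivity and neighborhoods the full 26-voxel shell.  Only within-mask
voxels enter any computation: out-of-mask voxels break runs, are excluded
from co-occurrence pairs, and do not contribute to neighborhood means.

With the default Ng list {16, 32, 64, 96} and the 9 volume versions
(raw + 8 wavelet subband reconstructions) a subject yields
48 x 4 x 9 = 1728 image features; appending age, gender and smoking gives
1731.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import (DEFAULT_NG_LIST, DEFAULT_WAVELET, SUBBAND_LABELS,
                         QuantizedVolume, dwt3_subbands, lloyd_max_quantize,
                         reconstruct_subband)
from .volume_io import ROIMask, VoxelVolume, extract_roi

# the 13 unique distance-1 direction offsets in 3D (26 neighbors / +-sign)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

GLOBAL_FEATURES = ("max", "min", "range", "mean", "entropy", "variance",
                   "skew", "kurt")
GLCM_FEATURES = ("energy", "contrast", "entropy", "homogeneity", "correlation",
                 "sumavg", "variance", "dissimilarity", "autocorr")
GLRLM_FEATURES = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
                  "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV")
GLSZM_FEATURES = ("SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
                  "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV")
NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complex", "strength")

FAMILY_FEATURES: dict[str, tuple[str, ...]] = {
    "Global": GLOBAL_FEATURES,
    "GLCM": GLCM_FEATURES,
    "GLRLM": GLRLM_FEATURES,
    "GLSZM": GLSZM_FEATURES,
    "NGTDM": NGTDM_FEATURES,
}

CLINICAL_FEATURES = ("Age", "Gender", "Smoking")

_EPS = 1e-12
_COARSENESS_CAP = 1.0 / _EPS


class EmptyMatrixError(ValueError):
    """Raised when a texture matrix would have no entries at all."""


# ---------------------------------------------------------------------------
# feature naming grammar ("GLSZM.ZSN @ WT(HHH) Ng=32", "Smoking @ Clinic")

_NAME_RE = re.compile(
    r"^(?:(?P<family>Global|GLCM|GLRLM|GLSZM|NGTDM)\.(?P<feature>\w+) @ "
    r"(?:rawNg=(?P<raw_ng>\d+)|WT\((?P<subband>[LH]{3})\) Ng=(?P<wt_ng>\d+))"
    r"|(?P<clinical>\w+) @ Clinic)$"
)


@dataclass(frozen=True)
class FeatureName:
    """Structured feature identifier rendering to the report grammar."""

    family: str                 # Global | GLCM | GLRLM | GLSZM | NGTDM | Clinic
    feature: str
    volume_tag: str = ""        # "raw" or "WT(<subband>)"; empty for Clinic
    ng: int | None = None

    def __str__(self) -> str:
        if self.family == "Clinic":
            return f"{self.feature} @ Clinic"
        if self.volume_tag == "raw":
            return f"{self.family}.{self.feature} @ rawNg={self.ng}"
        return f"{self.family}.{self.feature} @ {self.volume_tag} Ng={self.ng}"

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        m = _NAME_RE.match(name)
        if not m:
            raise ValueError(f"unparsable feature name: {name!r}")
        if m.group("clinical"):
            return cls("Clinic", m.group("clinical"))
        if m.group("raw_ng"):
            return cls(m.group("family"), m.group("feature"), "raw",
                       int(m.group("raw_ng")))
        return cls(m.group("family"), m.group("feature"),
                   f"WT({m.group('subband')})", int(m.group("wt_ng")))


# ---------------------------------------------------------------------------
# global (histogram) features

def global_features(volume: VoxelVolume | np.ndarray, mask: ROIMask | np.ndarray,
                    qvol: QuantizedVolume) -> dict[str, float]:
    """8 histogram statistics of the within-mask intensities.

    Moments are population moments; kurtosis is non-excess (Gaussian -> 3).
    A zero-variance ROI yields skewness and kurtosis of 0 rather than NaN.
    Entropy is the Shannon entropy (bits) of the quantized-level occupancy.
    """
    arr = volume.intensities if isinstance(volume, VoxelVolume) else np.asarray(volume, float)
    flags = mask.flags if isinstance(mask, ROIMask) else np.asarray(mask, bool)
    vals = arr[flags]
    mean = float(vals.mean())
    var = float(np.mean((vals - mean) ** 2))
    if var > 0:
        skew = float(np.mean((vals - mean) ** 3) / var ** 1.5)
        kurt = float(np.mean((vals - mean) ** 4) / var ** 2)
    else:
        skew = kurt = 0.0
    counts = np.bincount(qvol.mask_levels)[1:]
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "max": float(vals.max()),
        "min": float(vals.min()),
        "range": float(vals.max() - vals.min()),
        "mean": mean,
        "entropy": entropy,
        "variance": var,
        "skew": skew,
        "kurt": kurt,
    }


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(qvol: QuantizedVolume) -> np.ndarray:
    """Symmetric co-occurrence matrix over the 13 directions, normalized to 1."""
    ng = qvol.ng
    lvl = qvol.levels
    flags = qvol.mask
    mat = np.zeros((ng, ng))
    for d in DIRECTIONS_13:
        src, dst = _offset_slices(lvl.shape, d)
        a = lvl[src]
        b = lvl[dst]
        ok = flags[src] & flags[dst]
        if not ok.any():
            continue
        np.add.at(mat, (a[ok] - 1, b[ok] - 1), 1.0)
        np.add.at(mat, (b[ok] - 1, a[ok] - 1), 1.0)
    total = mat.sum()
    if total == 0:
        raise EmptyMatrixError("no valid voxel pair for the GLCM")
    return mat / total


def _offset_slices(shape, d):
    """Pair of slice tuples so arr[src] and arr[dst] are offset by d."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step == 1:
            src.append(slice(0, n - 1))
            dst.append(slice(1, n))
        else:  # step == -1
            src.append(slice(1, n))
            dst.append(slice(0, n - 1))
    return tuple(src), tuple(dst)


def glcm_features(qvol: QuantizedVolume) -> dict[str, float]:
    p = glcm_matrix(qvol)
    ng = p.shape[0]
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    mu = float((i * p).sum())          # symmetric: row mean == column mean
    sigma2 = float(((i - mu) ** 2 * p).sum())
    pos = p > 0
    out = {
        "energy": float((p ** 2).sum()),
        "contrast": float(((i - j) ** 2 * p).sum()),
        "entropy": float(-(p[pos] * np.log2(p[pos])).sum()),
        "homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "correlation": (float(((i - mu) * (j - mu) * p).sum() / sigma2)
                        if sigma2 > 0 else 0.0),
        "sumavg": float(((i + j) * p).sum()),
        "variance": sigma2,
        "dissimilarity": float((np.abs(i - j) * p).sum()),
        "autocorr": float((i * j * p).sum()),
    }
    return out


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(qvol: QuantizedVolume) -> np.ndarray:
    """Run-length counts r(level, length) merged over the 13 directions.

    A run is a maximal straight segment of equal-level within-mask voxels;
    out-of-mask voxels break runs.
    """
    lvl = qvol.levels
    flags = qvol.mask
    ng = qvol.ng
    max_len = max(lvl.shape) * 2  # diagonal runs cannot exceed max dim anyway
    mat = np.zeros((ng, max_len))
    shape = np.array(lvl.shape)
    coords = np.argwhere(flags)
    for d in np.array(DIRECTIONS_13):
        prev = coords - d
        inb = ((prev >= 0) & (prev < shape)).all(axis=1)
        prev_ok = np.zeros(len(coords), dtype=bool)
        pi = prev[inb]
        prev_ok[inb] = (flags[pi[:, 0], pi[:, 1], pi[:, 2]]
                        & (lvl[pi[:, 0], pi[:, 1], pi[:, 2]]
                           == lvl[coords[inb, 0], coords[inb, 1], coords[inb, 2]]))
        starts = coords[~prev_ok]
        run_lvl = lvl[starts[:, 0], starts[:, 1], starts[:, 2]]
        length = np.ones(len(starts), dtype=int)
        cur = starts.copy()
        active = np.arange(len(starts))
        while active.size:
            nxt = cur[active] + d
            inb = ((nxt >= 0) & (nxt < shape)).all(axis=1)
            ok = np.zeros(active.size, dtype=bool)
            ni = nxt[inb]
            ok[inb] = (flags[ni[:, 0], ni[:, 1], ni[:, 2]]
                       & (lvl[ni[:, 0], ni[:, 1], ni[:, 2]] == run_lvl[active[inb]]))
            cur[active[ok]] = nxt[ok]
            length[active[ok]] += 1
            active = active[ok]
        np.add.at(mat, (run_lvl - 1, length - 1), 1.0)
    if mat.sum() == 0:
        raise EmptyMatrixError("no run for the GLRLM")
    return mat[:, : int(np.flatnonzero(mat.any(axis=0))[-1]) + 1]


def _rlm_style_features(mat: np.ndarray, n_voxels: int, names: Sequence[str],
                        total_norm: float) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas over counts r(level, size)."""
    nr = mat.sum()
    p = mat / nr
    i = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    ri = mat.sum(axis=1)
    rj = mat.sum(axis=0)
    mu_i = float((i[:, 0] * p.sum(axis=1)).sum())
    mu_j = float((j[0, :] * p.sum(axis=0)).sum())
    vals = (
        float((mat / j ** 2).sum() / nr),          # SRE / SZE
        float((mat * j ** 2).sum() / nr),          # LRE / LZE
        float((ri ** 2).sum() / nr),               # GLN
        float((rj ** 2).sum() / nr),               # RLN / ZSN
        float(nr / total_norm),                    # RP / ZP
        float((mat / i ** 2).sum() / nr),          # LGRE / LGZE
        float((mat * i ** 2).sum() / nr),          # HGRE / HGZE
        float((mat / (i ** 2 * j ** 2)).sum() / nr),   # SRLGE / SZLGE
        float((mat * i ** 2 / j ** 2).sum() / nr),     # SRHGE / SZHGE
        float((mat * j ** 2 / i ** 2).sum() / nr),     # LRLGE / LZLGE
        float((mat * i ** 2 * j ** 2).sum() / nr),     # LRHGE / LZHGE
        float(((i - mu_i) ** 2 * p).sum()),        # GLV
        float(((j - mu_j) ** 2 * p).sum()),        # RLV / ZSV
    )
    return dict(zip(names, vals))


def glrlm_features(qvol: QuantizedVolume) -> dict[str, float]:
    mat = glrlm_matrix(qvol)
    n_vox = int(qvol.mask.sum())
    return _rlm_style_features(mat, n_vox, GLRLM_FEATURES,
                               total_norm=13.0 * n_vox)


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(qvol: QuantizedVolume) -> np.ndarray:
    """Zone counts z(level, size): 26-connected equal-level components."""
    lvl = qvol.levels
    flags = qvol.mask
    ng = qvol.ng
    n_vox = int(flags.sum())
    mat = np.zeros((ng, n_vox))
    for g in np.unique(lvl[flags]):
        labeled, n = ndimage.label((lvl == g) & flags, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        np.add.at(mat, (np.full(n, g - 1), sizes - 1), 1.0)
    if mat.sum() == 0:
        raise EmptyMatrixError("no zone for the GLSZM")
    return mat[:, : int(np.flatnonzero(mat.any(axis=0))[-1]) + 1]


def glszm_features(qvol: QuantizedVolume) -> dict[str, float]:
    mat = glszm_matrix(qvol)
    n_vox = int(qvol.mask.sum())
    return _rlm_style_features(mat, n_vox, GLSZM_FEATURES, total_norm=float(n_vox))


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_table(qvol: QuantizedVolume) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): occupancy and accumulated neighborhood deviation.

    s_i sums |i - mean of the within-mask 26-neighborhood| over mask voxels of
    level i that have at least one within-mask neighbor.
    """
    lvl = qvol.levels.astype(float)
    flags = qvol.mask
    ng = qvol.ng
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.correlate(lvl * flags, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(flags.astype(float), kernel, mode="constant",
                                cval=0.0)
    valid = flags & (nbr_cnt > 0.5)
    dev = np.zeros_like(lvl)
    dev[valid] = np.abs(lvl[valid] - nbr_sum[valid] / nbr_cnt[valid])
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    levels_v = qvol.levels[valid]
    np.add.at(n_i, levels_v - 1, 1.0)
    np.add.at(s_i, levels_v - 1, dev[valid])
    return n_i, s_i


def ngtdm_features(qvol: QuantizedVolume) -> dict[str, float]:
    n_i, s_i = ngtdm_table(qvol)
    n_tot = n_i.sum()
    if n_tot == 0:
        # e.g. a single-voxel mask: no voxel has any neighbor
        return {"coarseness": _COARSENESS_CAP, "contrast": 0.0, "busyness": 0.0,
                "complex": 0.0, "strength": 0.0}
    p_i = n_i / n_tot
    grades = np.arange(1, qvol.ng + 1, dtype=float)
    occ = p_i > 0
    n_gp = int(occ.sum())
    ps = float((p_i * s_i).sum())
    coarseness = min(1.0 / ps, _COARSENESS_CAP) if ps > _EPS else _COARSENESS_CAP

    pi_o = p_i[occ]
    gi_o = grades[occ]
    si_o = s_i[occ]
    diff2 = (gi_o[:, None] - gi_o[None, :]) ** 2
    if n_gp > 1:
        contrast = float((pi_o[:, None] * pi_o[None, :] * diff2).sum()
                         / (n_gp * (n_gp - 1)) * si_o.sum() / n_tot)
    else:
        contrast = 0.0
    busy_den = float(np.abs(gi_o[:, None] * pi_o[:, None]
                            - gi_o[None, :] * pi_o[None, :]).sum())
    busyness = ps / busy_den if busy_den > _EPS else 0.0
    psum = pi_o[:, None] + pi_o[None, :]
    ssum = pi_o[:, None] * si_o[:, None] + pi_o[None, :] * si_o[None, :]
    complexity = float((np.abs(gi_o[:, None] - gi_o[None, :]) * ssum
                        / (n_tot * psum)).sum())
    s_tot = float(si_o.sum())
    strength = (float((psum * diff2).sum()) / s_tot if s_tot > _EPS else 0.0)
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness,
            "complex": complexity, "strength": strength}


FAMILY_EXTRACTORS = {
    "GLCM": glcm_features,
    "GLRLM": glrlm_features,
    "GLSZM": glszm_features,
    "NGTDM": ngtdm_features,
}


# ---------------------------------------------------------------------------
# per-subject feature vector and cohort table

def extract_feature_vector(volume: VoxelVolume, mask: ROIMask,
                           ng_list: Sequence[int] = DEFAULT_NG_LIST,
                           kernel: str = DEFAULT_WAVELET) -> dict[str, float]:
    """All image features for one subject: 48 per (version, Ng) block.

    The volume is first cropped to the tight bounding box of the mask, then
    decomposed into 8 wavelet subband reconstructions.  Each of the 9 volume
    versions is quantized independently at each Ng (subband intensities have
    their own dynamic range) and the 8 global + 40 textural features are
    emitted per block, giving 48 x |ng_list| x 9 features.

    Ordering: volume version (raw, LLL..HHH), then Ng ascending, then family
    (Global, GLCM, GLRLM, GLSZM, NGTDM), then feature.
    """
    roi_vol, roi_mask = extract_roi(volume, mask, pad=0)
    subbands = dwt3_subbands(roi_vol, kernel=kernel)
    versions: list[tuple[str, np.ndarray]] = [("raw", roi_vol.intensities)]
    versions += [(f"WT({lab})", reconstruct_subband(subbands, lab))
                 for lab in SUBBAND_LABELS]
    out: dict[str, float] = {}
    for tag, arr in versions:
        for ng in ng_list:
            qvol = lloyd_max_quantize(arr, roi_mask.flags, ng)
            blocks = {"Global": global_features(arr, roi_mask.flags, qvol)}
            for fam, fn in FAMILY_EXTRACTORS.items():
                blocks[fam] = fn(qvol)
            for fam in FAMILY_FEATURES:
                for feat in FAMILY_FEATURES[fam]:
                    out[str(FeatureName(fam, feat, tag, ng))] = blocks[fam][feat]
    return out


@dataclass
class FeatureTable:
    """Cohort feature matrix: subjects x named feature columns plus labels."""

    data: pd.DataFrame                  # index = subject ids
    labels: np.ndarray                  # 0/1 per subject, positive class = 1
    meta: pd.DataFrame | None = None    # e.g. race, retained but not a feature
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.data):
            raise ValueError("labels length does not match table rows")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature columns")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "FeatureTable":
        meta = None if self.meta is None else self.meta.copy()
        return FeatureTable(self.data.copy(), self.labels.copy(), meta,
                            dict(self.manifest))


def assemble_feature_table(subjects: Iterable, ng_list: Sequence[int] = DEFAULT_NG_LIST,
                           kernel: str = DEFAULT_WAVELET,
                           include_clinical: bool = True) -> FeatureTable:
    """Extract every subject's features and stack them into a FeatureTable.

    ``subjects`` yields objects with .volume, .mask, .clinical and .label
    (see synthetic.SyntheticSubject) or (volume, mask, clinical, label)
    tuples.  Clinical covariates age / gender (male=1) / smoking (ever=1)
    are appended as features when ``include_clinical``; race is retained as
    row metadata only.
    """
    rows, labels, ids, meta_rows = [], [], [], []
    for s in subjects:
        if hasattr(s, "volume"):
            vol, msk, clin, label = s.volume, s.mask, s.clinical, s.label
        else:
            vol, msk, clin, label = s
        vec = extract_feature_vector(vol, msk, ng_list=ng_list, kernel=kernel)
        if include_clinical:
            vec[str(FeatureName("Clinic", "Age"))] = float(clin.age)
            vec[str(FeatureName("Clinic", "Gender"))] = float(clin.gender)
            vec[str(FeatureName("Clinic", "Smoking"))] = float(clin.smoking)
        rows.append(vec)
        labels.append(int(label))
        ids.append(clin.subject_id)
        meta_rows.append({"race": clin.race})
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate subject ids")
    labels = np.asarray(labels)
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("both classes must be present")
    df = pd.DataFrame(rows, index=ids)
    meta = pd.DataFrame(meta_rows, index=ids)
    manifest = {"kernel": kernel, "ng_list": list(ng_list),
                "include_clinical": include_clinical,
                "versions": ["raw"] + [f"WT({lab})" for lab in SUBBAND_LABELS],
                "feature_order": list(df.columns)}
    return FeatureTable(df, labels, meta, manifest)
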