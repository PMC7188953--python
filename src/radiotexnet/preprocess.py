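"""Gray-level quantization and 3D wavelet subband decomposition.

Texture matrices require a small integer gray-level alphabet.  Rather than
uniform binning, intensities inside the tumor mask are quantized with the
Lloyd-Max algorithm: an adaptive scalar quantizer that iterates between
nearest-centroid assignment and conditional-mean centroid updates, which
minimizes the within-mask quantization mean squared error for a given number
of levels Ng.

The wavelet stage performs a single-level separable 3D discrete wavelet
transform, yielding the 8 subbands {LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH}
(character order = filter applied along axes x, y, z; L = low-pass,
H = high-pass).  Each subband can be reconstructed back to image space on its
own, so the texture feature set can be recomputed per subband image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .volume_io import ROIMask, VoxelVolume

SUBBAND_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

#: map a subband label to the pywt coefficient key ('a' = approx = L).
_LABEL_TO_KEY = {lab: lab.replace("L", "a").replace("H", "d") for lab in SUBBAND_LABELS}

DEFAULT_WAVELET = "db1"
DEFAULT_NG_LIST = (16, 32, 64, 96)


@dataclass
class QuantizedVolume:
    """Within-mask integer gray levels 1..Ng with the fitted quantizer."""

    levels: np.ndarray          # int grid; 0 outside the mask
    mask: np.ndarray            # boolean grid
    ng: int                     # requested level count
    boundaries: np.ndarray      # decision thresholds, strictly increasing
    centroids: np.ndarray       # representative values per occupied level
    mse_trace: list[float] = field(default_factory=list)

    @property
    def occupied_levels(self) -> int:
        return len(np.unique(self.levels[self.mask]))

    @property
    def mask_levels(self) -> np.ndarray:
        """Levels of the within-mask voxels, in array scan order."""
        return self.levels[self.mask]


def _lloyd_iterations(values: np.ndarray, ng: int, tol: float, max_iter: int
                      ) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Run Lloyd-Max on a 1D value array; returns (labels0, centroids, mse_trace)."""
    n = values.size
    # equal-quantile initialization: Ng-1 boundaries at the k/Ng quantiles
    qs = np.quantile(values, np.arange(1, ng) / ng)
    labels = np.searchsorted(qs, values, side="right")
    centroids = np.empty(ng)
    for k in range(ng):
        sel = labels == k
        centroids[k] = values[sel].mean() if sel.any() else np.nan
    # seed any initially empty level from its neighbours' midpoint
    if np.isnan(centroids).any():
        occ = ~np.isnan(centroids)
        centroids = np.interp(np.arange(ng), np.flatnonzero(occ), centroids[occ])
    trace: list[float] = []
    for _ in range(max_iter):
        order = np.argsort(centroids, kind="stable")
        centroids = centroids[order]
        bounds = 0.5 * (centroids[:-1] + centroids[1:])
        # a value exactly on a boundary goes to the higher level
        labels = np.searchsorted(bounds, values, side="right")
        counts = np.bincount(labels, minlength=ng)
        # deterministic re-seeding: split the most populous splittable level
        # (>= 2 distinct values, guaranteed to exist while any level is empty
        # because #distinct > ng) at the median of its distinct values
        while (counts == 0).any():
            empty = int(np.flatnonzero(counts == 0)[0])
            splittable = np.array([
                counts[k] >= 2 and np.unique(values[labels == k]).size >= 2
                for k in range(ng)
            ])
            donor = int(np.argmax(np.where(splittable, counts, -1)))
            sel = labels == donor
            uvals = np.unique(values[sel])
            cut = uvals[uvals.size // 2]
            low_sel = sel & (values < cut)
            labels[low_sel] = empty
            centroids[empty] = values[low_sel].mean()
            centroids[donor] = values[sel & ~low_sel].mean()
            counts = np.bincount(labels, minlength=ng)
        new_centroids = np.array([
            values[labels == k].mean() if counts[k] else centroids[k]
            for k in range(ng)
        ])
        order = np.argsort(new_centroids, kind="stable")
        new_centroids = new_centroids[order]
        remap = np.empty(ng, dtype=int)
        remap[order] = np.arange(ng)
        labels = remap[labels]
        mse = float(np.mean((values - new_centroids[labels]) ** 2))
        trace.append(mse)
        shift = float(np.max(np.abs(new_centroids - centroids[order])))
        centroids = new_centroids
        if shift < tol:
            break
    return labels, centroids, trace


def lloyd_max_quantize(volume: VoxelVolume | np.ndarray, mask: ROIMask | np.ndarray,
                       ng: int, tol: float | None = None, max_iter: int = 200
                       ) -> QuantizedVolume:
    """Quantize within-mask intensities to levels 1..Ng by Lloyd-Max.

    The quantizer is fit on the within-mask voxels only and is deterministic
    (equal-quantile initialization, no random restarts).  ``tol`` defaults to
    1e-6 x the within-mask intensity range.  If the ROI has fewer distinct
    values than Ng the quantizer degrades gracefully to one level per distinct
    value, leaving the remaining levels unoccupied (MSE 0).
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    arr = volume.intensities if isinstance(volume, VoxelVolume) else np.asarray(volume, float)
    flags = mask.flags if isinstance(mask, ROIMask) else np.asarray(mask, bool)
    if arr.shape != flags.shape:
        raise ValueError("volume and mask shapes differ")
    if not flags.any():
        raise ValueError("empty mask")
    values = arr[flags]
    distinct = np.unique(values)
    levels = np.zeros(arr.shape, dtype=np.int32)
    if distinct.size <= ng:
        labels = np.searchsorted(distinct, values)
        centroids = distinct
        bounds = 0.5 * (distinct[:-1] + distinct[1:])
        trace = [0.0]
    else:
        if tol is None:
            tol = 1e-6 * float(values.max() - values.min())
        labels, centroids, trace = _lloyd_iterations(values, ng, tol, max_iter)
        bounds = 0.5 * (centroids[:-1] + centroids[1:])
    levels[flags] = labels + 1
    return QuantizedVolume(levels=levels, mask=flags, ng=ng,
                           boundaries=np.asarray(bounds, float),
                           centroids=np.asarray(centroids, float),
                           mse_trace=trace)


@dataclass
class SubbandSet:
    """Coefficient blocks of a single-level 3D DWT, keyed by subband label."""

    bands: dict[str, np.ndarray]
    kernel_name: str
    original_shape: tuple[int, int, int]
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if set(self.bands) != set(SUBBAND_LABELS):
            raise ValueError(f"expected the 8 labels {SUBBAND_LABELS}")


def dwt3_subbands(volume: VoxelVolume | np.ndarray, kernel: str = DEFAULT_WAVELET
                  ) -> SubbandSet:
    """Single-level separable 3D DWT with symmetric half-sample extension."""
    arr = volume.intensities if isinstance(volume, VoxelVolume) else np.asarray(volume, float)
    wav = pywt.Wavelet(kernel)
    if min(arr.shape) < wav.dec_len:
        raise ValueError(
            f"volume shape {arr.shape} smaller than the {kernel} filter support "
            f"({wav.dec_len})"
        )
    coeffs = pywt.dwtn(arr, wav, mode="symmetric")
    bands = {lab: coeffs[_LABEL_TO_KEY[lab]] for lab in SUBBAND_LABELS}
    return SubbandSet(bands=bands, kernel_name=kernel, original_shape=arr.shape)


def reconstruct_subband(subbands: SubbandSet, label: str) -> np.ndarray:
    """Inverse 3D DWT with every subband except ``label`` zeroed.

    Output is trimmed to the recorded original shape (odd dimensions grow by
    one sample under the extension convention).
    """
    if label not in SUBBAND_LABELS:
        raise ValueError(f"unknown subband label {label!r}")
    coeffs = {}
    for lab in SUBBAND_LABELS:
        block = subbands.bands[lab]
        coeffs[_LABEL_TO_KEY[lab]] = block if lab == label else np.zeros_like(block)
    rec = pywt.idwtn(coeffs, subbands.kernel_name, mode=subbands.mode)
    sx, sy, sz = subbands.original_shape
    return np.asarray(rec)[:sx, :sy, :sz]


def inverse_dwt3(subbands: SubbandSet) -> np.ndarray:
    """Full inverse transform (all 8 subbands), trimmed to the original shape."""
    coeffs = {_LABEL_TO_KEY[lab]: subbands.bands[lab] for lab in SUBBAND_LABELS}
    rec = pywt.idwtn(coeffs, subbands.kernel_name, mode=subbands.mode)
    sx, sy, sz = subbands.original_shape
    return np.asarray(rec)[:sx, :sy, :sz]
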