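"""Wavelet-statistic node features for ROI BOLD signals.

Each ROI's time series is decomposed with a 6-level Daubechies-1 (Haar)
discrete wavelet transform, yielding seven coefficient arrays
``[cA6, cD6, cD5, cD4, cD3, cD2, cD1]``: the level-6 approximation captures
persistent slow activity, the detail levels capture transient fluctuations in
dyadic frequency bands.  The node feature vector is the mean and population
variance of the raw signal followed by the mean and population variance of
every coefficient array — 2 + 7 + 7 = 16 features per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .cohort import BoldTimeSeries

__all__ = ["WaveletStats", "NodeFeatureMatrix", "wavelet_decompose",
           "coeff_stats", "node_feature_vector", "featurize_cohort",
           "FEATURE_NAMES", "N_FEATURES"]

#: boundary extension used when the signal length is not a power of two
BOUNDARY_MODE = "symmetric"

_LEVEL_TAGS = ["cA6", "cD6", "cD5", "cD4", "cD3", "cD2", "cD1"]

FEATURE_NAMES: tuple[str, ...] = tuple(
    ["raw_mean", "raw_var"]
    + [f"mean_{t}" for t in _LEVEL_TAGS]
    + [f"var_{t}" for t in _LEVEL_TAGS])

N_FEATURES = len(FEATURE_NAMES)  # 16


@dataclass(frozen=True)
class WaveletStats:
    """Coefficient arrays of one decomposition plus their mean/variance."""

    coeff_arrays: tuple[np.ndarray, ...]
    means: np.ndarray
    variances: np.ndarray


@dataclass(frozen=True)
class NodeFeatureMatrix:
    """Per-subject node features: ``values`` is N_roi x 16."""

    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != N_FEATURES:
            raise ValueError(f"node feature matrix must be N_roi x {N_FEATURES}")
        if not np.all(np.isfinite(v)):
            raise ValueError("node features contain non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


def wavelet_decompose(signal: np.ndarray, levels: int = 6,
                      wavelet_name: str = "db1") -> list[np.ndarray]:
    """6-level DWT of one signal, returned as ``[cA6, cD6, ..., cD1]``.

    The transform uses the orthonormal analysis filters of the requested
    wavelet (Haar for ``db1``), so for power-of-two lengths signal energy is
    conserved exactly across the coefficient arrays.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    min_len = 2 ** levels
    if signal.size < min_len:
        raise ValueError(
            f"signal of length {signal.size} is too short for a {levels}-level "
            f"decomposition; minimum length is {min_len}")
    if wavelet_name not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet {wavelet_name!r}")
    return pywt.wavedec(signal, wavelet_name, level=levels, mode=BOUNDARY_MODE)


def coeff_stats(coeff_arrays) -> tuple[np.ndarray, np.ndarray]:
    """Per-array mean and population variance (divisor N, not N-1)."""
    means, variances = [], []
    for arr in coeff_arrays:
        arr = np.asarray(arr, dtype=np.float64)
        if arr.size == 0:
            raise ValueError("empty coefficient array")
        means.append(arr.mean())
        variances.append(arr.var())
    return np.asarray(means), np.asarray(variances)


def wavelet_stats(signal: np.ndarray, levels: int = 6,
                  wavelet_name: str = "db1") -> WaveletStats:
    coeffs = wavelet_decompose(signal, levels, wavelet_name)
    means, variances = coeff_stats(coeffs)
    return WaveletStats(coeff_arrays=tuple(coeffs), means=means,
                        variances=variances)


def node_feature_vector(signal: np.ndarray, levels: int = 6,
                        wavelet_name: str = "db1") -> np.ndarray:
    """16-vector ``[raw_mean, raw_var, means(cA6..cD1), vars(cA6..cD1)]``."""
    signal = np.asarray(signal, dtype=np.float64)
    ws = wavelet_stats(signal, levels, wavelet_name)
    return np.concatenate([[signal.mean(), signal.var()], ws.means,
                           ws.variances])


def featurize_cohort(cohort: list[BoldTimeSeries]) -> list[NodeFeatureMatrix]:
    """One N_roi x 16 feature matrix per subject, ROI order preserved.

    Zero-variance ROI columns are permitted here (their detail features are
    simply zero); they are rejected later by the connectivity stage, whose
    Pearson denominator actually requires variance.
    """
    if not cohort:
        return []
    n_roi = cohort[0].n_roi
    out = []
    for subj in cohort:
        if subj.n_roi != n_roi:
            raise ValueError(
                f"subject {subj.subject_id} has {subj.n_roi} ROIs, "
                f"expected {n_roi}")
        mat = np.stack([node_feature_vector(subj.values[:, r])
                        for r in range(n_roi)])
        out.append(NodeFeatureMatrix(values=mat, subject_id=subj.subject_id))
    return out
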