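"""Marker filtering, kinship estimation and principal-coordinate analysis.

InDel genotypes are treated as biallelic present/absent markers with dosages
0, 0.5 (hemizygous) and 1.  Kinship uses a genomic (Astle-Balding-type)
estimator

    K_ij = (1/M) * sum_m (x_im - p_m) * (x_jm - p_m) / (p_m * (1 - p_m))

with monomorphic markers skipped and missing data handled pairwise-complete.
PCoA is classical metric multidimensional scaling of the 1 - K dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class MarkerFilterConfig:
    max_missing: float = 0.20
    max_het: float = 0.15
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_missing", "max_het", "min_maf"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")


def filter_markers(dosages: pd.DataFrame, cfg: Optional[MarkerFilterConfig] = None) -> pd.DataFrame:
    """Drop markers violating missing/het/MAF thresholds.

    ``dosages`` is marker x sample with values in {0, 0.5, 1} and NaN for
    missing.  A marker is kept iff missing rate < max_missing, hemizygous
    (0.5) rate < max_het, and minor presence-allele frequency > min_maf.
    """
    cfg = cfg or MarkerFilterConfig()
    X = dosages.to_numpy(dtype=float)
    n = X.shape[1]
    missing = np.isnan(X).sum(axis=1) / n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        het = np.nansum(X == 0.5, axis=1) / np.maximum(1, (~np.isnan(X)).sum(axis=1))
        p = np.nanmean(X, axis=1)
    maf = np.minimum(p, 1 - p)
    keep = (missing < cfg.max_missing) & (het < cfg.max_het) & (maf > cfg.min_maf)
    return dosages.loc[keep]


def best_probe_per_indel(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pick one probe per InDel by (call_rate desc, concordance desc, score
    desc), ties broken by lexicographic probe_id.

    ``metrics`` needs columns probe_id, indel_id and any of call_rate,
    concordance, score (missing columns rank equal).
    """
    df = metrics.copy()
    for col in ("call_rate", "concordance", "score"):
        if col not in df:
            df[col] = 0.0
    df = df.sort_values(
        by=["indel_id", "call_rate", "concordance", "score", "probe_id"],
        ascending=[True, False, False, False, True],
        kind="mergesort",
    )
    return df.groupby("indel_id", as_index=False).head(1).reset_index(drop=True)


@dataclass
class KinshipMatrix:
    values: np.ndarray
    samples: Sequence[str]
    n_markers: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.samples), columns=list(self.samples))


def ibd_kinship(
    dosages: pd.DataFrame,
    allele_freqs: Optional[np.ndarray] = None,
) -> KinshipMatrix:
    """Genomic kinship over presence dosages (marker x sample, NaN missing).

    Allele frequencies default to per-marker means over non-missing samples;
    markers with frequency 0 or 1 are skipped.  Each pair is averaged over
    markers non-missing in both samples.
    """
    X = dosages.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(X, axis=1) if allele_freqs is None else np.asarray(allele_freqs, float)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    X, p = X[usable], p[usable]
    denom = p * (1 - p)
    Z = (X - p[:, None]) / np.sqrt(denom)[:, None]
    obs = np.isfinite(Z)
    Zf = np.where(obs, Z, 0.0)
    num = Zf.T @ Zf
    cnt = obs.astype(float).T @ obs.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = num / cnt
    K = (K + K.T) / 2.0
    return KinshipMatrix(values=K, samples=list(dosages.columns), n_markers=int(usable.sum()))


def kinship_distance(K: KinshipMatrix, normalize: bool = True) -> np.ndarray:
    """1 - IBD dissimilarity, optionally rescaled to [0, 1], zero diagonal."""
    D = 1.0 - K.values
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    if normalize and D.max() > 0:
        D = D / D.max()
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def pcoa(distance: np.ndarray, n_axes: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Classical metric MDS (principal coordinate analysis).

    Double-centres -D^2/2, eigendecomposes, and returns coordinates for axes
    with positive eigenvalues only (a warning is emitted when negative
    eigenvalues indicate a non-Euclidean input), ordered by eigenvalue.

    Returns (coordinates (n x n_axes), eigenvalues (n_axes,)).
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if (eigvals < -1e-8 * max(1.0, abs(eigvals[0]))).any():
        warnings.warn("negative eigenvalues: distances are not Euclidean; "
                      "only positive axes returned", stacklevel=2)
    pos = eigvals > 1e-10 * max(1.0, abs(eigvals[0]) if len(eigvals) else 1.0)
    eigvals, eigvecs = eigvals[pos], eigvecs[:, pos]
    coords = eigvecs * np.sqrt(eigvals)
    if n_axes is not None:
        coords, eigvals = coords[:, :n_axes], eigvals[:n_axes]
    return coords, eigvals
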