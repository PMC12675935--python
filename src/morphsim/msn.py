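"""Morphometric similarity networks (MSNs).

An MSN is a per-subject weighted graph: nodes are cortical parcels, edge
weights are Pearson correlations between the parcels' z-scored
morphometric feature vectors.  Regional strength — the mean signed edge
weight between one parcel and all others — is the node-level statistic
carried into group contrasts.  Strength is computed on the full-density
matrix by default; density thresholding is available but off by default
(no operative density is canonical, and the edge-sign taxonomy needs
signed weights, so weights are never absolute-valued).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, DegenerateInputError
from .synthetic import SubjectFeatures


@dataclass
class SimilarityMatrix:
    """Symmetric regions x regions edge-weight matrix for one subject.

    The diagonal is structurally zero and excluded from all statistics;
    ``density`` is the fraction of off-diagonal edges retained (1.0 for an
    unthresholded matrix)."""

    subject_id: str
    weights: np.ndarray
    region_ids: np.ndarray
    density: float = 1.0

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ArgumentError(f"weights must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=0.0):
            raise ArgumentError("weights must be exactly symmetric")
        off = w[~np.eye(len(w), dtype=bool)]
        if len(off) and (np.nanmax(np.abs(off)) > 1.0 + 1e-12):
            raise ArgumentError("off-diagonal weights must lie in [-1, 1]")
        if not (0.0 < self.density <= 1.0):
            raise ArgumentError(f"density must be in (0, 1], got {self.density}")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class StrengthVector:
    """Per-region mean edge weight for one subject."""

    subject_id: str
    strength: np.ndarray
    region_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.strength)


def znormalize_features(table: SubjectFeatures) -> SubjectFeatures:
    """Z-score every feature column across regions (mean 0, sample SD 1, ddof=1).

    Raises
    ------
    DegenerateInputError
        If a feature column is constant across regions, naming the feature.
    """
    vals = table.values
    sd = vals.std(axis=0, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise DegenerateInputError(
            f"feature(s) with zero variance across regions for subject "
            f"{table.subject_id}: {dead}")
    out = (vals - vals.mean(axis=0)) / sd
    return SubjectFeatures(table.subject_id, out)


def build_msn(table: SubjectFeatures, normalized: bool = False) -> SimilarityMatrix:
    """Pearson-correlate every pair of regional feature vectors.

    Features are z-scored across regions first unless ``normalized`` flags
    the table as already normalized.  The result is a symmetric regions x
    regions matrix with a zero diagonal at density 1.

    Raises
    ------
    DegenerateInputError
        If any region's feature vector has zero variance (its correlation
        with every other region is undefined), naming the region.
    """
    if not normalized:
        table = znormalize_features(table)
    vals = table.values.to_numpy(float)
    row_sd = vals.std(axis=1, ddof=1)
    flat = table.values.index.to_numpy()[row_sd == 0]
    if len(flat):
        raise DegenerateInputError(
            f"region(s) with zero variance across features for subject "
            f"{table.subject_id}: {flat[:5].tolist()}")
    w = np.corrcoef(vals)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry and bounds
    np.fill_diagonal(w, 0.0)
    return SimilarityMatrix(table.subject_id, w, table.values.index.to_numpy(), density=1.0)


def threshold_density(msn: SimilarityMatrix, density: float) -> SimilarityMatrix:
    """Keep the top ``ceil(density * E)`` off-diagonal edges by absolute
    weight (E = number of unordered region pairs), zeroing the rest.

    Ties in |weight| are broken toward the lexicographically smaller (i, j)
    pair so the output is deterministic.  density=1 returns the input
    unchanged.
    """
    if not (0.0 < density <= 1.0):
        raise ArgumentError(f"density must be in (0, 1], got {density}")
    if density == 1.0:
        return msn
    n = msn.n_regions
    iu, ju = np.triu_indices(n, k=1)
    wts = msn.weights[iu, ju]
    n_keep = math.ceil(density * len(wts))
    order = np.lexsort((ju, iu, -np.abs(wts)))  # |w| desc, then (i, j) asc
    keep = order[:n_keep]
    out = np.zeros_like(msn.weights)
    out[iu[keep], ju[keep]] = wts[keep]
    out += out.T
    return SimilarityMatrix(msn.subject_id, out, msn.region_ids, density=density)


def regional_strength(msn: SimilarityMatrix) -> StrengthVector:
    """Mean edge weight between each region and all others (zeroed edges of a
    thresholded matrix count as 0 in the mean)."""
    n = msn.n_regions
    if n < 2:
        raise ArgumentError("need at least 2 regions for strength")
    s = msn.weights.sum(axis=1) / (n - 1)  # diagonal is structurally zero
    return StrengthVector(msn.subject_id, s, msn.region_ids)


def global_strength(sv: StrengthVector) -> float:
    """Arithmetic mean of the regional strengths."""
    if len(sv) == 0:
        raise ArgumentError("empty strength vector")
    return float(np.mean(sv.strength))


def strength_matrix(strengths: list) -> pd.DataFrame:
    """Stack per-subject StrengthVectors into a subjects x regions DataFrame."""
    if not strengths:
        raise ArgumentError("no strength vectors given")
    ref = strengths[0].region_ids
    for sv in strengths:
        if not np.array_equal(sv.region_ids, ref):
            raise ArgumentError(f"region ids differ for subject {sv.subject_id}")
    return pd.DataFrame(
        np.vstack([sv.strength for sv in strengths]),
        index=pd.Index([sv.subject_id for sv in strengths], name="subject_id"),
        columns=ref,
    )
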