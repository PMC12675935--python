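"""Cortical parcellation tables with spherical centroids.

A parcellation assigns every cortical region an id, a hemisphere label
(L/R) and a centroid on that hemisphere's unit sphere (the inflated
spherical projection used for spin permutations).  The default scale in
this line of work is a 308-parcel subdivision of the Desikan-Killiany
atlas with 152 left-hemisphere parcels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, ValidationError

_COLUMNS = ["region_id", "region_name", "hemisphere", "x", "y", "z"]


@dataclass(frozen=True)
class Parcellation:
    """Region table: region_id, region_name, hemisphere in {L, R}, unit centroid (x, y, z).

    Region ids must be unique and contiguous from 0; every centroid must
    have Euclidean norm 1 within 1e-9.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.table
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"parcellation table missing columns: {missing}")
        ids = t["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids) or not np.array_equal(np.sort(ids), np.arange(len(ids))):
            raise ValidationError("region_ids must be unique and contiguous from 0")
        bad_hemi = set(t["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        norms = np.linalg.norm(t[["x", "y", "z"]].to_numpy(), axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            off = t["region_id"].to_numpy()[np.abs(norms - 1.0) > 1e-9]
            raise ValidationError(f"centroids not on the unit sphere for regions {off[:5].tolist()}")
        object.__setattr__(self, "table", t.sort_values("region_id").reset_index(drop=True))

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        """(n_regions, 3) array of unit centroids, ordered by region_id."""
        return self.table[["x", "y", "z"]].to_numpy(float)

    def ids_of(self, hemisphere: str) -> np.ndarray:
        return self.table.loc[self.table["hemisphere"] == hemisphere, "region_id"].to_numpy()

    @property
    def left_ids(self) -> np.ndarray:
        return self.ids_of("L")

    @property
    def right_ids(self) -> np.ndarray:
        return self.ids_of("R")

    def mirrored_centroids(self) -> np.ndarray:
        """Centroids with the right hemisphere reflected through the sagittal
        plane (x -> -x) so both hemispheres share one sphere.  Used for
        cross-hemisphere distance kernels (homotopic regions come out close)."""
        c = self.centroids.copy()
        c[self.hemispheres == "R", 0] *= -1.0
        return c


def great_circle_distances(points: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (radians) between unit vectors."""
    g = np.clip(points @ points.T, -1.0, 1.0)
    return np.arccos(g)


def make_parcellation(n_left: int, n_right: int, seed: int) -> Parcellation:
    """Sample a synthetic parcellation with centroids uniform on each
    hemisphere's unit sphere.

    Parameters
    ----------
    n_left, n_right
        Number of parcels per hemisphere; each must be >= 4.
    seed
        Seed for the random centroid draw; output is deterministic given it.
    """
    if n_left < 4 or n_right < 4:
        raise ArgumentError(f"need at least 4 regions per hemisphere, got L={n_left}, R={n_right}")
    rng = np.random.default_rng(seed)
    rows = []
    rid = 0
    for hemi, n in (("L", n_left), ("R", n_right)):
        pts = rng.standard_normal((n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        for k in range(n):
            rows.append((rid, f"{hemi.lower()}h_parcel_{k:03d}", hemi, *pts[k]))
            rid += 1
    table = pd.DataFrame(rows, columns=_COLUMNS)
    return Parcellation(table)
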