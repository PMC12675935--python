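"""Synthetic cohorts and expression matrices with known ground truth.

The study design being emulated is an observational case-control MRI
study: healthy controls (HC) plus two stroke stages (AIS = acute/subacute,
CIS = chronic ischemic stroke), each subject contributing a regions x
morphometric-features table, plus a left-hemisphere regions x genes
expression matrix standing in for a donor-atlas transcriptome.  No
generative model exists for such data in the literature this emulates;
everything here is an explicit artifact choice so that downstream
estimators can be tested for calibration and recovery against a known
truth.

Generative model
----------------
feature[s, r, f] = baseline[r, f] * (1 - effect_size * severity[s] * w[f]
                                     * 1{r in affected[group(s)]})
                   + offset[s] + N(0, noise_sd)

baseline[r, f] = sqrt(global_weight) * g[f]
                 + sqrt(1 - global_weight) * local[r, f]

* g: one shared cortical profile per feature (regions co-vary strongly in
  real morphometrics, which is what makes MSN edges predominantly
  positive); local[., f]: a spatially smooth Gaussian field per feature
  (covariance exp(-d / spatial_corr_length), d = great-circle distance on
  the mirrored common sphere), so similarity has spatial structure under
  the null.
* the group effect is a partial inversion of the affected region's
  baseline profile (factor 1 - effect_size * severity, about -0.5 at the
  default effect size): the region's morphometric signature rotates away
  from, then against, its healthy pattern, which is the "decoupling"
  phenomenon the edge taxonomy describes.  A constant additive shift
  applied identically to every feature would be cancelled by the
  row-centering inside the inter-regional Pearson correlation and leave
  the MSN untouched, so a multiplicative profile effect is the minimal
  mechanism that moves similarity at all.
* offset[s]: scalar subject effect (absorbed by per-feature z-scoring, as
  a global shift would be in real data).
* severity[s] = exp(sigma * u_s - sigma^2 / 2), mean 1: subject-level
  modulation of the planted group effect; clinical scores are monotone
  binnings of a latent correlated with u_s, preserving their ordinal
  nature for rank-based tests.

Expression: planted genes = slope * standardized(effect_map) + smooth
field; all other genes are field only, same covariance kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError
from .parcellation import Parcellation, great_circle_distances

DEFAULT_FEATURES = (
    "thickness",
    "fractal_dim",
    "gyrification",
    "curvature",
    "sulcal_depth",
    "surface",
)

GROUPS = ("HC", "AIS", "CIS")


@dataclass
class SubjectFeatures:
    """One subject's regions x morphometric-features table."""

    subject_id: str
    values: pd.DataFrame  # index = region_id, columns = feature names

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic study; everything recovery tests check against.

    affected_regions maps each patient group to the region ids carrying the
    planted effect; effect_size is the standardized mean shift added to every
    feature of an affected region; planted_genes are expression columns
    coupled to the effect map with slope planted_gene_slope.
    spatial_corr_length is the great-circle e-folding scale (radians) of the
    smooth fields.
    """

    affected_regions: dict = field(default_factory=dict)  # group -> set of region ids
    effect_size: float = 1.5
    planted_genes: frozenset = frozenset()
    planted_gene_slope: float = 2.0
    noise_sd: float = 0.5
    spatial_corr_length: float = 1.0

    def to_json(self, path) -> None:
        d = asdict(self)
        d["affected_regions"] = {g: sorted(int(r) for r in v) for g, v in self.affected_regions.items()}
        d["planted_genes"] = sorted(self.planted_genes)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["affected_regions"] = {g: set(v) for g, v in d["affected_regions"].items()}
        d["planted_genes"] = frozenset(d["planted_genes"])
        return cls(**d)


def _smooth_fields(points: np.ndarray, n_fields: int, length: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n_fields zero-mean unit-variance Gaussian fields with covariance
    exp(-d/length) over the given unit-sphere points.  Returns (n_points, n_fields)."""
    d = great_circle_distances(points)
    cov = np.exp(-d / length)
    cov[np.diag_indices_from(cov)] += 1e-8  # Cholesky jitter
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((len(points), n_fields))


def _ordinal_scores(latent: np.ndarray, rank_corr: float, scale: float, max_val: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Monotone binning of a latent severity into a non-negative ordinal score.

    A Gaussian copula couples the score's latent to the input latent so the
    population Spearman correlation is approximately rank_corr; the binning
    (floor of a scaled exponential quantile transform) is monotone, so ranks
    survive up to ties.
    """
    rho_p = 2.0 * np.sin(np.pi * rank_corr / 6.0)  # Spearman -> Pearson on normals
    z = rho_p * latent + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(len(latent))
    u = stats.norm.cdf(z)
    return np.minimum(np.floor(-np.log1p(-u) * scale), max_val).astype(int)


def simulate_cohort(
    parcellation: Parcellation,
    n_per_group,
    truth: SyntheticTruth,
    n_features: int = 6,
    seed: int = 0,
    *,
    age_range: tuple = (40.0, 70.0),
    clinical_rank_corr: float = 0.4,
    subject_sd: float = 0.2,
    severity_sigma: float = 0.1,
    global_weight: float = 0.9,
    feature_weights=None,
):
    """Simulate a three-group cohort and its per-subject feature tables.

    Parameters
    ----------
    n_per_group
        (n_HC, n_AIS, n_CIS), each >= 3.
    truth
        Planted effect description; ``truth.affected_regions`` may name any
        subset of the parcellation's regions per patient group.
    n_features
        Number of morphometric features per region (>= 2); the canonical
        surface-derived set has six.

    Returns
    -------
    design : pandas.DataFrame
        Columns subject_id, group, age, sex, nihss, mrs (clinical scores are
        NaN for HC).
    features : list of SubjectFeatures
        One table per subject, aligned with design rows.
    """
    n_per_group = tuple(int(n) for n in n_per_group)
    if len(n_per_group) != len(GROUPS):
        raise ArgumentError(f"n_per_group must give counts for {GROUPS}")
    if any(n < 3 for n in n_per_group):
        raise ArgumentError(f"need >= 3 subjects per group, got {n_per_group}")
    if n_features < 2:
        raise ArgumentError(f"need >= 2 features, got {n_features}")
    region_set = set(parcellation.region_ids.tolist())
    for g, regs in truth.affected_regions.items():
        extra = set(regs) - region_set
        if extra:
            raise ArgumentError(f"affected regions for {g} outside parcellation: {sorted(extra)[:5]}")

    rng = np.random.default_rng(seed)
    n_regions = parcellation.n_regions
    if n_features == len(DEFAULT_FEATURES):
        feat_names = list(DEFAULT_FEATURES)
    else:
        feat_names = [f"feat_{k}" for k in range(n_features)]
    if feature_weights is None:
        w = np.ones(n_features)
    else:
        w = np.asarray(feature_weights, float)
    if w.shape != (n_features,):
        raise ArgumentError("feature_weights must have one entry per feature")
    if not (0.0 <= global_weight < 1.0):
        raise ArgumentError(f"global_weight must be in [0, 1), got {global_weight}")

    shared = rng.standard_normal(n_features)
    shared *= np.sqrt(n_features) / np.linalg.norm(shared)  # fixed profile energy
    local = _smooth_fields(parcellation.mirrored_centroids(), n_features,
                           truth.spatial_corr_length, rng)
    baseline = np.sqrt(global_weight) * shared[None, :] + np.sqrt(1.0 - global_weight) * local

    design_rows = []
    features = []
    sid = 0
    for group, n in zip(GROUPS, n_per_group):
        affected = np.isin(parcellation.region_ids, sorted(truth.affected_regions.get(group, ())))
        ages = rng.uniform(*age_range, size=n)
        sexes = np.array(["M", "F"])[rng.permutation(np.arange(n) % 2)]
        u = rng.standard_normal(n)  # latent severity
        severity = np.exp(severity_sigma * u - severity_sigma**2 / 2.0)
        if group == "HC":
            nihss = np.full(n, np.nan)
            mrs = np.full(n, np.nan)
        else:
            nihss = _ordinal_scores(u, clinical_rank_corr, scale=3.0, max_val=20, rng=rng).astype(float)
            mrs = _ordinal_scores(u, clinical_rank_corr, scale=2.0, max_val=6, rng=rng).astype(float)
        offsets = rng.normal(0.0, subject_sd, size=n)
        for k in range(n):
            vals = baseline + offsets[k]
            if affected.any() and group != "HC":
                # partial profile inversion at the affected regions
                vals = vals - truth.effect_size * severity[k] * (affected[:, None] * baseline * w)
            vals = vals + rng.normal(0.0, truth.noise_sd, size=(n_regions, n_features))
            subject_id = f"sub-{sid:04d}"
            design_rows.append((subject_id, group, ages[k], sexes[k], nihss[k], mrs[k]))
            features.append(SubjectFeatures(
                subject_id,
                pd.DataFrame(vals, index=parcellation.region_ids.copy(), columns=feat_names),
            ))
            sid += 1
    design = pd.DataFrame(design_rows, columns=["subject_id", "group", "age", "sex", "nihss", "mrs"])
    return design, features


def simulate_expression(
    parcellation: Parcellation,
    effect_map,
    truth: SyntheticTruth,
    n_genes: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a left-hemisphere regions x genes expression matrix.

    effect_map is a per-region scalar over the parcellation's left-hemisphere
    regions (pandas Series indexed by region id, or array in left-id order).
    Genes named in truth.planted_genes track the standardized effect map with
    slope truth.planted_gene_slope on top of a unit-variance spatially
    autocorrelated field; all other genes are field only.
    """
    left = parcellation.left_ids
    if isinstance(effect_map, pd.Series):
        try:
            em = effect_map.loc[left].to_numpy(float)
        except KeyError as exc:
            raise ArgumentError(f"effect_map missing left-hemisphere regions: {exc}") from exc
    else:
        em = np.asarray(effect_map, float)
        if em.shape != (len(left),):
            raise ArgumentError(
                f"effect_map length {em.shape} does not match {len(left)} left regions")
    if em.std(ddof=1) == 0:
        raise ArgumentError("effect_map is constant; cannot standardize")

    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    planted = sorted(truth.planted_genes)
    if n_genes < len(planted):
        raise ArgumentError(f"n_genes={n_genes} < {len(planted)} planted genes")
    unknown = set(planted) - set(gene_ids)
    if unknown:
        raise ArgumentError(f"planted genes outside the generated gene ids: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    pts = parcellation.centroids[np.isin(parcellation.region_ids, left)]
    values = _smooth_fields(pts, n_genes, truth.spatial_corr_length, rng)
    z_em = (em - em.mean()) / em.std(ddof=1)
    idx = [gene_ids.index(g) for g in planted]
    values[:, idx] += truth.planted_gene_slope * z_em[:, None]
    return pd.DataFrame(values, index=pd.Index(left, name="region_id"), columns=gene_ids)


def default_truth(
    parcellation: Parcellation,
    n_affected: int = 10,
    n_planted_genes: int = 20,
    overlap: float = 0.5,
    seed: int = 0,
    **kwargs,
) -> SyntheticTruth:
    """Convenience constructor: draw affected-region sets for AIS and CIS
    (each half left-hemisphere so transcriptomic coupling is exercised,
    sharing a fraction ``overlap`` of regions between stages) and name the
    first n_planted_genes gene ids as planted."""
    rng = np.random.default_rng(seed)
    left, right = parcellation.left_ids, parcellation.right_ids
    n_l = (n_affected + 1) // 2
    n_r = n_affected - n_l

    def draw(exclude=frozenset()):
        pool_l = np.setdiff1d(left, list(exclude))
        pool_r = np.setdiff1d(right, list(exclude))
        return set(rng.choice(pool_l, n_l, replace=False)) | set(rng.choice(pool_r, n_r, replace=False))

    ais = draw()
    n_shared = int(round(overlap * n_affected))
    shared = set(rng.choice(sorted(ais), n_shared, replace=False)) if n_shared else set()
    fresh = draw(exclude=ais)
    cis = shared | set(sorted(fresh)[: n_affected - n_shared])
    return SyntheticTruth(
        affected_regions={"AIS": ais, "CIS": cis},
        planted_genes=frozenset(f"G{i:04d}" for i in range(n_planted_genes)),
        **kwargs,
    )
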