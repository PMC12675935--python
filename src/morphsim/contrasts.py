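"""Case-control regional contrasts, FDR, edge taxonomy and clinical correlations.

The regional model is an ordinary least-squares fit per cortical region:

    strength_i = b0 + b1*age + b2*sex + b3*(age*sex) + b4*group

with sex coded M=0/F=1, the group dummy control=0/case=1, and contrasts
run as separate two-group models (AIS vs HC, CIS vs HC).  b4 is the group
effect; its two-sided t (df = n - 5) is the regional statistic, corrected
across regions with Benjamini-Hochberg FDR.  Edges are classified into a
four-quadrant taxonomy of how mean connection weights change from
controls to patients, and regional strength relates to clinical severity
through Spearman correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError, DegenerateInputError
from .msn import SimilarityMatrix
from .spin import spin_test

logger = logging.getLogger("morphsim.contrasts")

QUADRANTS = ("decoupling", "dedifferentiation", "hypercoupling", "hyperdedifferentiation")


@dataclass
class EdgeQuadrantSummary:
    """Counts and proportions of edge-change classes between group means.

    decoupling: HC-positive edge turns negative in patients;
    dedifferentiation: HC-negative turns positive; hypercoupling: positive
    in both, stronger in patients; hyperdedifferentiation: negative in
    both, more negative in patients.  Edges matching none of the four
    patterns are unclassified and excluded from proportions.
    """

    counts: dict
    proportions: dict
    n_classified: int
    n_unclassified: int
    edge_mask: np.ndarray


def bh_fdr(p, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted q-values and the q < alpha mask.

    q-values are monotone (cumulative minimum from the largest rank).
    """
    p = np.asarray(p, float)
    if p.ndim != 1 or len(p) == 0:
        raise ArgumentError("p must be a non-empty 1-D vector")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ArgumentError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def _design_matrix(design: pd.DataFrame, case: str, control: str):
    sub = design[design["group"].isin([case, control])]
    if (sub["group"] == case).sum() == 0 or (sub["group"] == control).sum() == 0:
        raise ArgumentError(f"both groups must be present ({case}, {control})")
    age = sub["age"].to_numpy(float)
    sex = (sub["sex"].to_numpy() == "F").astype(float)
    grp = (sub["group"].to_numpy() == case).astype(float)
    X = np.column_stack([np.ones(len(sub)), age, sex, age * sex, grp])
    names = ["intercept", "age", "sex", "age_x_sex", "group"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.max(np.abs(resid)) < 1e-8 * max(1.0, np.max(np.abs(X[:, j]))):
                bad.append(names[j])
        raise ArgumentError(
            f"rank-deficient design (e.g. single-sex subsample); collinear columns: {bad}")
    return sub.index, X


def fit_regional_lrm(
    strengths: pd.DataFrame,
    design: pd.DataFrame,
    case: str,
    control: str = "HC",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region OLS of strength on [1, age, sex, age*sex, group dummy].

    Parameters
    ----------
    strengths : DataFrame
        Subjects x regions regional-strength matrix, indexed by subject_id.
    design : DataFrame
        Cohort table with subject_id, group, age, sex columns.
    case, control : str
        Group labels; the dummy codes control=0, case=1.

    Returns
    -------
    DataFrame indexed by region id with columns beta4, t, p, q, significant.
    """
    design = design.set_index("subject_id") if "subject_id" in design.columns else design
    missing = set(design.index) - set(strengths.index)
    if missing & set(design.index[design["group"].isin([case, control])]):
        raise ArgumentError(f"strengths missing for subjects: {sorted(missing)[:5]}")
    rows, X = _design_matrix(design, case, control)
    Y = strengths.loc[rows].to_numpy(float)
    n, k = X.shape
    if n < k + 1:
        raise ArgumentError(f"need n >= {k + 1} subjects across both groups, got {n}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se4 = np.sqrt(xtx_inv[4, 4] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[4] / se4
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q, sig = bh_fdr(p, alpha)
    return pd.DataFrame(
        {"beta4": beta[4], "t": t, "p": p, "q": q, "significant": sig},
        index=pd.Index(strengths.columns, name="region_id"),
    )


def altered_edge_mask(hc_msns: list, case_msns: list, alpha: float = 0.05) -> np.ndarray:
    """Default "altered connections" mask: edges whose weights differ between
    groups by an uncorrected two-sample edge-wise t-test at level alpha."""
    hc = np.stack([m.weights for m in hc_msns])
    cs = np.stack([m.weights for m in case_msns])
    _, p = stats.ttest_ind(hc, cs, axis=0)
    mask = p < alpha
    np.fill_diagonal(mask, False)
    return mask & mask.T


def classify_edges(
    hc_mean: SimilarityMatrix, case_mean: SimilarityMatrix, edge_mask: np.ndarray
) -> EdgeQuadrantSummary:
    """Classify masked edges by how their mean weight changes from HC to case.

    For an edge with HC weight h and case weight c: decoupling if h > 0 > c;
    dedifferentiation if h < 0 < c; hypercoupling if 0 < h < c;
    hyperdedifferentiation if c < h < 0.  All other sign patterns (including
    weakened same-sign edges and zeros) are counted as unclassified and
    excluded from the proportions.
    """
    if hc_mean.weights.shape != case_mean.weights.shape:
        raise ArgumentError("matrices must share a parcellation")
    mask = np.asarray(edge_mask, bool)
    if mask.shape != hc_mean.weights.shape:
        raise ArgumentError("edge_mask shape must match the matrices")
    if not np.array_equal(mask, mask.T):
        raise ArgumentError("edge_mask must be symmetric")
    iu, ju = np.triu_indices(mask.shape[0], k=1)
    sel = mask[iu, ju]
    h = hc_mean.weights[iu, ju][sel]
    c = case_mean.weights[iu, ju][sel]
    counts = {
        "decoupling": int(np.sum((h > 0) & (c < 0))),
        "dedifferentiation": int(np.sum((h < 0) & (c > 0))),
        "hypercoupling": int(np.sum((h > 0) & (c > 0) & (c > h))),
        "hyperdedifferentiation": int(np.sum((h < 0) & (c < 0) & (c < h))),
    }
    n_classified = sum(counts.values())
    proportions = {
        k: (v / n_classified if n_classified else float("nan")) for k, v in counts.items()
    }
    return EdgeQuadrantSummary(
        counts=counts,
        proportions=proportions,
        n_classified=n_classified,
        n_unclassified=int(len(h) - n_classified),
        edge_mask=mask,
    )


def strength_vs_contrast(
    hc_mean_strength,
    contrast: pd.DataFrame,
    parcellation,
    n_spins: int = 1000,
    seed: int = 0,
    method: str = "spearman",
):
    """Correlation between mean HC regional strength and the contrast t-map,
    with a spin-permutation p.  Returns (rho, p_spin, SpinNullDistribution)."""
    s = np.asarray(hc_mean_strength, float)
    t = contrast["t"].to_numpy(float)
    if s.shape != t.shape:
        raise ArgumentError(f"length mismatch: {s.shape} strengths vs {t.shape} t-values")
    return spin_test(s, t, parcellation, n_spins=n_spins, method=method, seed=seed)


def clinical_correlations(
    strengths: pd.DataFrame,
    design: pd.DataFrame,
    score: str,
    scope: str,
    group: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of MSN strength with an ordinal clinical score.

    scope="global" correlates the subject-mean strength with the score (one
    row); scope="regional" correlates each region's strength with the score
    and BH-corrects across regions.  Patients only: subjects of ``group``
    with a non-missing score.
    """
    if score not in ("nihss", "mrs"):
        raise ArgumentError(f"score must be 'nihss' or 'mrs', got {score!r}")
    if scope not in ("global", "regional"):
        raise ArgumentError(f"scope must be 'global' or 'regional', got {scope!r}")
    d = design.set_index("subject_id") if "subject_id" in design.columns else design
    sub = d[(d["group"] == group) & d[score].notna()]
    if len(sub) < 4:
        raise DegenerateInputError(
            f"need >= 4 complete observations for {group}/{score}, got {len(sub)}")
    sc = sub[score].to_numpy(float)
    if np.all(sc == sc[0]):
        raise DegenerateInputError(f"{score} is constant in group {group}")
    S = strengths.loc[sub.index]
    if scope == "global":
        rho, p = stats.spearmanr(S.mean(axis=1).to_numpy(), sc)
        return pd.DataFrame(
            {"scope": ["global"], "score": [score], "group": [group],
             "unit": ["global"], "rho": [rho], "p": [p], "q": [p]})
    rows = []
    for region in S.columns:
        rho, p = stats.spearmanr(S[region].to_numpy(), sc)
        rows.append((region, rho, p))
    out = pd.DataFrame(rows, columns=["unit", "rho", "p"])
    out.insert(0, "scope", "regional")
    out.insert(1, "score", score)
    out.insert(2, "group", group)
    out["q"], _ = bh_fdr(out["p"].to_numpy(), alpha)
    return out
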