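"""PLS imaging transcriptomics: linking a regional contrast map to gene expression.

Partial least squares regression takes the regions x genes expression
matrix (columns standardized) as predictors and the regional case-control
t-map (centred) as the univariate response.  The first component, PLS1,
is the expression gradient most covariant with the contrast.  Component
count is screened by permuting the response (1-15 components, incremental
variance explained vs the permuted null); gene-level inference bootstraps
regions, refits PLS1 per replicate with sign alignment to the original
component, and summarizes each gene by Z = mean weight / bootstrap SD.
Genes with Z > +z_thresh (below -z_thresh) passing BH-FDR are called
PLS1+ (PLS1-).  Downstream utilities cover stage overlap, per-gene
spatial correlation with spin p-values, and hypergeometric
over-representation of called genes in user-supplied gene sets.

The PLS1 recursion implemented here is the textbook NIPALS variant with
predictor deflation; for a univariate response each component's weight
vector is the (normalized) covariance of the deflated predictors with the
response, and the scores are mutually orthogonal, so per-component
explained variance in the response is (t_k'y)^2 / (t_k't_k) / (y'y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, DegenerateInputError
from .contrasts import bh_fdr
from .spin import spin_permutations

logger = logging.getLogger("morphsim.transcriptomics")


@dataclass
class PlsFit:
    n_components: int
    gene_ids: list
    gene_weights: np.ndarray        # genes x components
    region_scores: np.ndarray       # regions x components
    explained_variance: np.ndarray  # incremental fraction of response variance
    component_p: np.ndarray | None = None
    cumulative_null: np.ndarray | None = field(default=None, repr=False)

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance)


def _standardize_predictors(X: np.ndarray, gene_ids) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if len(dead):
        names = [gene_ids[i] for i in dead[:5]]
        raise DegenerateInputError(f"constant gene column(s): {names}")
    return (X - X.mean(axis=0)) / sd


def _pls1_recursion(X: np.ndarray, y: np.ndarray, n_components: int):
    """PLS1 with predictor deflation on pre-standardized X and centred y.

    Returns (W genes x K, T regions x K, ev length K)."""
    n, p = X.shape
    Xd = X.copy()
    ssy = float(y @ y)
    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    ev = np.empty(n_components)
    for k in range(n_components):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            raise DegenerateInputError("predictors orthogonal to the response; no component")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        load = Xd.T @ t / tt
        ev[k] = (float(t @ y) ** 2 / tt) / ssy
        Xd -= np.outer(t, load)
        W[:, k] = w
        T[:, k] = t
    return W, T, ev


def _check_alignment(expr: pd.DataFrame, response) -> np.ndarray:
    if isinstance(response, pd.Series):
        missing = set(expr.index) - set(response.index)
        if missing:
            raise ArgumentError(f"response missing regions: {sorted(missing)[:5]}")
        return response.loc[expr.index].to_numpy(float)
    y = np.asarray(response, float)
    if y.shape != (len(expr),):
        raise ArgumentError(
            f"response length {y.shape} does not match {len(expr)} expression regions")
    return y


def fit_pls(expr: pd.DataFrame, response, n_components: int = 2) -> PlsFit:
    """Fit PLS with the contrast map as response and expression as predictors.

    expr is a regions x genes DataFrame; response a per-region scalar aligned
    with its index.  Predictors are column-standardized, the response
    centred.  n_components is truncated (with a warning) to the rank bound
    min(regions - 1, genes).
    """
    y = _check_alignment(expr, response)
    n, p = expr.shape
    bound = min(n - 1, p)
    if n_components < 1:
        raise ArgumentError(f"n_components must be >= 1, got {n_components}")
    if n_components > bound:
        logger.warning("n_components=%d exceeds rank bound %d; truncating", n_components, bound)
        n_components = bound
    if y.std(ddof=1) == 0:
        raise DegenerateInputError("constant response map")
    X = _standardize_predictors(expr.to_numpy(float), list(expr.columns))
    yc = y - y.mean()
    W, T, ev = _pls1_recursion(X, yc, n_components)
    return PlsFit(n_components, list(expr.columns), W, T, ev)


def select_components(
    expr: pd.DataFrame,
    response,
    max_components: int = 15,
    n_perm: int = 1000,
    seed: int = 0,
) -> PlsFit:
    """Permutation screen of component count.

    For each k the observed incremental variance explained is compared with
    its distribution when the response is randomly permuted across regions;
    component_p[k] = (1 + #{null >= observed}) / (n_perm + 1).  Cumulative
    null variance is retained alongside (both readings of "variance
    explained by each component" are reported).
    """
    fit = fit_pls(expr, response, max_components)
    K = fit.n_components
    y = _check_alignment(expr, response)
    X = _standardize_predictors(expr.to_numpy(float), list(expr.columns))
    rng = np.random.default_rng(seed)
    null_ev = np.empty((n_perm, K))
    for b in range(n_perm):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        _, _, ev = _pls1_recursion(X, yc, K)
        null_ev[b] = ev
    obs = fit.explained_variance
    fit.component_p = (1.0 + (null_ev >= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    fit.cumulative_null = np.cumsum(null_ev, axis=1)
    return fit


def bootstrap_gene_weights(
    expr: pd.DataFrame,
    response,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap the PLS1 gene weights by resampling regions with replacement.

    Each replicate refits the first component on the resampled rows; the
    replicate weight vector is sign-flipped when its correlation with the
    original component-1 weights is negative (PLS sign indeterminacy).
    Replicates with a constant resampled response or a constant resampled
    gene column are discarded and logged.

    Returns a genes-indexed DataFrame with mean_weight, boot_sd, z
    (= mean/SD), two-sided normal p, and BH q.
    """
    if n_boot < 100:
        raise ArgumentError(f"n_boot must be >= 100, got {n_boot}")
    y = _check_alignment(expr, response)
    X_raw = expr.to_numpy(float)
    n, p = X_raw.shape
    w0 = fit_pls(expr, response, 1).gene_weights[:, 0]
    rng = np.random.default_rng(seed)
    weights = np.empty((n_boot, p))
    kept = 0
    discarded = 0
    while kept < n_boot:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        Xb = X_raw[idx]
        sd = Xb.std(axis=0, ddof=1)
        if yb.std(ddof=1) == 0 or np.any(sd == 0):
            discarded += 1
            if discarded > 50 * n_boot:
                raise DegenerateInputError("all bootstrap replicates degenerate")
            continue
        Xs = (Xb - Xb.mean(axis=0)) / sd
        yc = yb - yb.mean()
        w = Xs.T @ yc
        w /= np.linalg.norm(w)
        if np.dot(w, w0) < 0:  # sign-align to the original component
            w = -w
        weights[kept] = w
        kept += 1
    if discarded:
        logger.warning("discarded %d degenerate bootstrap replicate(s)", discarded)
    mean_w = weights.mean(axis=0)
    sd_w = weights.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_w > 0, mean_w / sd_w, np.sign(mean_w) * np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    q, _ = bh_fdr(pvals)
    return pd.DataFrame(
        {"mean_weight": mean_w, "boot_sd": sd_w, "z": z, "p": pvals, "q": q},
        index=pd.Index(expr.columns, name="gene"),
    )


def classify_pls_genes(
    table: pd.DataFrame, z_thresh: float = 3.0, q_thresh: float = 0.05
) -> pd.DataFrame:
    """Call PLS1+ / PLS1- genes: |z| beyond the threshold AND q below the FDR
    gate; everything else is class 'none'.  Returns a copy with a 'class'
    column."""
    out = table.copy()
    cls = np.full(len(out), "none", dtype=object)
    pos = (out["z"] > z_thresh) & (out["q"] < q_thresh)
    neg = (out["z"] < -z_thresh) & (out["q"] < q_thresh)
    cls[pos.to_numpy()] = "PLS1+"
    cls[neg.to_numpy()] = "PLS1-"
    out["class"] = cls
    return out


def stage_overlap(set_a, set_b) -> list:
    """Exact intersection of two gene sets, sorted by gene id."""
    return sorted(set(set_a) & set(set_b))


def gene_map_correlation(
    expr: pd.DataFrame,
    response,
    genes,
    parcellation,
    n_spins: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene Spearman correlation with the contrast map plus spin p.

    Left-hemisphere spins are shared across all genes (one permutation set,
    one seed).  BH correction runs across the tested genes, on the spin p
    (column q) and on the analytic Spearman p (column q_naive) since
    either may be wanted downstream.
    """
    genes = list(genes)
    if not genes:
        raise ArgumentError("empty gene subset")
    unknown = set(genes) - set(expr.columns)
    if unknown:
        raise ArgumentError(f"genes not in the expression matrix: {sorted(unknown)[:5]}")
    y = _check_alignment(expr, response)
    if y.std() == 0:
        raise DegenerateInputError("constant response map")
    G = expr[genes].to_numpy(float)
    n = len(y)
    if n != len(parcellation.left_ids):
        raise ArgumentError("expression regions must be the parcellation's left hemisphere")
    perms = spin_permutations(parcellation, n_spins, seed, hemisphere="L")

    y_r = stats.rankdata(y)
    G_r = np.apply_along_axis(stats.rankdata, 0, G)

    def _cols_corr(A, b):
        Ac = A - A.mean(axis=0)
        bc = b - b.mean()
        return (Ac.T @ bc) / np.sqrt((Ac**2).sum(axis=0) * (bc**2).sum())

    rho = _cols_corr(G_r, y_r)
    p_naive = np.array([stats.spearmanr(G[:, j], y).pvalue for j in range(G.shape[1])])
    exceed = np.zeros(len(genes))
    for perm in perms:
        Gp = np.apply_along_axis(stats.rankdata, 0, G[perm])
        r_null = _cols_corr(Gp, y_r)
        exceed += np.abs(r_null) >= np.abs(rho)
    p_spin = (1.0 + exceed) / (n_spins + 1.0)
    q, _ = bh_fdr(p_spin)
    q_naive, _ = bh_fdr(p_naive)
    return pd.DataFrame(
        {"rho": rho, "p": p_naive, "p_spin": p_spin, "q": q, "q_naive": q_naive},
        index=pd.Index(genes, name="gene"),
    )


def hypergeometric_ora(study, background, gene_sets: dict) -> pd.DataFrame:
    """Over-representation of the study genes in each named gene set.

    p is the upper-tail hypergeometric probability of at least the observed
    overlap, drawing |study| genes from |background| of which |set ∩
    background| are in the set.  Sets with no background overlap are skipped
    (logged); BH runs across the tested sets.
    """
    study = set(study)
    background = set(background)
    stray = study - background
    if stray:
        raise ArgumentError(f"study genes not in background: {sorted(stray)[:10]}")
    M = len(background)
    N = len(study)
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & background
        if not in_bg:
            logger.warning("gene set %r has no overlap with the background; skipped", name)
            continue
        k = len(study & in_bg)
        p = float(stats.hypergeom.sf(k - 1, M, len(in_bg), N))
        rows.append((name, len(in_bg), k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    if len(out):
        out["q"], _ = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = []
    return out
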