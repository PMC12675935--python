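"""End-to-end orchestration of the five analysis stages.

Stage order: MSN construction -> strengths -> case-control contrasts ->
clinical correlations -> strength-vs-contrast spin tests (+ edge
taxonomy) -> PLS transcriptomics per contrast -> stage overlap ->
over-representation analysis.  Every stage writes its own TSV artifact;
a JSON provenance sidecar records seeds, draw counts and the config
hash.  A stage failure aborts downstream stages but leaves earlier
outputs intact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .errors import ArgumentError, PipelineStageError
from .msn import build_msn, threshold_density, regional_strength, strength_matrix, SimilarityMatrix
from .contrasts import (fit_regional_lrm, classify_edges, altered_edge_mask,
                        strength_vs_contrast, clinical_correlations)
from .parcellation import make_parcellation
from .synthetic import simulate_cohort, simulate_expression, default_truth
from .transcriptomics import (select_components, bootstrap_gene_weights, classify_pls_genes,
                              stage_overlap, gene_map_correlation, hypergeometric_ora)

logger = logging.getLogger("morphsim.pipeline")

CONTRASTS = (("AIS", "HC"), ("CIS", "HC"))


@dataclass
class RunConfig:
    """Paths and knobs for a full pipeline run.  All stochastic stages derive
    their seeds from ``seed`` via numpy SeedSequence spawning."""

    parcellation: str
    features: str
    design: str
    expression: str
    out_dir: str
    gene_sets: str | None = None
    density: float = 1.0
    alpha: float = 0.05
    z_thresh: float = 3.0
    q_thresh: float = 0.05
    n_spins: int = 10_000
    n_perm: int = 1000
    n_boot: int = 1000
    max_components: int = 15
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.density <= 1.0):
            raise ArgumentError(f"density must be in (0, 1], got {self.density}")
        if not (0.0 < self.alpha < 1.0) or not (0.0 < self.q_thresh < 1.0):
            raise ArgumentError("alpha and q_thresh must lie in (0, 1)")
        if self.z_thresh <= 0:
            raise ArgumentError("z_thresh must be positive")
        if self.n_spins < 100 or self.n_perm < 10 or self.n_boot < 100:
            raise ArgumentError("n_spins >= 100, n_perm >= 10, n_boot >= 100 required")
        if self.seed is None:
            raise ArgumentError("seed is mandatory for stochastic stages")


def simulate_inputs(
    out_dir,
    n_left: int = 30,
    n_right: int = 30,
    n_per_group=(30, 30, 30),
    n_genes: int = 300,
    n_features: int = 6,
    seed: int = 0,
    truth=None,
    n_gene_sets: int = 20,
) -> dict:
    """Write a complete synthetic input bundle (parcellation, design, feature
    tables, expression, gene sets, truth JSON) and return its paths.

    Planted expression genes track the mean of the two contrasts' true
    effect maps over the left hemisphere; the gene-set file contains one
    set concentrated on the planted genes plus random-membership sets.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_parc, s_truth, s_cohort, s_expr, s_sets = (int(c.generate_state(1)[0] % 2**31)
                                                 for c in ss.spawn(5))
    parc = make_parcellation(n_left, n_right, seed=s_parc)
    truth = truth if truth is not None else default_truth(parc, seed=s_truth)
    design, features = simulate_cohort(parc, n_per_group, truth,
                                       n_features=n_features, seed=s_cohort)
    left = parc.left_ids
    effect = np.zeros(len(left))
    for grp in ("AIS", "CIS"):
        effect += np.isin(left, sorted(truth.affected_regions.get(grp, ()))).astype(float)
    if effect.std() == 0:  # no left-hemisphere effect planted: use a smooth gradient
        effect = parc.centroids[np.isin(parc.region_ids, left)][:, 1]
    expr = simulate_expression(parc, effect, truth, n_genes=n_genes, seed=s_expr)

    rng = np.random.default_rng(s_sets)
    all_genes = list(expr.columns)
    planted = sorted(truth.planted_genes)
    sets = {}
    if planted:
        sets["planted_program"] = set(planted) | set(rng.choice(all_genes, 5, replace=False))
    max_size = max(3, min(40, n_genes // 3))
    for k in range(n_gene_sets - len(sets)):
        size = int(rng.integers(3, max_size + 1))
        sets[f"random_set_{k:02d}"] = set(rng.choice(all_genes, size, replace=False))

    h = mio.config_hash({"seed": seed, "n_left": n_left, "n_right": n_right,
                         "n_per_group": list(n_per_group), "n_genes": n_genes})
    paths = {
        "parcellation": out / "parcellation.tsv",
        "design": out / "design.tsv",
        "features": out / "features.tsv",
        "expression": out / "expression.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    mio.write_parcellation(parc, paths["parcellation"], h)
    mio.write_design(design, paths["design"], h)
    mio.write_feature_tables(features, paths["features"], h)
    mio.write_expression(expr, paths["expression"], h)
    mio.write_gmt(sets, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(name, str(exc)) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return a manifest {artifact name: path}."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    cfg_dict.pop("out_dir")  # hash identifies the analysis, not its destination
    h = mio.config_hash(cfg_dict)
    ss = np.random.SeedSequence(config.seed)
    seeds = {k: int(c.generate_state(1)[0] % 2**31)
             for k, c in zip(["spin_strength", "pls_AIS", "pls_CIS", "genemap"], ss.spawn(4))}
    manifest: dict = {}
    provenance = {"config": asdict(config), "config_hash": h, "stage_seeds": seeds}

    parc = mio.read_parcellation(config.parcellation)
    design = mio.read_design(config.design)
    features = mio.read_feature_tables(config.features, parc)
    expr = mio.read_expression(config.expression)

    @_stage("msn")
    def st_msn():
        msns = {}
        for sf in features:
            m = build_msn(sf)
            if config.density < 1.0:
                m = threshold_density(m, config.density)
            msns[sf.subject_id] = m
        return msns

    msns = st_msn()

    @_stage("strengths")
    def st_strengths():
        sm = strength_matrix([regional_strength(m) for m in msns.values()])
        mio.write_tsv(sm, out / "strengths.tsv", stage="strengths",
                      units="mean Pearson r", cfg_hash=h)
        manifest["strengths"] = str(out / "strengths.tsv")
        return sm

    strengths = st_strengths()

    @_stage("contrasts")
    def st_contrasts():
        res = {}
        for case, control in CONTRASTS:
            c = fit_regional_lrm(strengths, design, case, control, alpha=config.alpha)
            p = out / f"contrast_{case}_vs_{control}.tsv"
            mio.write_tsv(c, p, stage="contrasts", units="t-statistic", cfg_hash=h)
            manifest[f"contrast_{case}"] = str(p)
            res[case] = c
        return res

    contrasts = st_contrasts()

    @_stage("edge_taxonomy")
    def st_edges():
        groups = design.set_index("subject_id")["group"]
        rows = []
        for case, _ in CONTRASTS:
            hc_ms = [msns[s] for s in msns if groups[s] == "HC"]
            case_ms = [msns[s] for s in msns if groups[s] == case]
            mask = altered_edge_mask(hc_ms, case_ms, alpha=config.alpha)
            mean_of = lambda ms: SimilarityMatrix(
                "mean", np.mean([m.weights for m in ms], axis=0), parc.region_ids)
            summ = classify_edges(mean_of(hc_ms), mean_of(case_ms), mask)
            for quad, cnt in summ.counts.items():
                rows.append((case, quad, cnt, summ.proportions[quad],
                             summ.n_classified, summ.n_unclassified))
        df = pd.DataFrame(rows, columns=["contrast", "quadrant", "count", "proportion",
                                         "n_classified", "n_unclassified"])
        mio.write_tsv(df, out / "edge_quadrants.tsv", stage="edge_taxonomy",
                      units="edge counts/proportions", cfg_hash=h, index=False)
        manifest["edge_quadrants"] = str(out / "edge_quadrants.tsv")
        return df

    st_edges()

    @_stage("clinical")
    def st_clinical():
        frames = []
        for grp in ("AIS", "CIS"):
            for score in ("nihss", "mrs"):
                for scope in ("global", "regional"):
                    frames.append(clinical_correlations(strengths, design, score,
                                                        scope, grp, alpha=config.alpha))
        df = pd.concat(frames, ignore_index=True)
        mio.write_tsv(df, out / "clinical_correlations.tsv", stage="clinical",
                      units="Spearman rho", cfg_hash=h, index=False)
        manifest["clinical"] = str(out / "clinical_correlations.tsv")
        return df

    st_clinical()

    @_stage("spin_strength_vs_t")
    def st_spin():
        groups = design.set_index("subject_id")["group"]
        hc_subjects = [s for s in strengths.index if groups[s] == "HC"]
        hc_mean = strengths.loc[hc_subjects].mean(axis=0).to_numpy()
        rows = []
        for case, _ in CONTRASTS:
            rho, p_spin, null = strength_vs_contrast(
                hc_mean, contrasts[case], parc, n_spins=config.n_spins,
                seed=seeds["spin_strength"])
            rows.append((case, rho, p_spin, null.n_spins))
        df = pd.DataFrame(rows, columns=["contrast", "rho", "p_spin", "n_spins"])
        mio.write_tsv(df, out / "strength_vs_t.tsv", stage="spin_strength_vs_t",
                      units="Spearman rho", cfg_hash=h, index=False)
        manifest["strength_vs_t"] = str(out / "strength_vs_t.tsv")
        provenance["n_spins"] = config.n_spins
        return df

    st_spin()

    @_stage("pls")
    def st_pls():
        called = {}
        summary_rows = []
        for case, _ in CONTRASTS:
            tmap = contrasts[case]["t"]
            tmap_left = tmap.loc[expr.index]
            fit = select_components(expr, tmap_left, max_components=config.max_components,
                                    n_perm=config.n_perm, seed=seeds[f"pls_{case}"])
            gw = bootstrap_gene_weights(expr, tmap_left, n_boot=config.n_boot,
                                        seed=seeds[f"pls_{case}"] + 1)
            gw = classify_pls_genes(gw, config.z_thresh, config.q_thresh)
            p = out / f"pls_genes_{case}.tsv"
            mio.write_tsv(gw, p, stage="pls", units="PLS1 weight / bootstrap Z", cfg_hash=h)
            manifest[f"pls_genes_{case}"] = str(p)
            from .spin import spin_test
            rho, p_spin, _ = spin_test(fit.region_scores[:, 0], tmap_left.to_numpy(), parc,
                                       n_spins=config.n_spins, seed=seeds["genemap"])
            summary_rows.append((case, fit.n_components,
                                 fit.explained_variance[0], float(fit.component_p[0]),
                                 rho, p_spin,
                                 int((gw["class"] == "PLS1+").sum()),
                                 int((gw["class"] == "PLS1-").sum())))
            called[case] = set(gw.index[gw["class"] != "none"])
        df = pd.DataFrame(summary_rows, columns=["contrast", "n_components", "ev1",
                                                 "p_component1", "pls1_vs_t_rho",
                                                 "pls1_vs_t_pspin", "n_pls1_plus",
                                                 "n_pls1_minus"])
        mio.write_tsv(df, out / "pls_summary.tsv", stage="pls",
                      units="variance fraction / rho", cfg_hash=h, index=False)
        manifest["pls_summary"] = str(out / "pls_summary.tsv")
        return called

    called = st_pls()

    @_stage("overlap")
    def st_overlap():
        genes = stage_overlap(called["AIS"], called["CIS"])
        df = pd.DataFrame({"gene": genes})
        mio.write_tsv(df, out / "overlap_genes.tsv", stage="overlap",
                      units="gene ids", cfg_hash=h, index=False)
        manifest["overlap_genes"] = str(out / "overlap_genes.tsv")
        if genes:
            tmap_left = contrasts["AIS"]["t"].loc[expr.index]
            gm = gene_map_correlation(expr, tmap_left, genes, parc,
                                      n_spins=max(100, config.n_spins // 10),
                                      seed=seeds["genemap"])
            mio.write_tsv(gm, out / "overlap_gene_map_corr.tsv", stage="overlap",
                          units="Spearman rho", cfg_hash=h)
            manifest["overlap_gene_map_corr"] = str(out / "overlap_gene_map_corr.tsv")
        return genes

    overlap = st_overlap()

    @_stage("ora")
    def st_ora():
        if config.gene_sets is None:
            logger.info("no gene sets supplied; skipping over-representation")
            return None
        sets = mio.read_gmt(config.gene_sets)
        study = set(overlap) if overlap else set().union(*called.values()) if any(called.values()) else set()
        background = set(expr.columns)
        if not study:
            logger.warning("no called genes; ORA skipped")
            return None
        res = hypergeometric_ora(study, background, sets)
        mio.write_tsv(res, out / "ora.tsv", stage="ora", units="hypergeometric p", cfg_hash=h)
        manifest["ora"] = str(out / "ora.tsv")
        return res

    st_ora()

    provenance["artifacts"] = manifest
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True, default=str)
    manifest["provenance"] = str(out / "provenance.json")
    logger.info("pipeline complete: %d artifacts in %s", len(manifest), out)
    return manifest
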