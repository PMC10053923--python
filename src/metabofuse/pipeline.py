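"""End-to-end orchestration: simulate/load -> preprocess -> model -> select.

``run_pipeline`` executes the full workflow on either a synthetic study or
user-supplied delimited files, in one of three modes mirroring how such
studies are analyzed: ``nmr`` (binned J-res block only), ``ms`` (curated
LC-MS block only) or ``fused`` (block-scaled concatenation of both).  The
result bundle carries every intermediate artifact so each figure- or
table-shaped output can be regenerated from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import discriminants as disc
from . import fusion, ms, mvda, nmr
from .synthetic import Study, StudyDesign, generate_study, reference_library

_LOG = logging.getLogger("metabofuse.pipeline")

__all__ = ["RunConfig", "ResultBundle", "PipelineError", "run_pipeline", "write_report", "write_bundle"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Either ``design`` (synthetic study) or the input paths must be given.
    Defaults are the workflow's standard operating values: 0.04 ppm bins
    over 0.0-9.0 ppm, 3 ppm mass tolerance, 2 predictive components,
    7-fold Q², 100 permutations, top-15 VIPs and Q = 5% FDR.
    """

    mode: str = "fused"  # nmr | ms | fused
    design: StudyDesign | None = None
    nmr_manifest: str | None = None
    ms_features: str | None = None
    metadata: str | None = None
    library: str | None = None
    blank_ids: list[str] | None = None  # None -> samples named BLANK*
    bin_lo: float = 0.0
    bin_hi: float = 9.0
    bin_width: float = 0.04
    bin_statistic: str = "mean"
    blank_threshold: float = 0.0
    n_components: int = 2
    n_ortho: int = 1
    folds: int = 7
    n_permutations: int = 100
    k: int = 15
    Q: float = 0.05
    alpha: float = 0.05
    tol_ppm: float = 3.0
    fdr_method: str = "bh"  # bh (step-up over all variables) | paper (rank rule on VIP candidates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("nmr", "ms", "fused"):
            raise ValueError(f"mode must be nmr|ms|fused, got {self.mode!r}")
        if self.fdr_method not in ("bh", "paper"):
            raise ValueError(f"fdr_method must be bh|paper, got {self.fdr_method!r}")
        if self.design is None and not (self.nmr_manifest and self.ms_features and self.metadata):
            raise ValueError("provide either a synthetic design or input paths")


@dataclass
class ResultBundle:
    config: RunConfig
    labels: list[str]
    sample_ids: list[str]
    binned: nmr.BinnedNmrMatrix | None
    curated: ms.FeatureTable | None
    qc: ms.QcReport | None
    fused: fusion.FusedMatrix | None
    X_raw: pd.DataFrame
    X_scaled: pd.DataFrame
    block_of: pd.Series
    plsda: mvda.LatentModel
    inner: dict
    biplot: pd.DataFrame
    oplsda: mvda.LatentModel
    opls_target: str
    q2: float
    permutation: mvda.PermutationReport
    vip_top: pd.DataFrame
    pvalues: pd.Series
    fdr_table: pd.DataFrame
    selected: pd.DataFrame
    annotations: list[ms.Annotation]
    groups: disc.GroupSummary | None
    truth_recall: float | None = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            _LOG.info("stage %s", name)
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - stage boundary
                raise PipelineError(name, e) from e

        return wrapper

    return deco


def _most_distinct_season(model: mvda.LatentModel, labels: list[str]) -> str:
    """Season whose score centroid lies farthest from the overall centroid."""
    T = model.T[:, : min(2, model.n_components)]
    labs = np.asarray(labels)
    overall = T.mean(axis=0)
    best, best_d = None, -1.0
    for season in sorted(set(labels)):
        d = float(np.linalg.norm(T[labs == season].mean(axis=0) - overall))
        if d > best_d:
            best, best_d = season, d
    return best


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute all stages; any stage error aborts with the stage name."""

    study: Study | None = None
    truth = None

    @_stage("load")
    def load():
        nonlocal study, truth
        if config.design is not None:
            study = generate_study(config.design)
            truth = study.truth
            meta = pd.DataFrame([vars(m) for m in study.metadata])
            return study.projections, study.features, meta, reference_library()
        projections = nmr.read_manifest(config.nmr_manifest)
        table = ms.read_feature_table(config.ms_features)
        meta = pd.read_csv(config.metadata)
        library = ms.read_library(config.library) if config.library else reference_library()
        return projections, table, meta, library

    projections, table, meta, library = load()
    labels_by_id = dict(zip(meta["sample_id"].astype(str), meta["season"].astype(str)))

    @_stage("bin")
    def bin_stage():
        return nmr.stack_binned(
            projections, config.bin_lo, config.bin_hi, config.bin_width, config.bin_statistic
        )

    @_stage("curate")
    def curate_stage():
        blanks = config.blank_ids
        if blanks is None:
            blanks = [s for s in table.sample_ids if s.upper().startswith("BLANK")]
        curated = ms.remove_blank_features(table, blanks, config.blank_threshold)
        qc = ms.qc_check_standard(curated)
        if not qc.passed:
            _LOG.warning(
                "external-standard QC failed (nearest %s at rt %.2f, m/z %.4f)",
                qc.nearest_id,
                qc.nearest_rt or float("nan"),
                qc.nearest_mz or float("nan"),
            )
        return curated, qc

    binned = bin_stage() if config.mode in ("nmr", "fused") else None
    curated, qc = curate_stage() if config.mode in ("ms", "fused") else (None, None)

    @_stage("fuse")
    def fuse_stage():
        if config.mode == "fused":
            fused = fusion.fuse(binned, curated)
            return fused, fused.values, fused.block_of
        if config.mode == "nmr":
            X = binned.values
            return None, X, pd.Series(fusion.NMR_BLOCK, index=X.columns)
        X = curated.area_matrix()
        return None, X, pd.Series(fusion.MS_BLOCK, index=X.columns)

    fused, X_raw, block_of = fuse_stage()
    sample_ids = [str(s) for s in X_raw.index]
    missing = [s for s in sample_ids if s not in labels_by_id]
    if missing:
        raise PipelineError("fuse", ValueError(f"samples without metadata: {missing}"))
    labels = [labels_by_id[s] for s in sample_ids]

    @_stage("scale")
    def scale_stage():
        X_scaled, _, _ = mvda.pareto_scale(X_raw)
        return X_scaled

    X_scaled = scale_stage()
    design = mvda.ClassDesign(sample_ids, labels)

    @_stage("fit")
    def fit_stage():
        model = mvda.fit_plsda(X_scaled, design, n_components=config.n_components)
        inner = mvda.inner_relation(model)
        biplot = mvda.biplot_data(model, block_of) if model.n_components >= 2 else pd.DataFrame()
        target = _most_distinct_season(model, labels)
        opls = mvda.fit_oplsda(X_scaled, design.contrast(target), n_ortho=config.n_ortho)
        return model, inner, biplot, target, opls

    plsda, inner, biplot, opls_target, oplsda = fit_stage()

    @_stage("validate")
    def validate_stage():
        q2 = mvda.q2_crossval(
            X_scaled,
            design.Y.to_numpy(),
            n_components=config.n_components,
            folds=config.folds,
            seed=config.seed,
        )
        perm = mvda.permutation_test(
            X_scaled,
            design,
            n=config.n_permutations,
            seed=config.seed,
            n_components=config.n_components,
            folds=config.folds,
        )
        return q2, perm

    q2, permutation = validate_stage()

    @_stage("select")
    def select_stage():
        vip_top = disc.rank_vip(plsda, k=config.k)
        pvals = disc.feature_pvalues(X_raw, labels)
        if config.fdr_method == "paper":
            cand = pvals[pvals.index.isin(vip_top["variable"])]
            fdr_table = disc.fdr_rank(cand, Q=config.Q, alpha=config.alpha)
        else:
            rejected = disc.bh_stepup(pvals, Q=config.Q)
            # present the BH outcome in the same rank-table shape
            fdr_table = disc.fdr_rank(pvals, Q=config.Q, alpha=config.alpha)
            if len(fdr_table):
                fdr_table["retained"] = (
                    fdr_table["variable"].map(rejected).astype(bool).to_numpy()
                )
        selected = disc.select_discriminants(vip_top, fdr_table, universe=X_raw.columns)
        selected["block"] = selected["variable"].map(block_of) if len(selected) else None
        return vip_top, pvals, fdr_table, selected

    vip_top, pvalues, fdr_table, selected = select_stage()

    @_stage("annotate")
    def annotate_stage():
        if curated is None or not len(selected):
            return []
        sel_ids = set(selected["variable"])
        sub = ms.FeatureTable(
            features=[f for f in curated.features if f.feature_id in sel_ids],
            sample_ids=curated.sample_ids,
        )
        return ms.dereplicate(sub, library, tol_ppm=config.tol_ppm)

    annotations = annotate_stage()

    @_stage("summarize")
    def summarize_stage():
        if not len(selected):
            return None
        return disc.group_summaries(X_raw, labels, list(selected["variable"]))

    groups = summarize_stage()

    recall = None
    if truth is not None and config.design is not None and config.design.effect_size > 1:
        planted = [i for i in truth.all_ids() if i in set(X_raw.columns)]
        if planted:
            recall = len(set(selected["variable"]) & set(planted)) / len(planted)

    return ResultBundle(
        config=config,
        labels=labels,
        sample_ids=sample_ids,
        binned=binned,
        curated=curated,
        qc=qc,
        fused=fused,
        X_raw=X_raw,
        X_scaled=X_scaled,
        block_of=block_of,
        plsda=plsda,
        inner=inner,
        biplot=biplot,
        oplsda=oplsda,
        opls_target=opls_target,
        q2=q2,
        permutation=permutation,
        vip_top=vip_top,
        pvalues=pvalues,
        fdr_table=fdr_table,
        selected=selected,
        annotations=annotations,
        groups=groups,
        truth_recall=recall,
    )


# ---------------------------------------------------------------------------
# reporting


def write_report(bundle: ResultBundle) -> str:
    """Human-readable run summary (model diagnostics + discriminant table)."""
    c = bundle.config
    lines = [
        "metabofuse run report",
        "=====================",
        f"mode: {c.mode}   seed: {c.seed}   samples: {len(bundle.sample_ids)}   "
        f"variables: {bundle.X_raw.shape[1]}",
        "",
        "PLS-DA",
        f"  components: {bundle.plsda.n_components}",
        f"  R2X per component: {', '.join(f'{v:.3f}' for v in bundle.plsda.r2x)}",
        f"  R2Y (cum): {bundle.plsda.r2y[-1]:.4f}   Q2 ({c.folds}-fold): {bundle.q2:.4f}",
        f"  inner relation t1~u1: R2 = {bundle.inner['r2']:.4f}, "
        f"slope = {bundle.inner['slope']:.4f}",
        "",
        f"OPLS-DA ({bundle.opls_target} vs rest)",
        f"  R2X(pred) = {bundle.oplsda.r2x_pred:.3f}   R2X(ortho) = {bundle.oplsda.r2x_ortho:.3f}",
        "",
        f"Permutation test (n = {bundle.permutation.n_permutations})",
        f"  R2 intercept = {bundle.permutation.r2_intercept:.4f}",
        f"  Q2 intercept = {bundle.permutation.q2_intercept:.4f}",
        f"  valid (R2 line above Q2 line, negative Q2 intercept): "
        f"{bundle.permutation.valid}",
        "",
        f"Discriminant selection (top-{c.k} VIP, Q = {c.Q:g}, method = {c.fdr_method})",
        f"  retained discriminants: {len(bundle.selected)}",
    ]
    if len(bundle.selected):
        lines.append("")
        lines.append("  id\tblock\tVIP\tp-value\tFDR")
        for row in bundle.selected.to_dict("records"):
            lines.append(
                f"  {row['variable']}\t{row.get('block', '')}\t"
                f"{row['VIP']:.2f}\t{row['p_value']:.5f}\t{row['fdr_reported']:.3f}"
            )
    else:
        lines.append("  no discriminants retained")
    if bundle.annotations:
        lines.append("")
        lines.append("Annotations (accurate mass, Level 3)")
        for a in bundle.annotations:
            lines.append(
                f"  {a.feature_id}: {a.compound} {a.adduct} "
                f"theo {a.theoretical_mz:.4f}, {a.ppm:+.2f} ppm"
            )
    if bundle.truth_recall is not None:
        lines.append("")
        lines.append(f"Planted-discriminant recall: {bundle.truth_recall:.2f}")
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_bundle(bundle: ResultBundle, outdir: str | Path) -> dict:
    """Write every artifact as delimited text plus a checksum manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def save_df(name: str, df: pd.DataFrame, **kw):
        p = outdir / name
        df.to_csv(p, **kw)
        written[name] = p

    if bundle.binned is not None:
        save_df("binned_nmr.csv", bundle.binned.values)
    if bundle.curated is not None:
        save_df("curated_features.csv", bundle.curated.to_frame(), index=False)
    if bundle.fused is not None:
        p = outdir / "fused_matrix.csv"
        fusion.write_fused(bundle.fused, p)
        written["fused_matrix.csv"] = p
    scores = pd.DataFrame(
        bundle.plsda.T,
        index=bundle.sample_ids,
        columns=[f"t{i + 1}" for i in range(bundle.plsda.n_components)],
    )
    scores["season"] = bundle.labels
    save_df("plsda_scores.csv", scores)
    loadings = pd.DataFrame(
        bundle.plsda.P,
        index=bundle.plsda.variable_ids,
        columns=[f"p{i + 1}" for i in range(bundle.plsda.n_components)],
    )
    loadings["block"] = [bundle.block_of[v] for v in bundle.plsda.variable_ids]
    save_df("plsda_loadings.csv", loadings)
    inner = pd.DataFrame({"t1": bundle.inner["t1"], "u1": bundle.inner["u1"]}, index=bundle.sample_ids)
    save_df("inner_relation.csv", inner)
    save_df("biplot.csv", bundle.biplot, index=False)
    save_df("vip_top.csv", bundle.vip_top, index=False)
    save_df("fdr_table.csv", bundle.fdr_table, index=False)
    save_df("discriminants.csv", bundle.selected, index=False)
    perm = pd.DataFrame(
        {
            "correlation": bundle.permutation.correlations,
            "R2": bundle.permutation.r2,
            "Q2": bundle.permutation.q2,
        }
    )
    save_df("permutation.csv", perm, index=False)
    if bundle.annotations:
        ann = pd.DataFrame(
            [
                {
                    "feature_id": a.feature_id,
                    "compound": a.compound,
                    "formula": str(a.formula) if a.formula else "",
                    "adduct": a.adduct,
                    "theoretical_mz": a.theoretical_mz,
                    "observed_mz": a.observed_mz,
                    "ppm": a.ppm,
                    "level": a.level,
                }
                for a in bundle.annotations
            ]
        )
        save_df("annotations.csv", ann, index=False)
    if bundle.groups is not None:
        save_df("group_stats.csv", bundle.groups.stats, index=False)
        save_df("group_anova.csv", bundle.groups.anova, index=False)
        save_df("group_tukey.csv", bundle.groups.tukey, index=False)
    report = write_report(bundle)
    (outdir / "report.txt").write_text(report)
    written["report.txt"] = outdir / "report.txt"

    cfg = asdict(bundle.config)
    if bundle.config.design is not None:
        cfg["design"] = asdict(bundle.config.design)
    manifest = {
        "config": cfg,
        "files": {name: _sha256(p) for name, p in sorted(written.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
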