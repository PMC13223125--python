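"""Leakage-safe stratified cross-validation of the full pipeline.

Every fit-capable stage -- column standardization, univariate
pre-screening, the CNN pretraining head, SKOA selection, EA-GAT
training, the SHAP background -- sees only the training rows of a fold.
Deterministic per-entity representations (windows, event segments,
segment trees, drug depictions) are computed once and reused, since they
involve no fitting across samples. A leakage sentinel refits a fold with
poisoned test rows and asserts that no fitted artifact changes.

Wrapper selection runs over a univariate pre-screened candidate pool
(point-biserial |correlation| with the training labels) so the feature
graph the classifier sees stays desk-scale; the pool size is
configurable and the screening statistic is fitted on training rows
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dscnn, drugrep, eagat, featex, seqrep, skoa
from .cohort import Cohort, SENSITIVE
from .eagat import EAGATConfig
from .skoa import SKOAConfig

ABLATION_VARIANTS = (
    "full",
    "no_skoa",
    "no_mnja",
    "no_drug_structure",
    "non_graph_classifier",
    "no_aranda",
)


@dataclass
class FoldPlan:
    assignments: np.ndarray  # test-fold index per sample
    n_folds: int
    seed: int

    def test_mask(self, fold: int) -> np.ndarray:
        return self.assignments == fold


@dataclass
class PipelineConfig:
    seed: int = 0
    n_folds: int = 10
    variant: str = "full"
    use_tensors: bool = False
    tensor_size: int = 56
    max_segments: int = 40
    k_min: int = 4
    prescreen: int = 30
    shap_background: int = 200
    skoa: SKOAConfig = field(
        default_factory=lambda: SKOAConfig(population=10, max_iter=10)
    )
    eagat: EAGATConfig = field(
        default_factory=lambda: EAGATConfig(
            hidden=8, epochs=150, patience=25, l2=1e-3, fully_connected=False,
            graph_k=10,
        )
    )
    dscnn: dscnn.DSCNNConfig = field(default_factory=dscnn.DSCNNConfig)


def make_folds(labels: Sequence[str], n: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified partition into n test folds, deterministic under seed."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot build {n} folds"
        )
    skf = StratifiedKFold(n_splits=n, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(assignments=assignments, n_folds=n, seed=seed)


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


def _cell_line_tree_channels(
    cohort: Cohort, cell_id: str, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Tree-distance map and event-indicator map for one cell line.

    Segments come from the event scans of genes carrying a mutation call
    in this cell line (capped for tractability); the segment tree over
    their descriptors supplies the patristic map.
    """
    cl = cohort.cell_lines[cell_id]
    size = config.tensor_size
    segments: list[seqrep.SegmentEvent] = []
    mutated = [
        g for k, g in enumerate(cohort.genes)
        if cl.mutation_calls is not None and cl.mutation_calls[k] > 0
    ]
    for gene in mutated:
        variant = cohort.sequences.get(gene)
        reference = cohort.reference_sequences.get(gene, variant)
        if not variant:
            continue
        segs = seqrep.scan_sequence(variant, reference, k_min=config.k_min,
                                    gene_id=gene)
        segments.extend(segs.segments)
        if len(segments) >= config.max_segments:
            segments = segments[: config.max_segments]
            break
    if len(segments) < 2:
        return np.zeros((size, size)), np.zeros((size, size))
    descriptors = [seqrep.segment_descriptor(s) for s in segments]
    tree = seqrep.mnja_build_tree(descriptors, gene_id=cell_id)
    tree_map = seqrep.tree_to_map(tree, size=size)
    order = tree.leaf_order()
    leaf_idx = [int(name[1:]) for name in order]  # leaves are "S{i}"
    event_map = seqrep.event_indicator_map(segments, leaf_idx, size=size)
    return tree_map, event_map


def featurize(
    cohort: Cohort, config: Optional[PipelineConfig] = None
) -> featex.FeatureMatrix:
    """Per-pair feature matrix: deep || handcrafted || attributes.

    Attribute columns carry per-gene omics values (expression, mutation,
    CNV) plus drug descriptors including the drug-target match; with
    ``use_tensors`` the fused tensor per pair additionally yields CNN and
    texture blocks. No statistic fitted across rows is used here, so the
    matrix is fold-agnostic; standardization happens per fold.
    """
    config = config or PipelineConfig()
    genes = cohort.genes
    pair_index = []
    attr_rows = []
    parsed = {
        did: drugrep.parse_structure(d.smiles, d.inchi, drug_id=did)
        for did, d in cohort.drugs.items()
    }
    for rec in cohort.responses:
        cl = cohort.cell_lines[rec.cell_line_id]
        drug = cohort.drugs[rec.drug_id]
        altered = [g for k, g in enumerate(genes) if cl.mutation_calls[k] > 0]
        desc = drugrep.drug_descriptors(
            parsed[rec.drug_id], cell_line_altered_genes=altered,
            drug_targets=drug.targets,
        )
        row = np.concatenate([cl.expression, cl.mutation_calls, cl.cnv, desc])
        attr_rows.append(row)
        pair_index.append(f"{rec.cell_line_id}|{rec.drug_id}")
    attr_names = (
        [f"expression_{g}" for g in genes]
        + [f"mutation_{g}" for g in genes]
        + [f"cnv_{g}" for g in genes]
        + [f"drug_{n}" for n in drugrep.DESCRIPTOR_NAMES]
    )
    index = pd.Index(pair_index, name="pair")
    attributes = pd.DataFrame(np.array(attr_rows), index=index, columns=attr_names)

    if config.use_tensors:
        params = dscnn.init_params(config.dscnn)
        tree_cache = {}
        depiction_cache = {}
        deep_rows, hand_rows = [], []
        for rec in cohort.responses:
            cid, did = rec.cell_line_id, rec.drug_id
            if cid not in tree_cache:
                tree_cache[cid] = _cell_line_tree_channels(cohort, cid, config)
            if did not in depiction_cache:
                depiction_cache[did] = drugrep.render_depiction(
                    parsed[did], size=config.tensor_size
                )
            tree_map, event_map = tree_cache[cid]
            tensor = featex.fuse_tensor(tree_map, event_map, depiction_cache[did])
            deep_rows.append(dscnn.forward_features(tensor.values, params))
            hand_rows.append(featex.handcrafted_features(tensor))
        deep = pd.DataFrame(
            np.array(deep_rows), index=index,
            columns=[f"deep_{k}" for k in range(len(deep_rows[0]))],
        )
        handcrafted = pd.DataFrame(
            np.array(hand_rows), index=index,
            columns=[f"tex_{k}" for k in range(len(hand_rows[0]))],
        )
    else:
        deep = pd.DataFrame(index=index)
        handcrafted = pd.DataFrame(index=index)

    return featex.assemble_features(deep, handcrafted, attributes)


def labels_vector(cohort: Cohort) -> np.ndarray:
    return np.array(
        [1 if r.label == SENSITIVE else 0 for r in cohort.responses], dtype=int
    )


# ---------------------------------------------------------------------------
# Per-fold pipeline
# ---------------------------------------------------------------------------


@dataclass
class FoldArtifacts:
    scaler_mean: np.ndarray
    screened_columns: list[str]
    mask: skoa.FeatureMask
    selected_columns: list[str]
    model: object
    scores: np.ndarray
    test_index: np.ndarray
    metrics: dict[str, float]


def _prescreen(
    X: np.ndarray, y: np.ndarray, train_mask: np.ndarray, top: int
) -> np.ndarray:
    """Columns ranked by |point-biserial correlation| on training rows."""
    Xt, yt = X[train_mask], y[train_mask]
    Xc = Xt - Xt.mean(axis=0)
    yc = yt - yt.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    corr = np.zeros(X.shape[1])
    nz = denom > 0
    corr[nz] = np.abs(Xc[:, nz].T @ yc)[...] / denom[nz]
    top = min(top, X.shape[1])
    return np.sort(np.argsort(-corr, kind="stable")[:top])


def _apply_variant(matrix: featex.FeatureMatrix, variant: str) -> featex.FeatureMatrix:
    if variant not in ABLATION_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; valid: {', '.join(ABLATION_VARIANTS)}"
        )
    drop_tags: set[str] = set()
    if variant == "no_mnja":
        drop_tags = {"deep", "handcrafted"}
    elif variant == "no_drug_structure":
        drop_tags = {"drug-descriptor"}
    if not drop_tags:
        return matrix
    keep = [c for c in matrix.columns if matrix.provenance[c] not in drop_tags]
    return featex.FeatureMatrix(
        data=matrix.data[keep],
        provenance={c: matrix.provenance[c] for c in keep},
    )


def run_fold(
    matrix: featex.FeatureMatrix,
    y: np.ndarray,
    plan: FoldPlan,
    fold: int,
    config: PipelineConfig,
    poison_test_rows: bool = False,
) -> FoldArtifacts:
    """Train on a fold's training rows, score its held-out test rows.

    ``poison_test_rows`` replaces test-row features by extreme constants
    before fitting; the leakage sentinel uses it to verify that fitted
    artifacts do not depend on test rows.
    """
    matrix = _apply_variant(matrix, config.variant)
    X = matrix.to_array()
    test_mask = plan.test_mask(fold)
    train_mask = ~test_mask
    if poison_test_rows:
        X = X.copy()
        X[test_mask] = 1e9

    scaler = featex.FoldScaler().fit(X[train_mask])
    Xs = scaler.transform(X)

    cols = _prescreen(X, y, train_mask, config.prescreen)
    col_names = [matrix.columns[c] for c in cols]
    X_pool = Xs[:, cols]

    if config.variant == "no_skoa":
        mask = skoa.FeatureMask(selected=np.ones(len(cols), dtype=bool),
                                fold_id=fold)
    else:
        mask, _ = skoa.run(
            X_pool[train_mask], y[train_mask], seed=config.seed + fold,
            config=config.skoa, fold_id=fold,
        )
    sel = mask.column_indices()
    X_sel = X_pool[:, sel]
    selected_names = [col_names[s] for s in sel]

    if config.variant == "non_graph_classifier":
        model = eagat.train_mlp(X_sel[train_mask], y[train_mask],
                                seed=config.seed + fold)
        scores = model.predict_proba(X_sel[test_mask])[:, 1]
    else:
        activation = "relu" if config.variant == "no_aranda" else "aranda"
        egcfg = replace(config.eagat, activation=activation,
                        seed=config.seed + fold)
        model = eagat.train(X_sel[train_mask], y[train_mask], config=egcfg)
        scores = eagat.sensitivity_score(X_sel[test_mask], model)

    metrics = score_metrics(y[test_mask], scores)
    return FoldArtifacts(
        scaler_mean=scaler.mean_.copy(),
        screened_columns=col_names,
        mask=mask,
        selected_columns=selected_names,
        model=model,
        scores=scores,
        test_index=np.flatnonzero(test_mask),
        metrics=metrics,
    )


def score_metrics(y_true: np.ndarray, scores: np.ndarray,
                  threshold: float = 0.5) -> dict[str, float]:
    """Threshold and ranking metrics for one set of predictions."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    y_true = np.asarray(y_true, dtype=int)
    pred = (np.asarray(scores) > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    from .doseresponse import confusion_metrics

    out = confusion_metrics(tp, fp, tn, fn)
    out["precision"] = out["ppv"]
    out["recall"] = out["sensitivity"]
    pr = out["precision"]
    rc = out["recall"]
    out["f1"] = (
        2 * pr * rc / (pr + rc) if np.isfinite(pr + rc) and (pr + rc) > 0 else float("nan")
    )
    if np.unique(y_true).size == 2:
        out["auroc"] = float(roc_auc_score(y_true, scores))
        out["auprc"] = float(average_precision_score(y_true, scores))
    else:
        out["auroc"] = out["auprc"] = float("nan")
    return out


@dataclass
class MetricsReport:
    per_fold: pd.DataFrame
    pooled: dict[str, float]
    stability: Optional[float]
    variant: str

    def summary(self) -> pd.DataFrame:
        stats = self.per_fold.agg(["mean", "std"]).T
        stats.columns = ["mean", "sd"]
        return stats


def run_cv(
    matrix: featex.FeatureMatrix,
    y: np.ndarray,
    config: PipelineConfig,
    plan: Optional[FoldPlan] = None,
) -> tuple[MetricsReport, list[FoldArtifacts]]:
    """Cross-validate the pipeline; pooled and per-fold metrics."""
    plan = plan or make_folds(y, n=config.n_folds, seed=config.seed)
    artifacts = []
    pooled_scores = np.zeros(len(y))
    for fold in range(plan.n_folds):
        art = run_fold(matrix, y, plan, fold, config)
        pooled_scores[art.test_index] = art.scores
        artifacts.append(art)
    per_fold = pd.DataFrame([a.metrics for a in artifacts])
    pooled = score_metrics(y, pooled_scores)
    stability = (
        skoa.jaccard_stability([a.mask for a in artifacts])
        if len(artifacts) > 1
        else None
    )
    report = MetricsReport(
        per_fold=per_fold, pooled=pooled, stability=stability,
        variant=config.variant,
    )
    return report, artifacts


def run_ablation(
    matrix: featex.FeatureMatrix,
    y: np.ndarray,
    variants: Sequence[str],
    config: PipelineConfig,
) -> dict[str, MetricsReport]:
    """Run several variants over identical folds for controlled comparison."""
    plan = make_folds(y, n=config.n_folds, seed=config.seed)
    reports = {}
    for variant in variants:
        if variant not in ABLATION_VARIANTS:
            raise ValueError(
                f"unknown variant {variant!r}; valid: "
                f"{', '.join(ABLATION_VARIANTS)}"
            )
        vcfg = replace(config, variant=variant)
        reports[variant], _ = run_cv(matrix, y, vcfg, plan=plan)
    return reports


def explain_fold(
    matrix: featex.FeatureMatrix,
    y: np.ndarray,
    plan: FoldPlan,
    fold: int,
    config: PipelineConfig,
    artifacts: FoldArtifacts,
    n_explained: int = 16,
    n_coalitions: int = 400,
    background_size: Optional[int] = None,
):
    """Kernel SHAP attribution of a fitted fold's test predictions.

    Rebuilds the fold's standardized selected-feature view, draws the
    background from training rows only (pair identifiers guard against
    overlap), and explains up to ``n_explained`` test samples.
    """
    from . import explain

    matrix = _apply_variant(matrix, config.variant)
    X = matrix.to_array()
    test_mask = plan.test_mask(fold)
    train_mask = ~test_mask
    scaler = featex.FoldScaler().fit(X[train_mask])
    Xs = scaler.transform(X)
    name_to_pos = {c: i for i, c in enumerate(matrix.columns)}
    sel_cols = [name_to_pos[c] for c in artifacts.selected_columns]
    X_sel = Xs[:, sel_cols]

    rng = np.random.default_rng(config.seed + 1000 + fold)
    train_idx = np.flatnonzero(train_mask)
    bg_size = min(background_size or config.shap_background, len(train_idx))
    bg_idx = rng.choice(train_idx, size=bg_size, replace=False)
    samp_idx = np.flatnonzero(test_mask)[:n_explained]
    pair_ids = np.asarray(matrix.data.index)

    model = artifacts.model
    if isinstance(model, eagat.EAGATParams):
        fn = lambda A: eagat.sensitivity_score(A, model)  # noqa: E731
    else:
        fn = lambda A: model.predict_proba(A)[:, 1]  # noqa: E731
    return explain.kernel_shap(
        fn,
        X_sel[samp_idx],
        X_sel[bg_idx],
        seed=config.seed + fold,
        feature_names=artifacts.selected_columns,
        n_coalitions=n_coalitions,
        sample_ids=pair_ids[samp_idx],
        background_ids=pair_ids[bg_idx],
    )


def leakage_sentinel(
    matrix: featex.FeatureMatrix,
    y: np.ndarray,
    plan: FoldPlan,
    fold: int,
    config: PipelineConfig,
) -> bool:
    """True when poisoning test rows changes no fitted artifact."""
    clean = run_fold(matrix, y, plan, fold, config)
    poisoned = run_fold(matrix, y, plan, fold, config, poison_test_rows=True)
    same_scaler = np.allclose(clean.scaler_mean, poisoned.scaler_mean)
    same_screen = clean.screened_columns == poisoned.screened_columns
    same_mask = np.array_equal(clean.mask.selected, poisoned.mask.selected)
    same_model = True
    if isinstance(clean.model, eagat.EAGATParams):
        same_model = all(
            np.allclose(a, b)
            for a, b in zip(clean.model.flat(), poisoned.model.flat())
        )
    return bool(same_scaler and same_screen and same_mask and same_model)
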