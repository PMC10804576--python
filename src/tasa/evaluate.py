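"""Scoring of DMP/DMR calls and validation of the simulator itself.

DMP calls are scored as plain set confusion counts over the probe
universe. DMR calls are scored with a 20%-overlap rule: a truth region
found with more than 20% of its length covered by detections is a TP,
otherwise an FN; a detected region whose overlap with every truth region
is at most 20% of its own length is an FP. Region sets are also
stratified by effect size (mean absolute case-control beta difference,
threshold 0.3) to score large- and small-effect regions separately.

The simulator-validation suite quantifies how closely simulated samples
resemble their target tissue: a PCA dispersion score (distance between
group centroids in the leading principal components) and an SVM
protocol in which a multi-class classifier trained on real tissue
profiles classifies the simulated samples, with the mean absolute
decision value as the confidence score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import cross_val_score, train_test_split
from sklearn.svm import SVC

from .core import BetaMatrix, EvalReport, RegionSet, ValidationError
from .simulate import SimulationResult

__all__ = [
    "OverlapConfig",
    "DispersionReport",
    "SvmEvalReport",
    "dmp_eval",
    "dmr_eval",
    "stratify_regions_by_effect",
    "guideline_improvement",
    "pca_dispersion",
    "svm_eval",
    "run_pipelines",
]


@dataclass
class OverlapConfig:
    min_overlap_fraction: float = 0.2
    fold_change_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap_fraction < 1):
            raise ValidationError("min_overlap_fraction must lie in (0, 1)")
        if not (0 < self.fold_change_threshold < 1):
            raise ValidationError("fold_change_threshold must lie in (0, 1)")


@dataclass
class DispersionReport:
    score_sim_vs_target_ref: float
    score_sim_vs_source: float
    score_grouped: float


@dataclass
class SvmEvalReport:
    train_accuracy: float
    cv_accuracy: float
    test_accuracy: float
    mean_abs_decision: float
    simulated_predictions: pd.Series


def dmp_eval(truth_probes: set, predicted_probes: set, universe: set) -> EvalReport:
    """Confusion counts for probe-level calls over a fixed universe."""
    truth, pred, uni = set(truth_probes), set(predicted_probes), set(universe)
    outside = (truth | pred) - uni
    if outside:
        raise ValidationError(f"probes outside the universe: {sorted(outside)[:5]}")
    tp = len(truth & pred)
    fp = len(pred - truth)
    fn = len(truth - pred)
    tn = len(uni - (truth | pred))
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn)


def dmr_eval(
    truth: RegionSet, detected: RegionSet, cfg: OverlapConfig | None = None
) -> EvalReport:
    """Score detected regions against truth with the 20%-overlap rule.

    Truth side: a truth region is a TP when the total length covered by
    detections strictly exceeds ``min_overlap_fraction`` of the truth
    length, else an FN (overlaps from several detections are pooled).
    Detection side: a detected region is an FP when its overlap with
    every single truth region is at most the fraction of its *own*
    length — so a long detection grazing a short truth region can count
    as both the TP for that region and an FP for itself. There is no
    region-level TN.
    """
    cfg = cfg or OverlapConfig()
    styles = truth.chrom_styles() | detected.chrom_styles()
    if len(styles) > 1:
        raise ValidationError("mixed chromosome naming ('chr1' vs '1') between region sets")

    frac = cfg.min_overlap_fraction
    tp = fn = 0
    for t in truth:
        covered = sum(t.overlap_len(d) for d in detected)
        if covered > frac * t.length:
            tp += 1
        else:
            fn += 1
    fp = 0
    for d in detected:
        best = max((d.overlap_len(t) for t in truth), default=0)
        if best <= frac * d.length:
            fp += 1
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=None)


def stratify_regions_by_effect(
    truth: RegionSet, sim: SimulationResult, cfg: OverlapConfig | None = None
) -> tuple[RegionSet, RegionSet]:
    """Split truth regions into large- and small-effect sets.

    A region's effect is the mean over member probes of the absolute
    case-control mean beta difference; regions with effect above
    ``fold_change_threshold`` go to the large set.
    """
    cfg = cfg or OverlapConfig()
    missing = truth.probe_ids - set(sim.beta.probe_ids)
    if missing:
        raise ValidationError(f"region probes missing from matrix: {sorted(missing)[:5]}")
    case = sim.beta.beta[sim.case_samples].mean(axis=1)
    ctrl = sim.beta.beta[sim.control_samples].mean(axis=1)
    diff = (case - ctrl).abs()
    large, small = [], []
    for reg in truth:
        effect = float(diff.loc[list(reg.probes)].mean())
        (large if effect > cfg.fold_change_threshold else small).append(reg)
    return RegionSet(large), RegionSet(small)


def guideline_improvement(
    f1_by_pipeline: Mapping[str, float], selected_pipeline: str
) -> float | None:
    """Percent F1 gain of the selected pipeline over the pipeline average.

    Returns ``None`` when the average F1 is zero (undefined).
    """
    if len(f1_by_pipeline) < 2:
        raise ValidationError("need at least 2 pipelines to compare")
    if selected_pipeline not in f1_by_pipeline:
        raise ValidationError(f"selected pipeline {selected_pipeline!r} not among candidates")
    mean_f1 = float(np.mean(list(f1_by_pipeline.values())))
    if mean_f1 == 0:
        return None
    return 100.0 * (f1_by_pipeline[selected_pipeline] - mean_f1) / mean_f1


def pca_dispersion(group_a: pd.DataFrame, group_b: pd.DataFrame, k: int = 2) -> float:
    """Distance between two sample groups in a shared PC space.

    Both inputs are probes x samples slices over the same probes. PCA is
    fitted on the pooled samples; the score is the Euclidean distance
    between the two group centroids in the first ``k`` components.
    Lower means the groups are harder to tell apart.
    """
    if not group_a.index.equals(group_b.index):
        group_b = group_b.loc[group_a.index]
    x = np.hstack([group_a.to_numpy(dtype=float), group_b.to_numpy(dtype=float)]).T
    n = x.shape[0]
    max_k = min(n, x.shape[1])
    if k > max_k or n < k + 1:
        raise ValidationError(f"k={k} exceeds available components for {n} samples")
    coords = PCA(n_components=k, random_state=0).fit_transform(x)
    ca = coords[: group_a.shape[1]].mean(axis=0)
    cb = coords[group_a.shape[1] :].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def dispersion_report(
    simulated: pd.DataFrame,
    target_ref_samples: pd.DataFrame,
    source_samples: pd.DataFrame,
    k: int = 2,
) -> DispersionReport:
    """The three dispersion comparisons used to rank simulators.

    (1) simulated vs real target-tissue samples — lower is better;
    (2) simulated vs source-tissue samples — higher is better;
    (3) {simulated + real target} vs {source samples} — higher is better.
    """
    sim_plus_target = pd.concat([simulated, target_ref_samples], axis=1)
    return DispersionReport(
        score_sim_vs_target_ref=pca_dispersion(simulated, target_ref_samples, k),
        score_sim_vs_source=pca_dispersion(simulated, source_samples, k),
        score_grouped=pca_dispersion(sim_plus_target, source_samples, k),
    )


def svm_eval(
    train_tissues: BetaMatrix,
    simulated: BetaMatrix,
    k: int = 10,
    split: float = 0.8,
    folds: int = 10,
    seed: int = 0,
) -> SvmEvalReport:
    """Classify simulated samples with an SVM trained on real tissues.

    Tissue labels come from the ``group`` metadata column. A random
    ``split`` fraction of samples trains a PCA (first ``k`` components)
    and a linear one-vs-rest SVM with ``folds``-fold cross-validation;
    held-out and simulated samples are projected into the trained PC
    space before classification. The mean absolute decision value over
    simulated samples measures how confidently they land in a class.
    """
    labels = train_tissues.sample_meta["group"]
    classes = labels.unique()
    if len(classes) < 3:
        raise ValidationError("need at least 3 tissue classes")
    counts = labels.value_counts()
    if (counts < folds).any():
        raise ValidationError(
            f"classes with fewer samples than folds: {counts[counts < folds].index.tolist()}"
        )
    x = train_tissues.beta.to_numpy(dtype=float).T
    y = labels.to_numpy()
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, train_size=split, random_state=seed, stratify=y
    )
    pca = PCA(n_components=min(k, x_tr.shape[0] - 1, x_tr.shape[1]), random_state=0).fit(x_tr)
    p_tr, p_te = pca.transform(x_tr), pca.transform(x_te)
    clf = SVC(kernel="linear", decision_function_shape="ovr", random_state=seed)
    cv_acc = float(np.mean(cross_val_score(clf, p_tr, y_tr, cv=folds)))
    clf.fit(p_tr, y_tr)
    sim_probes = simulated.beta.loc[train_tissues.probe_ids]
    p_sim = pca.transform(sim_probes.to_numpy(dtype=float).T)
    decisions = clf.decision_function(p_sim)
    preds = pd.Series(clf.predict(p_sim), index=simulated.sample_ids)
    return SvmEvalReport(
        train_accuracy=float(clf.score(p_tr, y_tr)),
        cv_accuracy=cv_acc,
        test_accuracy=float(clf.score(p_te, y_te)),
        mean_abs_decision=float(np.mean(np.abs(decisions))),
        simulated_predictions=preds,
    )


def run_pipelines(
    sim: SimulationResult,
    manifest: pd.DataFrame,
    normalizations: Sequence[str] = ("raw", "baqn"),
    batch_corrections: Sequence[str] = ("none", "combat"),
    q_max: float = 0.05,
    overlap_cfg: OverlapConfig | None = None,
) -> pd.DataFrame:
    """Score every normalization x batch-correction pipeline variant.

    Each variant preprocesses the simulated scenario, runs the internal
    DMP caller, merges calls into regions, and scores DMPs against the
    truth probe set and DMRs against the truth regions. Returns one row
    per pipeline with the confusion-derived metrics; F1 (with absent
    values treated as 0 for ranking) is the selection criterion.
    """
    from . import detect as _detect
    from . import preprocess as _pre

    rows = []
    universe = set(sim.beta.probe_ids)
    for norm in normalizations:
        if norm == "raw":
            normed = sim.beta
        elif norm == "baqn":
            normed = _pre.baqn(sim.beta, manifest)
        elif norm == "betaqn":
            normed = _pre.betaqn(sim.beta)
        else:
            raise ValidationError(f"unknown normalization {norm!r}")
        for bc in batch_corrections:
            if bc == "none":
                data = normed
            elif bc == "combat":
                data = _pre.batch_correct(normed)
            else:
                raise ValidationError(f"unknown batch correction {bc!r}")
            dmps = _detect.dmp_ttest(data, q_max=q_max)
            called = _detect.dmps_to_regions(dmps, manifest)
            dmp_rep = dmp_eval(
                sim.truth_probes, set(dmps.index[dmps["significant"]]), universe
            )
            dmr_rep = dmr_eval(sim.truth_regions, called, overlap_cfg)
            rows.append(
                {
                    "pipeline": f"{norm}+{bc}",
                    "normalization": norm,
                    "batch_correction": bc,
                    "dmp_f1": dmp_rep.f1,
                    "dmp_precision": dmp_rep.precision,
                    "dmp_recall": dmp_rep.recall,
                    "dmr_f1": dmr_rep.f1,
                    "dmr_precision": dmr_rep.precision,
                    "dmr_recall": dmr_rep.recall,
                    "n_detected_regions": len(called),
                }
            )
    return pd.DataFrame(rows).set_index("pipeline")
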