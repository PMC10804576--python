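"""Confusion scoring, the 20%-overlap DMR rule, and simulator validation."""

import numpy as np
import pandas as pd
import pytest

from tasa.core import BetaMatrix, Region, RegionSet, ValidationError
from tasa.evaluate import (
    OverlapConfig,
    dmp_eval,
    dmr_eval,
    guideline_improvement,
    pca_dispersion,
    stratify_regions_by_effect,
    svm_eval,
)
from tasa.simulate import SimulationResult


def brute_force_dmr(truth, detected, frac=0.2):
    """Exhaustive pairwise interval intersection, independent loop."""
    def olap(a, b):
        if a.chrom != b.chrom:
            return 0
        return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)

    tp = sum(
        1 for t in truth if sum(olap(t, d) for d in detected) > frac * (t.end - t.start + 1)
    )
    fn = len(truth.regions) - tp
    fp = sum(
        1
        for d in detected
        if all(olap(d, t) <= frac * (d.end - d.start + 1) for t in truth)
    )
    return tp, fp, fn


def _random_region_set(rng, n, chroms=("chr1", "chr2")):
    regions = []
    for chrom in chroms:
        pos = 1
        for _ in range(n // len(chroms)):
            start = pos + int(rng.integers(5, 400))
            end = start + int(rng.integers(10, 600))
            regions.append(Region(chrom, start, end))
            pos = end + 1
    return RegionSet(regions)


class TestDmpEval:
    def test_perfect_prediction(self):
        uni = {f"p{i}" for i in range(10)}
        truth = {"p0", "p1"}
        r = dmp_eval(truth, truth, uni)
        assert r.precision == r.recall == r.f1 == 1.0

    def test_counts_arithmetic(self):
        uni = {f"p{i}" for i in range(100)}
        truth = set(list(uni)[:10])
        pred = set(list(uni)[2:12])
        r = dmp_eval(truth, pred, uni)
        assert (r.tp, r.fp, r.fn, r.tn) == (8, 2, 2, 88)
        assert r.precision == pytest.approx(0.8)
        assert r.recall == pytest.approx(0.8)
        assert r.f1 == pytest.approx(0.8)

    def test_matches_set_oracle_on_random_sets(self):
        rng = np.random.default_rng(1)
        uni = [f"p{i}" for i in range(1000)]
        for _ in range(20):
            truth = set(rng.choice(uni, size=rng.integers(0, 300), replace=False))
            pred = set(rng.choice(uni, size=rng.integers(0, 300), replace=False))
            r = dmp_eval(truth, pred, set(uni))
            assert r.tp == len(truth & pred)
            assert r.fp == len(pred - truth)
            assert r.fn == len(truth - pred)
            assert r.tn == 1000 - len(truth | pred)

    def test_prediction_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            dmp_eval({"a"}, {"zz"}, {"a", "b"})


class TestDmrEval:
    def test_exact_match_perfect(self):
        rs = RegionSet([Region("chr1", 100, 200), Region("chr1", 500, 700)])
        r = dmr_eval(rs, rs)
        assert r.f1 == 1.0 and r.fp == 0 and r.fn == 0

    def test_boundary_twenty_percent_tie(self):
        # truth [100,199] len 100; detected [150,399] len 250
        # overlap 50 > 20 -> truth is a TP; 50/250 = exactly 0.2, not
        # strictly more -> the detection still counts as an FP
        truth = RegionSet([Region("chr1", 100, 199)])
        det = RegionSet([Region("chr1", 150, 399)])
        r = dmr_eval(truth, det)
        assert (r.tp, r.fp, r.fn) == (1, 1, 0)
        assert r.precision == 0.5 and r.recall == 1.0

    def test_pooled_detections_cover_truth(self):
        truth = RegionSet([Region("chr1", 100, 199)])
        det = RegionSet([Region("chr1", 100, 111), Region("chr1", 150, 161)])
        # each detection covers 12% alone, 24% pooled -> TP
        r = dmr_eval(truth, det)
        assert r.tp == 1 and r.fn == 0 and r.fp == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            truth = _random_region_set(rng, int(rng.integers(2, 12)))
            det = _random_region_set(rng, int(rng.integers(2, 12)))
            r = dmr_eval(truth, det)
            assert (r.tp, r.fp, r.fn) == brute_force_dmr(truth, det)

    def test_irrelevant_detections_hurt_precision_not_recall(self):
        rng = np.random.default_rng(3)
        truth = _random_region_set(rng, 6)
        det = RegionSet(list(truth.regions))
        base = dmr_eval(truth, det)
        far = RegionSet(list(det.regions) + [Region("chr1", 10**6, 10**6 + 50)])
        with_noise = dmr_eval(truth, far)
        assert with_noise.recall == base.recall
        assert with_noise.precision < base.precision

    def test_mixed_chromosome_naming_rejected(self):
        truth = RegionSet([Region("chr1", 1, 100)])
        det = RegionSet([Region("1", 1, 100)])
        with pytest.raises(ValidationError, match="naming"):
            dmr_eval(truth, det)


def _sim_with_shifts(shifts):
    """Two regions of 3 probes each; cases shifted by the given amounts."""
    probes = [f"cg{i}" for i in range(6)]
    samples = [f"S{j}" for j in range(8)]
    vals = np.full((6, 8), 0.4)
    for i, shift in enumerate(np.repeat(shifts, 3)):
        vals[i, :4] += shift
    meta = pd.DataFrame({"group": ["case"] * 4 + ["control"] * 4}, index=samples)
    regions = RegionSet(
        [
            Region("chr1", 100, 130, tuple(probes[:3])),
            Region("chr1", 500, 530, tuple(probes[3:])),
        ]
    )
    return SimulationResult(
        beta=BetaMatrix(pd.DataFrame(vals, index=probes, columns=samples), meta),
        truth_regions=regions,
        truth_probes=set(probes),
        case_samples=samples[:4],
        control_samples=samples[4:],
    )


class TestStratify:
    @pytest.mark.parametrize(
        "shifts, n_large, n_small",
        [((0.4, 0.4), 2, 0), ((0.1, 0.1), 0, 2), ((0.4, 0.1), 1, 1)],
    )
    def test_partition_matches_construction(self, shifts, n_large, n_small):
        sim = _sim_with_shifts(shifts)
        large, small = stratify_regions_by_effect(sim.truth_regions, sim)
        assert (len(large), len(small)) == (n_large, n_small)
        assert len(large) + len(small) == len(sim.truth_regions)

    def test_missing_probe_rejected(self):
        sim = _sim_with_shifts((0.4, 0.4))
        rogue = RegionSet([Region("chr1", 900, 950, ("cgZZ",))])
        with pytest.raises(ValidationError, match="missing"):
            stratify_regions_by_effect(rogue, sim)


class TestGuidelineImprovement:
    def test_arithmetic(self):
        assert guideline_improvement(
            {"a": 0.6, "b": 0.5, "c": 0.4}, "a"
        ) == pytest.approx(20.0)

    def test_selected_equals_mean_is_zero(self):
        assert guideline_improvement({"a": 0.5, "b": 0.5}, "a") == pytest.approx(0.0)

    def test_best_of_random_scores_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = {f"p{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 5))}
            best = max(scores, key=scores.get)
            assert guideline_improvement(scores, best) >= 0

    def test_zero_mean_undefined(self):
        assert guideline_improvement({"a": 0.0, "b": 0.0}, "a") is None


class TestPcaDispersion:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.uniform(0, 1, size=(50, 10)))
        assert pca_dispersion(a, a.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_score_proportional_to_separation(self):
        # two point-mass groups separated by delta along one probe axis:
        # the leading PC is that axis, so the score equals delta
        v = np.full(50, 0.4)
        scores = []
        for delta in (0.1, 0.2):
            a = pd.DataFrame(np.tile(v[:, None], 6))
            shifted = v.copy()
            shifted[0] += delta
            b = pd.DataFrame(np.tile(shifted[:, None], 6))
            scores.append(pca_dispersion(a, b))
        assert scores[0] == pytest.approx(0.1, abs=1e-9)
        assert scores[1] == pytest.approx(2 * scores[0], rel=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame(rng.uniform(0, 1, size=(30, 8)))
        b = pd.DataFrame(rng.uniform(0, 1, size=(30, 6)))
        k = 2
        x = np.hstack([a.to_numpy(), b.to_numpy()]).T
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (x.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        pcs = v[:, np.argsort(w)[::-1][:k]]
        coords = xc @ pcs
        oracle = np.linalg.norm(coords[:8].mean(axis=0) - coords[8:].mean(axis=0))
        assert pca_dispersion(a, b, k) == pytest.approx(oracle, rel=1e-8)

    def test_k_too_large_rejected(self):
        a = pd.DataFrame(np.full((5, 2), 0.5))
        with pytest.raises(ValidationError, match="k="):
            pca_dispersion(a, a, k=10)


def _three_tissue_world(seed=0, n_probes=80, per_class=30, sep=0.3, noise=0.02):
    rng = np.random.default_rng(seed)
    centers = {
        "monocyte": rng.uniform(0.2, 0.4, n_probes),
        "cd8": rng.uniform(0.2, 0.4, n_probes) + sep,
        "breast": rng.uniform(0.2, 0.4, n_probes) - 0.15,
    }
    cols, labels, mats = [], [], []
    for tissue, center in centers.items():
        block = np.clip(
            center[:, None] + rng.normal(0, noise, size=(n_probes, per_class)), 0, 1
        )
        mats.append(block)
        cols += [f"{tissue}{j}" for j in range(per_class)]
        labels += [tissue] * per_class
    probes = [f"cg{i}" for i in range(n_probes)]
    beta = pd.DataFrame(np.hstack(mats), index=probes, columns=cols)
    meta = pd.DataFrame({"group": labels}, index=cols)
    return BetaMatrix(beta, meta), centers


class TestSvmEval:
    def test_separated_tissues_classified_perfectly(self):
        train, centers = _three_tissue_world()
        rng = np.random.default_rng(9)
        simulated = BetaMatrix(
            pd.DataFrame(
                np.clip(centers["cd8"][:, None] + rng.normal(0, 0.02, size=(80, 5)), 0, 1),
                index=train.probe_ids,
                columns=[f"sim{j}" for j in range(5)],
            )
        )
        rep = svm_eval(train, simulated, seed=1)
        assert rep.train_accuracy == 1.0
        assert rep.test_accuracy == 1.0
        assert (rep.simulated_predictions == "cd8").all()
        assert rep.mean_abs_decision > 0

    def test_permuted_labels_near_chance(self):
        train, _ = _three_tissue_world(seed=3)
        rng = np.random.default_rng(4)
        train.sample_meta["group"] = rng.permutation(train.sample_meta["group"].to_numpy())
        simulated = train.subset_samples(list(train.sample_ids[:5]))
        rep = svm_eval(train, simulated, seed=2)
        assert rep.cv_accuracy < 0.6  # 3 classes -> chance ~ 1/3

    def test_too_few_classes_rejected(self):
        train, _ = _three_tissue_world()
        train.sample_meta["group"] = ["a"] * 45 + ["b"] * 45
        with pytest.raises(ValidationError, match="3 tissue classes"):
            svm_eval(train, train)
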