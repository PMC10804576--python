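"""Tissue-aware simulation of differentially methylated regions.

Starting from a real (or synthetic) source beta matrix, probes inside
candidate co-methylated regions are shifted so that designated case
samples mimic a target tissue. Per-probe the shift is anchored to a pair
of tissue reference profiles: mu_IR is the source-tissue reference mean
and the simulated value for probe p in case sample j is

    beta'[p, j] = beta[p, j] - (mu_IR[p] - b[p, j])

where b is drawn by one of four approaches of increasing realism:

S1  b = mu_SR, the target reference mean (deterministic shift);
S2  a per-probe average of n uniform draws on [min_SR, max_SR], then a
    per-sample uniform around that average;
S3  b ~ Normal(mu_SR, sigma_I) per sample (displayed-equation form), or
    Normal(a_bar, sigma_I) with a_bar from uniform draws (text form);
S4  a_i ~ Beta(0.4, 0.5) truncated to [min_SR, max_SR], a_bar their
    mean, then b ~ Normal(a_bar, sigma_I) per sample.

sigma_I is the per-probe standard deviation of the source data, so the
simulated samples inherit the source's inter-sample variability while
their level moves to the target tissue. Control samples and probes
outside the regions are left bit-identical to the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, RegionSet, ReferenceProfile, SourceStats, ValidationError
from .fixtures import TABLE1_LARGE, TABLE1_SMALL, FixtureConfig
from . import fixtures
from .regions import RegionConfig, candidate_regions, comethylation_scores

__all__ = [
    "SimulatorConfig",
    "DrawSet",
    "SimulationResult",
    "ScenarioConfig",
    "truncated_beta_draw",
    "simulate",
    "build_scenarios",
]

APPROACHES = ("S1", "S2", "S3", "S4")


@dataclass
class SimulatorConfig:
    approach: str = "S4"
    beta_alpha: float = 0.4
    beta_beta: float = 0.5
    clamp_eps: float = 1e-6
    seed: int = 0
    # S3 as printed draws b ~ N(mu_SR, sigma_I); the surrounding text
    # instead describes uniform first-stage draws that are averaged and
    # fed to the normal. Both are available; the equation is the default.
    s3_mode: str = "equation"
    # number of first-stage draws n; defaults to the number of case samples
    n_first_stage: int | None = None

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValidationError(f"approach must be one of {APPROACHES}")
        if self.beta_alpha <= 0 or self.beta_beta <= 0:
            raise ValidationError("beta distribution parameters must be positive")
        if not (0 < self.clamp_eps < 0.5):
            raise ValidationError("clamp_eps must lie in (0, 0.5)")
        if self.s3_mode not in ("equation", "text"):
            raise ValidationError("s3_mode must be 'equation' or 'text'")


@dataclass
class DrawSet:
    """The per-probe draws behind one simulated probe (for inspection)."""

    a: np.ndarray
    a_bar: float
    b: np.ndarray
    b_u: float | None
    n: int


@dataclass
class SimulationResult:
    beta: BetaMatrix
    truth_regions: RegionSet
    truth_probes: set[str]
    case_samples: list[str]
    control_samples: list[str]
    region_effects: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def measured_region_effects(self) -> pd.Series:
        """Mean over member probes of |mean(case) - mean(control)|, per region."""
        case = self.beta.beta[self.case_samples].mean(axis=1)
        ctrl = self.beta.beta[self.control_samples].mean(axis=1)
        diff = (case - ctrl).abs()
        vals = {}
        for i, reg in enumerate(self.truth_regions):
            vals[f"{reg.chrom}:{reg.start}-{reg.end}"] = float(diff.loc[list(reg.probes)].mean())
        return pd.Series(vals, dtype=float)


def truncated_beta_draw(
    alpha: float,
    beta: float,
    lo,
    hi,
    count: int | tuple[int, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draws from Beta(alpha, beta) conditioned on [lo, hi].

    Inverse-CDF sampling: uniforms on [F(lo), F(hi)] pushed through the
    beta quantile function. ``lo``/``hi`` may be arrays broadcast
    against the requested shape's trailing axis.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(lo >= hi):
        raise ValidationError("truncation requires lo < hi")
    if np.any(lo < 0) or np.any(hi > 1):
        raise ValidationError("truncation bounds must lie in [0, 1]")
    f_lo = stats.beta.cdf(lo, alpha, beta)
    f_hi = stats.beta.cdf(hi, alpha, beta)
    u = rng.uniform(f_lo, f_hi, size=count)
    return stats.beta.ppf(u, alpha, beta)


def _first_stage_average(
    cfg: SimulatorConfig, lo: np.ndarray, hi: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-probe average of n first-stage draws (uniform or truncated beta)."""
    width = hi - lo
    degenerate = width <= 0
    hi_eff = np.where(degenerate, lo + 1e-9, hi)
    if cfg.approach == "S4":
        a = truncated_beta_draw(cfg.beta_alpha, cfg.beta_beta, lo, hi_eff, (n, len(lo)), rng)
    else:
        a = rng.uniform(lo, hi_eff, size=(n, len(lo)))
    a_bar = a.mean(axis=0)
    return np.where(degenerate, lo, a_bar)


def simulate(
    source: BetaMatrix,
    case_samples: Iterable[str],
    regions: RegionSet,
    ref_input: ReferenceProfile,
    ref_target: ReferenceProfile,
    stats_src: SourceStats | None = None,
    cfg: SimulatorConfig | None = None,
) -> SimulationResult:
    """Alter region probes of the case samples toward the target tissue.

    ``ref_input`` is the source-tissue reference (supplies mu_IR),
    ``ref_target`` the target-tissue reference (supplies mu_SR, min_SR,
    max_SR). ``stats_src`` defaults to the per-probe sd of ``source``.
    Control samples and out-of-region probes are returned unchanged.
    """
    cfg = cfg or SimulatorConfig()
    if stats_src is None:
        stats_src = SourceStats.from_beta(source)
    case = [str(s) for s in case_samples]
    missing = set(case) - set(source.sample_ids)
    if missing:
        raise ValidationError(f"case samples not in source: {sorted(missing)[:5]}")
    probes = sorted(regions.probe_ids)
    for name, frame in (
        ("source", source.beta),
        ("input reference", ref_input.profile),
        ("target reference", ref_target.profile),
        ("source stats", stats_src.sd_beta.to_frame()),
    ):
        miss = set(probes) - set(frame.index)
        if miss:
            raise ValidationError(f"region probes missing from {name}: {sorted(miss)[:5]}")

    lo = ref_target.min_beta.loc[probes].to_numpy(dtype=float)
    hi = ref_target.max_beta.loc[probes].to_numpy(dtype=float)
    if np.any(lo > hi):
        raise ValidationError("target reference has min_beta > max_beta")
    mu_sr = ref_target.mean_beta.loc[probes].to_numpy(dtype=float)
    mu_ir = ref_input.mean_beta.loc[probes].to_numpy(dtype=float)
    sigma = stats_src.sd_beta.loc[probes].to_numpy(dtype=float)

    rng = np.random.default_rng(cfg.seed)
    n_case = len(case)
    n_first = cfg.n_first_stage or max(n_case, 1)
    p = len(probes)

    # b: per-(probe, case sample) target-level draw, shape (p, n_case)
    if cfg.approach == "S1":
        b = np.broadcast_to(mu_sr[:, None], (p, n_case)).copy()
    elif cfg.approach == "S2":
        a_bar = _first_stage_average(cfg, lo, hi, n_first, rng)
        half = np.sqrt(3.0) * sigma
        b_lo = np.clip(a_bar - half, 0.0, 1.0)
        b_hi = np.clip(a_bar + half, 0.0, 1.0)
        b_hi = np.maximum(b_hi, b_lo + 1e-12)
        b = rng.uniform(b_lo[:, None], b_hi[:, None], size=(p, n_case))
    elif cfg.approach == "S3":
        center = (
            mu_sr
            if cfg.s3_mode == "equation"
            else _first_stage_average(cfg, lo, hi, n_first, rng)
        )
        b = rng.normal(center[:, None], sigma[:, None], size=(p, n_case))
    else:  # S4
        a_bar = _first_stage_average(cfg, lo, hi, n_first, rng)
        b = rng.normal(a_bar[:, None], sigma[:, None], size=(p, n_case))

    out = source.beta.copy()
    block = out.loc[probes, case].to_numpy(dtype=float)
    block = block - (mu_ir[:, None] - b)
    block = np.clip(block, cfg.clamp_eps, 1.0 - cfg.clamp_eps)
    out.loc[probes, case] = block

    meta = source.sample_meta.copy()
    if not len(meta):
        meta = pd.DataFrame(index=source.sample_ids.copy())
    meta["group"] = ["case" if s in set(case) else "control" for s in source.sample_ids]
    control = [s for s in source.sample_ids if s not in set(case)]

    result = SimulationResult(
        beta=BetaMatrix(out, meta),
        truth_regions=regions,
        truth_probes=set(probes),
        case_samples=case,
        control_samples=control,
    )
    result.region_effects = result.measured_region_effects()
    return result


# ---------------------------------------------------------------------------
# benchmark scenario grid


@dataclass(frozen=True)
class ScenarioConfig:
    """One benchmark context: size x target-tissue difference x threshold."""

    name: str
    size: str  # "small" | "large"
    target: str  # "A" (large tissue difference) | "B" (small difference)
    corr_threshold: float
    approach: str = "S4"
    seed: int = 0
    null: bool = False  # null twin: same split, no alteration


# Fixture tissue differences for the two simulated targets: target A
# plays the distant tissue (large mean shift), target B the close one.
TARGET_DELTAS = {"A": 0.4, "B": 0.15}
CORR_THRESHOLDS = (0.1, 0.2, 0.4)
BATCH_GRIDS = {"small": TABLE1_SMALL, "large": TABLE1_LARGE}


def _case_split(meta: pd.DataFrame) -> list[str]:
    """floor(count/2) cases per batch; controls keep the remainder."""
    cases: list[str] = []
    for _, sub in meta.groupby("batch", sort=True):
        if len(sub) < 2:
            raise ValidationError(f"batch with fewer than 2 samples: {len(sub)}")
        cases.extend(sub.index[: len(sub) // 2])
    return cases


def build_scenarios(
    seed: int = 0,
    approach: str = "S4",
    sizes: Sequence[str] = ("small", "large"),
    targets: Sequence[str] = ("A", "B"),
    corr_thresholds: Sequence[float] = CORR_THRESHOLDS,
    fixture_cfg: FixtureConfig | None = None,
    include_null: bool = True,
) -> list[tuple[ScenarioConfig, SimulationResult]]:
    """Materialize the benchmark grid from synthetic source batches.

    For each dataset size the five source batches are generated with the
    per-batch sample counts of the benchmark design (large: 204, 156,
    31, 17, 24 = 432 samples; small: 14, 6, 4, 4, 4 = 32). Candidate
    regions are clustered from the source data at each correlation
    threshold, the target reference is shifted by the target tissue's
    delta inside those regions, and half of every batch (rounded down)
    is simulated into the target tissue. Each scenario gets a null twin
    with the identical case/control split but no probe alteration.
    """
    base_cfg = replace(fixture_cfg or FixtureConfig(), seed=seed)
    # one manifest / planted-region layout shared by every scenario
    manifest = fixtures.make_manifest(base_cfg)
    planted = fixtures.make_truth_regions(base_cfg, manifest)
    out: list[tuple[ScenarioConfig, SimulationResult]] = []
    for si, size in enumerate(sizes):
        fcfg = replace(base_cfg, batch_sizes=BATCH_GRIDS[size], seed=seed + 1000 * si)
        source = fixtures.make_source_beta(fcfg, manifest, planted)
        cases = _case_split(source.sample_meta)
        scores_cache: dict[float, RegionSet] = {}
        for ti, (target, delta) in enumerate(
            (t, TARGET_DELTAS[t]) for t in targets
        ):
            ref_in, ref_tg = fixtures.make_reference_pair(
                replace(fcfg, delta=delta), manifest, planted
            )
            for ki, thr in enumerate(corr_thresholds):
                if thr not in scores_cache:
                    # cluster on the largest single batch: pooling batches
                    # would let shared batch shifts masquerade as
                    # co-methylation
                    biggest = source.sample_meta["batch"].value_counts().idxmax()
                    one_batch = source.subset_samples(
                        source.sample_meta.index[source.sample_meta["batch"] == biggest]
                    )
                    rcfg = RegionConfig(corr_threshold=thr)
                    scores = comethylation_scores(one_batch, manifest, rcfg)
                    scores_cache[thr] = candidate_regions(scores, manifest, rcfg)
                regs = scores_cache[thr]
                scen_seed = seed + 7919 * si + 104729 * ti + 1299709 * ki
                scfg = ScenarioConfig(
                    name=f"{size}-{target}-r{thr}",
                    size=size,
                    target=target,
                    corr_threshold=thr,
                    approach=approach,
                    seed=scen_seed,
                )
                sim = simulate(
                    source,
                    cases,
                    regs,
                    ref_in,
                    ref_tg,
                    cfg=SimulatorConfig(approach=approach, seed=scen_seed % (2**31)),
                )
                out.append((scfg, sim))
                if include_null:
                    null_beta = source.copy()
                    meta = null_beta.sample_meta
                    meta["group"] = [
                        "case" if s in set(cases) else "control" for s in null_beta.sample_ids
                    ]
                    null_sim = SimulationResult(
                        beta=BetaMatrix(null_beta.beta, meta),
                        truth_regions=RegionSet([]),
                        truth_probes=set(),
                        case_samples=list(cases),
                        control_samples=[s for s in null_beta.sample_ids if s not in set(cases)],
                    )
                    out.append((replace(scfg, name=scfg.name + "-null", null=True), null_sim))
    return out
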