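"""Deterministic synthetic inputs: manifest, signals, source beta, references.

Every external input the pipeline consumes — a 450k-style probe
manifest, raw M/U signal matrices with detection p-values, a multi-batch
source beta matrix with planted co-methylated regions, and a pair of
tissue reference profiles (min/mean/max beta per probe) — can be
generated here from a seed. Planted ground truth (region boundaries,
defective probes and samples, batch labels) is returned alongside the
data so downstream modules can be checked against construction.

The source matrix emulates pooled monocyte array batches: per-probe
baseline means are bimodal (most CpGs near 0 or 1), batch effects are
additive on the logit scale, and probes inside planted regions share a
per-region per-sample latent factor so that windowed correlation
clustering has signal to find.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import (
    BetaMatrix,
    Region,
    RegionSet,
    ReferenceProfile,
    SignalMatrix,
    ValidationError,
)

__all__ = [
    "FixtureConfig",
    "make_manifest",
    "make_truth_regions",
    "make_reference_pair",
    "make_source_beta",
    "make_signal_matrix",
    "write_fixture_set",
]

# Per-batch sample counts for the two benchmark sizes (five source batches).
TABLE1_LARGE = (204, 156, 31, 17, 24)
TABLE1_SMALL = (14, 6, 4, 4, 4)


@dataclass
class FixtureConfig:
    """Knobs for the synthetic-data generator.

    ``delta`` is the mean absolute beta shift between source and target
    reference means inside designated regions (the simulated tissue
    difference); ``comethylation`` is the shared-factor weight rho that
    sets the expected between-probe correlation inside a planted region.
    """

    n_probes: int = 2000
    n_chroms: int = 2
    mean_gap_bp: float = 500.0
    batch_sizes: tuple[int, ...] = TABLE1_SMALL
    design_ii_fraction: float = 0.7
    snp_fraction: float = 0.05
    nonspecific_fraction: float = 0.02
    region_size_range: tuple[int, int] = (5, 10)
    region_buffer_probes: int = 4
    max_regions: int = 60
    max_region_gap_bp: int = 702
    min_region_len_bp: int = 12
    delta: float = 0.3
    delta_sign: int = 1
    ref_bracket_width: float = 0.10
    sd_logit_range: tuple[float, float] = (0.10, 0.30)
    comethylation: float = 0.9
    batch_offset_logit_sd: float = 0.4
    batch_offsets: tuple[float, ...] | None = None
    signal_total_intensity: float = 6000.0
    beta_offset: float = 100.0
    n_bad_detection_probes: int = 0
    n_negative_intensity_probes: int = 0
    n_bad_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_chroms <= 0:
            raise ValidationError("counts must be positive")
        if not (0.0 <= self.delta <= 1.0):
            raise ValidationError("delta must lie in [0, 1]")
        if any(b <= 0 for b in self.batch_sizes):
            raise ValidationError("batch sizes must be positive")


def _rng(cfg: FixtureConfig, stream: int) -> np.random.Generator:
    # independent substream per generator so the makers can be called in
    # any order and still be reproducible
    return np.random.default_rng([cfg.seed, stream])


def make_manifest(cfg: FixtureConfig) -> pd.DataFrame:
    """Synthetic probe manifest sorted by (chrom, pos).

    Inter-probe gaps are exponential with the configured mean so a tail
    of gaps exceeds the 702 bp region-splitting threshold. Exactly
    ``round(snp_fraction * n)`` probes get an SNP allele frequency above
    5% and ``round(nonspecific_fraction * n)`` are flagged non-specific.
    """
    rng = _rng(cfg, 1)
    n = cfg.n_probes
    per_chrom = np.full(cfg.n_chroms, n // cfg.n_chroms)
    per_chrom[: n % cfg.n_chroms] += 1

    rows = []
    k = 0
    for ci, n_c in enumerate(per_chrom):
        gaps = np.maximum(2, rng.exponential(cfg.mean_gap_bp, size=n_c).astype(int))
        pos = 1000 + np.cumsum(gaps)
        for p in pos:
            rows.append((f"cg{k:07d}", f"chr{ci + 1}", int(p)))
            k += 1
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])

    df["design_type"] = np.where(rng.random(n) < cfg.design_ii_fraction, "II", "I")
    df["snp_af"] = np.nan
    n_snp = round(cfg.snp_fraction * n)
    snp_idx = rng.choice(n, size=n_snp, replace=False)
    df.loc[snp_idx, "snp_af"] = rng.uniform(0.06, 0.5, size=n_snp)
    df["nonspecific"] = False
    n_ns = round(cfg.nonspecific_fraction * n)
    pool = np.setdiff1d(np.arange(n), snp_idx)
    ns_idx = rng.choice(pool, size=min(n_ns, len(pool)), replace=False)
    df.loc[ns_idx, "nonspecific"] = True
    df["island_len_bp"] = rng.integers(12, 2000, size=n)
    return df.sort_values(["chrom", "pos"], kind="mergesort").set_index("probe_id")


def make_truth_regions(cfg: FixtureConfig, manifest: pd.DataFrame) -> RegionSet:
    """Plant co-methylated regions: blocks of consecutive probes whose
    internal gaps stay below the splitting threshold and whose span
    passes the minimum length filter, separated by buffer probes."""
    rng = _rng(cfg, 2)
    regions: list[Region] = []
    for chrom, sub in manifest.groupby(manifest["chrom"], sort=True):
        pos = sub["pos"].to_numpy()
        ids = sub.index.to_numpy()
        i = 0
        while i < len(pos) and len(regions) < cfg.max_regions:
            size = int(rng.integers(cfg.region_size_range[0], cfg.region_size_range[1] + 1))
            j = i + size
            if j > len(pos):
                break
            gaps = np.diff(pos[i:j])
            span = pos[j - 1] - pos[i] + 1
            if (gaps <= cfg.max_region_gap_bp).all() and span >= cfg.min_region_len_bp:
                regions.append(Region(chrom, int(pos[i]), int(pos[j - 1]), tuple(ids[i:j])))
                i = j + cfg.region_buffer_probes
            else:
                i += 1
    return RegionSet(regions)


def _probe_params(cfg: FixtureConfig, manifest: pd.DataFrame, regions: RegionSet):
    """Per-probe baseline mean and logit-scale sd, shared by the beta
    and reference generators. Region probes get mid-range means so a
    +/- delta shift stays inside (0, 1)."""
    rng = _rng(cfg, 3)
    n = len(manifest)
    u = rng.random(n)
    means = np.where(
        u < 0.4,
        rng.beta(2, 10, size=n),
        np.where(u < 0.8, rng.beta(10, 2, size=n), rng.beta(5, 5, size=n)),
    )
    in_region = manifest.index.isin(regions.probe_ids)
    lo, hi = (0.20, 0.60) if cfg.delta_sign >= 0 else (0.40, 0.80)
    means[in_region] = rng.uniform(lo, hi, size=in_region.sum())
    means = np.clip(means, 0.02, 0.98)
    sd_logit = rng.uniform(*cfg.sd_logit_range, size=n)
    return pd.Series(means, index=manifest.index), pd.Series(sd_logit, index=manifest.index)


def make_reference_pair(
    cfg: FixtureConfig, manifest: pd.DataFrame, regions: RegionSet
) -> tuple[ReferenceProfile, ReferenceProfile]:
    """Source and target tissue reference profiles.

    Target means differ from source by ~delta (with the configured sign)
    inside ``regions`` and are identical outside; min/max bracket the
    mean by ``ref_bracket_width`` on each side, clipped to (0, 1).
    """
    missing = regions.probe_ids - set(manifest.index)
    if missing:
        raise ValidationError(f"region probes not in manifest: {sorted(missing)[:5]}")
    means, _ = _probe_params(cfg, manifest, regions)

    def bracket(mean: pd.Series) -> pd.DataFrame:
        w = cfg.ref_bracket_width
        return pd.DataFrame(
            {
                "min_beta": np.clip(mean - w, 0.0, 1.0),
                "mean_beta": mean,
                "max_beta": np.clip(mean + w, 0.0, 1.0),
            },
            index=mean.index,
        )

    target_means = means.copy()
    in_region = manifest.index.isin(regions.probe_ids)
    target_means[in_region] = np.clip(
        means[in_region] + cfg.delta_sign * cfg.delta, 0.01, 0.99
    )
    source = ReferenceProfile("source", bracket(means))
    target = ReferenceProfile("target", bracket(target_means))
    return source, target


def make_source_beta(
    cfg: FixtureConfig, manifest: pd.DataFrame, regions: RegionSet | None = None
) -> BetaMatrix:
    """Multi-batch source beta matrix with planted co-methylation.

    On the logit scale each value is baseline + batch offset + noise;
    inside a planted region the noise mixes a shared per-region
    per-sample factor (weight rho = ``comethylation``) with independent
    noise, giving expected between-probe correlation rho.
    """
    if regions is None:
        regions = make_truth_regions(cfg, manifest)
    rng = _rng(cfg, 4)
    means, sd_logit = _probe_params(cfg, manifest, regions)
    n_probes = len(manifest)
    n_samples = int(sum(cfg.batch_sizes))

    if cfg.batch_offsets is not None:
        offsets = np.asarray(cfg.batch_offsets, dtype=float)
        if len(offsets) != len(cfg.batch_sizes):
            raise ValidationError("batch_offsets length must match batch_sizes")
    else:
        offsets = rng.normal(0.0, cfg.batch_offset_logit_sd, size=len(cfg.batch_sizes))

    batch_of_sample = np.repeat(np.arange(len(cfg.batch_sizes)), cfg.batch_sizes)
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    batch_labels = [f"batch{b + 1}" for b in batch_of_sample]

    rho = cfg.comethylation
    noise = rng.normal(size=(n_probes, n_samples))
    region_list = list(regions)
    if region_list and rho > 0:
        shared = rng.normal(size=(len(region_list), n_samples))
        pos_of = {p: i for i, p in enumerate(manifest.index)}
        for ri, reg in enumerate(region_list):
            rows = [pos_of[p] for p in reg.probes]
            noise[rows, :] = np.sqrt(rho) * shared[ri][None, :] + np.sqrt(1 - rho) * noise[rows, :]

    logit_base = logit(means.to_numpy())[:, None]
    vals = expit(logit_base + offsets[batch_of_sample][None, :] + sd_logit.to_numpy()[:, None] * noise)
    beta = pd.DataFrame(vals, index=manifest.index, columns=sample_ids)
    meta = pd.DataFrame({"batch": batch_labels}, index=pd.Index(sample_ids, name="sample_id"))
    return BetaMatrix(beta, meta)


def make_signal_matrix(cfg: FixtureConfig, manifest: pd.DataFrame) -> tuple[SignalMatrix, dict]:
    """M/U intensity matrices consistent with a planted beta.

    Intensities satisfy beta = M / (M + U + offset) exactly for the
    planted beta. Defects are planted on request: probes with a failed
    detection p-value, probes with a negative intensity, and dim samples
    whose log2 median intensity falls below 10 in both channels. Returns
    the signals plus a truth dict naming every planted defect.
    """
    rng = _rng(cfg, 5)
    n_probes, n_samples = len(manifest), int(sum(cfg.batch_sizes))
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]

    planted_beta = np.clip(rng.beta(2, 2, size=(n_probes, n_samples)), 0.02, 0.95)
    total = cfg.signal_total_intensity * rng.uniform(0.8, 1.2, size=(1, n_samples))
    M = planted_beta * (total + cfg.beta_offset)
    U = (1 - planted_beta) * (total + cfg.beta_offset) - cfg.beta_offset
    detp = rng.uniform(0.0, 0.01, size=(n_probes, n_samples))

    clean = np.setdiff1d(
        np.arange(n_probes),
        np.where(manifest["nonspecific"].to_numpy() | (manifest["snp_af"].to_numpy() > 0.05))[0],
    )
    picked = rng.choice(
        clean, size=cfg.n_bad_detection_probes + cfg.n_negative_intensity_probes, replace=False
    )
    bad_det = picked[: cfg.n_bad_detection_probes]
    bad_neg = picked[cfg.n_bad_detection_probes :]

    bad_samples = rng.choice(n_samples, size=cfg.n_bad_samples, replace=False)
    # plant per-probe defects only in good samples, so probe and sample
    # filters commute on this fixture
    good_samples = np.setdiff1d(np.arange(n_samples), bad_samples)
    for i in bad_det:
        detp[i, rng.choice(good_samples)] = 0.5
    for i in bad_neg:
        M[i, rng.choice(good_samples)] = -3.0
    for j in bad_samples:
        # log2(median) ~ 9 in both channels, below the threshold of 10
        scale = 512.0 / np.median(M[:, j])
        M[:, j] *= scale
        U[:, j] *= 512.0 / np.median(U[:, j])

    idx = manifest.index
    sig = SignalMatrix(
        pd.DataFrame(M, index=idx, columns=sample_ids),
        pd.DataFrame(U, index=idx, columns=sample_ids),
        pd.DataFrame(detp, index=idx, columns=sample_ids),
    )
    truth = {
        "bad_detection_probes": sorted(idx[bad_det]),
        "negative_intensity_probes": sorted(idx[bad_neg]),
        "snp_probes": sorted(idx[manifest["snp_af"].to_numpy() > 0.05]),
        "nonspecific_probes": sorted(idx[manifest["nonspecific"]]),
        "bad_samples": sorted(np.asarray(sample_ids)[bad_samples]),
    }
    return sig, truth


def write_fixture_set(cfg: FixtureConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize a complete fixture set on disk (CLI backend)."""
    from . import core

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = make_manifest(cfg)
    regions = make_truth_regions(cfg, manifest)
    ref_source, ref_target = make_reference_pair(cfg, manifest, regions)
    beta = make_source_beta(cfg, manifest, regions)
    sig, truth = make_signal_matrix(cfg, manifest)

    paths = {
        "manifest": outdir / "manifest.csv",
        "source_beta": outdir / "source_beta.tsv",
        "sample_meta": outdir / "samples.tsv",
        "signals_m": outdir / "signals_M.tsv",
        "signals_u": outdir / "signals_U.tsv",
        "signals_p": outdir / "signals_detp.tsv",
        "reference_source": outdir / "reference_source.csv",
        "reference_target": outdir / "reference_target.csv",
        "truth_regions": outdir / "truth_regions.bed",
        "truth_meta": outdir / "truth_meta.json",
    }
    core.write_manifest(manifest, paths["manifest"])
    core.write_beta_matrix(beta, paths["source_beta"], paths["sample_meta"])
    core.write_signal_matrix(sig, paths["signals_m"], paths["signals_u"], paths["signals_p"])
    core.write_reference_profile(ref_source, paths["reference_source"])
    core.write_reference_profile(ref_target, paths["reference_target"])
    core.write_regions_bed(regions, paths["truth_regions"])
    truth["config"] = asdict(cfg)
    paths["truth_meta"].write_text(json.dumps(truth, indent=2, default=str) + "\n")
    return paths
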