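"""Candidate co-methylated regions for DMR simulation.

Adjacent CpGs tend to be co-methylated, so candidate regions are runs of
neighbouring probes whose beta profiles correlate across samples. Each
probe is scored by its mean Pearson correlation with the probes inside a
centred genomic window (default size 3, i.e. the two flanking probes on
the same chromosome). Runs of probes whose score exceeds a threshold are
then split wherever two adjacent probes lie more than 702 bp apart (the
median HMM-island length) and runs spanning fewer than 12 bp (the
minimum HMM-island length) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BetaMatrix, Region, RegionSet, ValidationError

__all__ = ["RegionConfig", "comethylation_scores", "candidate_regions"]


@dataclass
class RegionConfig:
    window: int = 3
    corr_threshold: float = 0.2
    min_region_len_bp: int = 12
    max_adjacent_gap_bp: int = 702

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be odd and >= 3")
        if not (0 < self.corr_threshold < 1):
            raise ValidationError("corr_threshold must lie in (0, 1)")
        if self.min_region_len_bp <= 0 or self.max_adjacent_gap_bp <= 0:
            raise ValidationError("length thresholds must be positive")


def _sorted_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    return manifest.sort_values(["chrom", "pos"], kind="mergesort")


def comethylation_scores(
    beta: BetaMatrix, manifest: pd.DataFrame, cfg: RegionConfig | None = None
) -> pd.Series:
    """Mean Pearson correlation of each probe with its windowed neighbours.

    Probes are ordered by (chrom, pos); a probe's neighbours are the up
    to (window-1)/2 probes on each side on the same chromosome, so
    chromosome-terminal probes are scored from the neighbours they have.
    Zero-variance probes correlate with nothing and score 0.
    """
    cfg = cfg or RegionConfig()
    if beta.n_samples < 3:
        raise ValidationError("co-methylation scores need at least 3 samples")
    ann = _sorted_manifest(manifest.loc[beta.probe_ids])
    x = beta.beta.loc[ann.index].to_numpy(dtype=float)
    n = x.shape[0]
    half = (cfg.window - 1) // 2

    xm = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xm**2).sum(axis=1))
    chrom = ann["chrom"].to_numpy()

    acc = np.zeros(n)
    cnt = np.zeros(n)
    for k in range(1, half + 1):
        same = chrom[:-k] == chrom[k:]
        denom = norm[:-k] * norm[k:]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(denom > 0, (xm[:-k] * xm[k:]).sum(axis=1) / denom, 0.0)
        c = np.where(same, c, np.nan)
        valid = ~np.isnan(c)
        acc[:-k][valid] += c[valid]
        cnt[:-k][valid] += 1
        acc[k:][valid] += c[valid]
        cnt[k:][valid] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    return pd.Series(score, index=ann.index, name="comethylation")


def candidate_regions(
    scores: pd.Series, manifest: pd.DataFrame, cfg: RegionConfig | None = None
) -> RegionSet:
    """Runs of passing probes, split at large gaps, length-filtered.

    A probe passes when its score strictly exceeds ``corr_threshold``.
    Maximal runs of consecutive passing probes (per chromosome) are
    split wherever the gap between adjacent member probes exceeds
    ``max_adjacent_gap_bp``; a resulting run whose genomic span
    (end - start + 1) is below ``min_region_len_bp`` is dropped. A
    single-probe run spans 1 bp and can never pass the default filter.
    """
    cfg = cfg or RegionConfig()
    ann = _sorted_manifest(manifest.loc[scores.index])
    scores = scores.loc[ann.index]

    regions: list[Region] = []
    for chrom, sub in ann.groupby(ann["chrom"], sort=True):
        pos = sub["pos"].to_numpy()
        ids = sub.index.to_numpy()
        passing = scores.loc[sub.index].to_numpy() > cfg.corr_threshold

        run: list[int] = []
        for i in range(len(pos) + 1):
            split = i == len(pos) or not passing[i]
            if not split and run and pos[i] - pos[run[-1]] > cfg.max_adjacent_gap_bp:
                _flush(regions, chrom, pos, ids, run, cfg)
                run = []
            if split:
                _flush(regions, chrom, pos, ids, run, cfg)
                run = []
            else:
                run.append(i)
    return RegionSet(regions)


def _flush(regions: list[Region], chrom, pos, ids, run: list[int], cfg: RegionConfig) -> None:
    if not run:
        return
    start, end = int(pos[run[0]]), int(pos[run[-1]])
    if end - start + 1 >= cfg.min_region_len_bp:
        regions.append(Region(str(chrom), start, end, tuple(ids[run])))
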