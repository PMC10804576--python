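"""Probe/sample quality control and beta-value computation.

Probes are dropped when their detection p-value fails, when any
intensity is negative, when they sit on a common SNP (allele frequency
above 5%), or when they are flagged non-specific (multi-mapping).
Samples are dropped when dim in both channels: log2 of the median
intensity below 10 in M *and* U. Beta is then M / (M + U + offset) with
the platform-conventional offset of 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BetaMatrix, SignalMatrix, ValidationError

__all__ = ["QcConfig", "filter_probes", "filter_samples", "compute_beta"]


@dataclass
class QcConfig:
    detection_p_max: float = 0.05
    snp_af_max: float = 0.05
    log2_median_min: float = 10.0
    # fraction of samples allowed to fail detection before the probe is
    # dropped; 0 means any single failing sample excludes the probe
    detection_fail_fraction: float = 0.0
    beta_offset: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.detection_p_max <= 1 and 0 <= self.snp_af_max <= 1):
            raise ValidationError("p-value / allele-frequency thresholds must lie in [0, 1]")
        if not (0 <= self.detection_fail_fraction <= 1):
            raise ValidationError("detection_fail_fraction must lie in [0, 1]")
        if self.beta_offset < 0:
            raise ValidationError("beta_offset must be nonnegative")


def filter_probes(
    sig: SignalMatrix, manifest: pd.DataFrame, cfg: QcConfig | None = None
) -> tuple[SignalMatrix, dict[str, list[str]]]:
    """Drop failing probes; return the filtered signals and a removal log.

    The log maps each removed probe id to the list of reasons that
    applied: "detection", "negative_intensity", "snp", "nonspecific".
    """
    cfg = cfg or QcConfig()
    missing = sig.probe_ids.difference(manifest.index)
    if len(missing):
        raise ValidationError(f"probes missing annotation: {list(missing[:5])}")
    ann = manifest.loc[sig.probe_ids]

    n_samples = len(sig.sample_ids)
    fail_frac = (sig.detection_p.to_numpy() > cfg.detection_p_max).mean(axis=1)
    detection = fail_frac > cfg.detection_fail_fraction + 1e-12
    negative = ((sig.M.to_numpy() < 0) | (sig.U.to_numpy() < 0)).any(axis=1)
    snp = (ann["snp_af"].to_numpy(dtype=float) > cfg.snp_af_max) & ~np.isnan(
        ann["snp_af"].to_numpy(dtype=float)
    )
    nonspecific = ann["nonspecific"].to_numpy(dtype=bool)

    log: dict[str, list[str]] = {}
    reasons = {
        "detection": detection,
        "negative_intensity": negative,
        "snp": snp,
        "nonspecific": nonspecific,
    }
    for i, probe in enumerate(sig.probe_ids):
        hit = [name for name, mask in reasons.items() if mask[i]]
        if hit:
            log[probe] = hit
    keep = sig.probe_ids[~(detection | negative | snp | nonspecific)]
    return sig.subset(probes=keep), log


def filter_samples(
    sig: SignalMatrix, cfg: QcConfig | None = None
) -> tuple[SignalMatrix, dict[str, dict[str, float]]]:
    """Drop samples whose log2 median intensity is below the threshold in
    both channels; strict "less than", so a median of exactly 2**10 stays."""
    cfg = cfg or QcConfig()
    if sig.M.empty:
        raise ValidationError("signal matrix is empty")
    log2_m = np.log2(np.maximum(sig.M.median(axis=0).to_numpy(), 1e-12))
    log2_u = np.log2(np.maximum(sig.U.median(axis=0).to_numpy(), 1e-12))
    bad = (log2_m < cfg.log2_median_min) & (log2_u < cfg.log2_median_min)
    log = {
        str(s): {"log2_median_M": float(m), "log2_median_U": float(u)}
        for s, m, u, b in zip(sig.sample_ids, log2_m, log2_u, bad)
        if b
    }
    if bad.all():
        raise ValidationError("sample QC removed every sample")
    return sig.subset(samples=sig.sample_ids[~bad]), log


def compute_beta(sig: SignalMatrix, cfg: QcConfig | None = None) -> BetaMatrix:
    """beta = M / (M + U + offset), clipped into [0, 1].

    A zero denominator (possible only with offset 0 and empty signal)
    yields beta 0.
    """
    cfg = cfg or QcConfig()
    M = sig.M.to_numpy(dtype=float)
    U = sig.U.to_numpy(dtype=float)
    denom = M + U + cfg.beta_offset
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(denom > 0, M / np.where(denom == 0, 1.0, denom), 0.0)
    beta = np.clip(beta, 0.0, 1.0)
    return BetaMatrix(pd.DataFrame(beta, index=sig.probe_ids, columns=sig.sample_ids))
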