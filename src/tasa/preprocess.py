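"""Normalization and batch-effect correction for beta matrices.

Two quantile-normalization flavours are provided: plain between-array
quantile normalization of beta-values (BetaQN) and its probe-type
stratified variant (BAQN), where type I and type II probes — the two
Infinium chemistries, which have different intensity distributions — are
normalized separately. Normalizations are compared with four metrics:
the median per-probe standard deviation across samples (over all probes,
type I only, type II only) and dmrse, the standard error across samples
of the mean beta over a fixed set of imprinted-DMR probes (a quantity
that should be stable in healthy tissue, so smaller is better).

Batch correction is parametric empirical-Bayes location/scale
adjustment (ComBat): probes are standardized against a linear fit that
retains the biological group covariate, per-batch location and scale
estimates are shrunk toward their across-probe priors, and the data are
back-transformed with the batch terms removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import BetaMatrix, ValidationError

__all__ = [
    "NormReport",
    "quantile_normalize",
    "betaqn",
    "baqn",
    "norm_metrics",
    "batch_correct",
]


@dataclass
class NormReport:
    method: str
    median_probe_sd_all: float
    median_probe_sd_type1: float
    median_probe_sd_type2: float
    dmrse: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _qn_block(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of x to the mean-of-sorted reference."""
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # ties -> averaged rank
        out[:, j] = np.interp(ranks, grid, ref)
    return out


def quantile_normalize(beta: BetaMatrix, strata: pd.Series | None = None) -> BetaMatrix:
    """Between-array quantile normalization, optionally within probe strata.

    Within each stratum every sample's values are replaced by the
    reference distribution (the mean of the per-sample sorted values) at
    the sample's own ranks, so after normalization all samples share the
    stratum-wise distribution while each sample's rank order is kept.
    Strata with fewer than 2 probes are left unchanged with a warning.
    """
    if beta.n_samples < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    x = beta.beta.to_numpy(dtype=float).copy()
    if strata is None:
        x = _qn_block(x)
    else:
        strata = strata.reindex(beta.probe_ids)
        if strata.isna().any():
            raise ValidationError("every probe needs a stratum label")
        for label in strata.unique():
            rows = np.where((strata == label).to_numpy())[0]
            if len(rows) < 2:
                warnings.warn(f"stratum {label!r} has < 2 probes; left unchanged")
                continue
            x[rows, :] = _qn_block(x[rows, :])
    out = pd.DataFrame(x, index=beta.probe_ids, columns=beta.sample_ids)
    return BetaMatrix(out, beta.sample_meta.copy())


def betaqn(beta: BetaMatrix) -> BetaMatrix:
    """Unstratified between-array quantile normalization of beta-values."""
    return quantile_normalize(beta, None)


def baqn(beta: BetaMatrix, manifest: pd.DataFrame) -> BetaMatrix:
    """Quantile normalization stratified by Infinium design type (I/II)."""
    return quantile_normalize(beta, manifest.loc[beta.probe_ids, "design_type"])


def norm_metrics(
    beta: BetaMatrix,
    manifest: pd.DataFrame,
    idmr_probes: set[str] | list[str],
    method: str = "",
) -> NormReport:
    """The four normalization-evaluation metrics (all in beta units)."""
    sds = beta.beta.std(axis=1, ddof=1)
    design = manifest.loc[beta.probe_ids, "design_type"]
    idmr = [p for p in idmr_probes if p in beta.beta.index]
    dmrse: float | None
    if not idmr:
        warnings.warn("empty imprinted-DMR probe set; dmrse undefined")
        dmrse = None
    else:
        per_sample_mean = beta.beta.loc[idmr].mean(axis=0)
        dmrse = float(per_sample_mean.std(ddof=1) / np.sqrt(beta.n_samples))
    return NormReport(
        method=method,
        median_probe_sd_all=float(sds.median()),
        median_probe_sd_type1=float(sds[design == "I"].median()),
        median_probe_sd_type2=float(sds[design == "II"].median()),
        dmrse=dmrse,
    )


# ---------------------------------------------------------------------------
# ComBat


def _combat_it_sol(z: np.ndarray, g_hat, d_hat, g_bar, t2, a, b, tol=1e-4):
    """EB shrinkage iterations for one batch's location/scale."""
    n = (~np.isnan(z)).sum(axis=1)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > tol:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        ssq = np.nansum((z - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * ssq + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-30)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old + 1e-30)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def batch_correct(
    beta: BetaMatrix,
    batch: pd.Series | None = None,
    group: pd.Series | None = None,
) -> BetaMatrix:
    """Parametric empirical-Bayes batch adjustment on beta-values.

    ``batch`` / ``group`` default to the ``batch`` and ``group`` columns
    of the sample metadata. The group label is kept as a covariate so
    biological differences are not removed with the batch terms. Output
    is clipped into [0, 1] (the adjustment is unbounded but beta is not).
    """
    meta = beta.sample_meta
    if batch is None:
        if "batch" not in meta.columns:
            raise ValidationError("no batch labels supplied or in sample_meta")
        batch = meta["batch"]
    if group is None and "group" in meta.columns:
        group = meta["group"]
    batch = pd.Series(batch).reindex(beta.sample_ids)
    if batch.isna().any():
        raise ValidationError("every sample needs a batch label")
    batches = batch.unique().tolist()
    if len(batches) < 2:
        raise ValidationError("batch correction needs at least 2 batches")
    counts = batch.value_counts()
    if (counts < 2).any():
        raise ValidationError(f"batches with < 2 samples: {counts[counts < 2].index.tolist()}")

    n = len(batch)
    batch_design = pd.get_dummies(batch, dtype=float).loc[:, batches].to_numpy()
    covars = np.empty((n, 0))
    if group is not None:
        group = pd.Series(group).reindex(beta.sample_ids)
        tab = pd.crosstab(batch, group)
        if len(tab.columns) > 1 and ((tab > 0).sum(axis=1) == 1).any():
            raise ValidationError("batch confounded with group: a batch contains one group only")
        covars = pd.get_dummies(group, drop_first=True, dtype=float).to_numpy()

    x = beta.beta.to_numpy(dtype=float)
    design = np.hstack([batch_design, covars])
    # per-probe OLS fit of batch means + group covariates
    b_hat, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    n_batches = len(batches)
    batch_sizes = batch_design.sum(axis=0)
    grand_mean = (batch_sizes / n) @ b_hat[:n_batches]
    fitted_covar = covars @ b_hat[n_batches:] if covars.shape[1] else 0.0
    stand_mean = grand_mean[None, :] + fitted_covar  # samples x probes
    resid = x.T - design @ b_hat
    var_pooled = (resid**2).mean(axis=0)
    var_pooled = np.maximum(var_pooled, 1e-12)
    z = (x.T - stand_mean) / np.sqrt(var_pooled)[None, :]  # samples x probes

    adjusted = z.copy()
    for bi, blab in enumerate(batches):
        sel = (batch == blab).to_numpy()
        zb = z[sel].T  # probes x samples-in-batch
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, v = d_hat.mean(), d_hat.var(ddof=1)
        a_prior = (2 * v + m**2) / max(v, 1e-12)
        b_prior = (m * v + m**3) / max(v, 1e-12)
        g_star, d_star = _combat_it_sol(zb, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        adjusted[sel] = (zb.T - g_star[None, :]) / np.sqrt(np.maximum(d_star, 1e-12))[None, :]

    out = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean
    out = np.clip(out.T, 0.0, 1.0)
    return BetaMatrix(
        pd.DataFrame(out, index=beta.probe_ids, columns=beta.sample_ids),
        beta.sample_meta.copy(),
    )
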