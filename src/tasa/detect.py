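"""Internal DMP/DMR callers and file adapters for external tools.

The built-in caller is deliberately plain — a per-probe Welch t-test
with Benjamini-Hochberg correction, followed by adjacency merging of
significant probes into regions — so the benchmark can run end-to-end
without R. Published DMP/DMR tools plug in through a file contract:
beta/phenotype/manifest tables out, BED region calls back in.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    BetaMatrix,
    Region,
    RegionSet,
    ValidationError,
    read_regions_bed,
    write_manifest,
)

__all__ = ["dmp_ttest", "dmps_to_regions", "export_for_external", "read_external_regions"]


def dmp_ttest(
    beta: BetaMatrix,
    groups: pd.Series | None = None,
    case_label: str = "case",
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-probe Welch two-sample t-test with BH adjustment.

    Returns a frame indexed by probe with columns ``effect`` (mean beta
    case - control), ``p_value``, ``q_value``, ``significant`` (q <=
    ``q_max``) and ``zero_variance`` (both groups constant; p forced to
    1). ``groups`` defaults to the ``group`` metadata column.
    """
    if groups is None:
        if "group" not in beta.sample_meta.columns:
            raise ValidationError("no group labels supplied or in sample_meta")
        groups = beta.sample_meta["group"]
    groups = pd.Series(groups).reindex(beta.sample_ids)
    levels = groups.dropna().unique().tolist()
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 group levels, got {levels}")
    if case_label in levels:
        case = case_label
    else:
        case = sorted(levels)[-1]
    other = [l for l in levels if l != case][0]
    a = beta.beta.loc[:, (groups == case).to_numpy()].to_numpy(dtype=float)
    b = beta.beta.loc[:, (groups == other).to_numpy()].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("both groups need at least 2 samples")

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    _, q, *_ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "effect": a.mean(axis=1) - b.mean(axis=1),
            "p_value": p,
            "q_value": q,
            "significant": q <= q_max,
            "zero_variance": zero_var,
        },
        index=beta.probe_ids,
    )


def dmps_to_regions(
    dmps: pd.DataFrame,
    manifest: pd.DataFrame,
    max_gap_bp: int = 702,
    min_probes: int = 2,
) -> RegionSet:
    """Merge significant probes into regions by genomic adjacency.

    Significant probes on one chromosome are chained while consecutive
    calls are within ``max_gap_bp``; chains with fewer than
    ``min_probes`` members are dropped.
    """
    missing = dmps.index.difference(manifest.index)
    if len(missing):
        raise ValidationError(f"DMP probes missing annotation: {list(missing[:5])}")
    sig = dmps.index[dmps["significant"].to_numpy(dtype=bool)]
    ann = manifest.loc[sig].sort_values(["chrom", "pos"], kind="mergesort")

    regions: list[Region] = []
    for chrom, sub in ann.groupby(ann["chrom"], sort=True):
        pos = sub["pos"].to_numpy()
        ids = sub.index.to_numpy()
        run = [0] if len(pos) else []
        for i in range(1, len(pos) + 1):
            if i < len(pos) and pos[i] - pos[i - 1] <= max_gap_bp:
                run.append(i)
                continue
            if len(run) >= min_probes:
                regions.append(
                    Region(str(chrom), int(pos[run[0]]), int(pos[run[-1]]), tuple(ids[run]))
                )
            run = [i] if i < len(pos) else []
    return RegionSet(regions)


def export_for_external(beta: BetaMatrix, manifest: pd.DataFrame, outdir: str | Path) -> dict:
    """Write the file layout external DMP/DMR tool wrappers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "pheno": outdir / "pheno.tsv",
        "manifest": outdir / "manifest.csv",
    }
    beta.beta.to_csv(paths["beta"], sep="\t", index_label="probe_id")
    meta = beta.sample_meta
    if not len(meta):
        raise ValidationError("sample metadata (group labels) required for export")
    meta.to_csv(paths["pheno"], sep="\t", index_label="sample_id")
    write_manifest(manifest.loc[beta.probe_ids], paths["manifest"])
    return paths


def read_external_regions(path: str | Path) -> RegionSet:
    """Parse an external caller's BED output into a RegionSet."""
    return read_regions_bed(path)
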