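"""Shared domain types and tabular/interval I/O.

The package moves four kinds of data around: probe-level beta-value
matrices (probes x samples), raw two-channel signal-intensity matrices
with detection p-values, probe manifests (genomic annotation for each
array probe), and per-tissue reference profiles giving the minimum, mean
and maximum beta observed for every probe in a tissue. Genomic region
sets (runs of co-methylated probes) are stored 1-based closed internally
and exchanged as BED (0-based half-open).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BetaMatrix",
    "SignalMatrix",
    "ReferenceProfile",
    "SourceStats",
    "Region",
    "RegionSet",
    "EvalReport",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_manifest",
    "write_manifest",
    "read_reference_profile",
    "write_reference_profile",
    "read_regions_bed",
    "write_regions_bed",
]

MANIFEST_REQUIRED = ("probe_id", "chrom", "pos", "design_type")
MANIFEST_OPTIONAL = ("snp_af", "nonspecific", "island_len_bp")


class ValidationError(ValueError):
    """An input violated a structural or range invariant."""


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt", ".bed")) else ","


def _check_unique(labels: Iterable, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Probes x samples beta-values plus per-sample metadata.

    ``beta`` is indexed by probe id with sample ids as columns;
    ``sample_meta`` is indexed by sample id and typically carries
    ``batch`` and ``group`` columns.
    """

    beta: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "probe ids")
        _check_unique(self.beta.columns, "sample ids")
        vals = self.beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1) | ~np.isfinite(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0, 1] at probe {self.beta.index[i]!r}, "
                f"sample {self.beta.columns[j]!r}: {vals[i, j]}"
            )
        if len(self.sample_meta) and not self.sample_meta.index.equals(self.beta.columns):
            self.sample_meta = self.sample_meta.reindex(self.beta.columns)
            if self.sample_meta.isna().all(axis=1).any():
                missing = self.sample_meta.index[self.sample_meta.isna().all(axis=1)]
                raise ValidationError(f"samples missing metadata: {list(missing[:5])}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        meta = self.sample_meta.loc[list(sample_ids)] if len(self.sample_meta) else pd.DataFrame()
        return BetaMatrix(self.beta[list(sample_ids)], meta)

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.beta.copy(), self.sample_meta.copy())


@dataclass
class SignalMatrix:
    """Methylated/unmethylated intensities and detection p-values."""

    M: pd.DataFrame
    U: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (("U", self.U), ("detection_p", self.detection_p)):
            if df.shape != self.M.shape:
                raise ValidationError(f"{name} shape {df.shape} != M shape {self.M.shape}")
            if not (df.index.equals(self.M.index) and df.columns.equals(self.M.columns)):
                raise ValidationError(f"{name} axis labels differ from M")
        _check_unique(self.M.index, "probe ids")
        _check_unique(self.M.columns, "sample ids")
        p = self.detection_p.to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("detection p-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.M.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.M.columns

    def subset(self, probes=None, samples=None) -> "SignalMatrix":
        M, U, P = self.M, self.U, self.detection_p
        if probes is not None:
            M, U, P = M.loc[probes], U.loc[probes], P.loc[probes]
        if samples is not None:
            M, U, P = M[samples], U[samples], P[samples]
        return SignalMatrix(M, U, P)


@dataclass
class ReferenceProfile:
    """Per-probe min/mean/max beta for one named tissue.

    Emulates a Methbank-style tissue reference: for every probe the
    table stores the minimum, average and maximum beta-value seen for
    that tissue.
    """

    tissue: str
    profile: pd.DataFrame  # columns: min_beta, mean_beta, max_beta

    def __post_init__(self) -> None:
        need = {"min_beta", "mean_beta", "max_beta"}
        missing = need - set(self.profile.columns)
        if missing:
            raise ValidationError(f"reference profile missing columns: {sorted(missing)}")
        _check_unique(self.profile.index, "probe ids")
        p = self.profile
        if ((p < 0) | (p > 1)).to_numpy().any():
            raise ValidationError("reference betas must lie in [0, 1]")
        if (p["min_beta"] > p["mean_beta"]).any() or (p["mean_beta"] > p["max_beta"]).any():
            bad = p.index[(p["min_beta"] > p["mean_beta"]) | (p["mean_beta"] > p["max_beta"])]
            raise ValidationError(f"min <= mean <= max violated for probes {list(bad[:5])}")

    @property
    def mean_beta(self) -> pd.Series:
        return self.profile["mean_beta"]

    @property
    def min_beta(self) -> pd.Series:
        return self.profile["min_beta"]

    @property
    def max_beta(self) -> pd.Series:
        return self.profile["max_beta"]


@dataclass
class SourceStats:
    """Per-probe standard deviation of beta across source samples."""

    sd_beta: pd.Series

    def __post_init__(self) -> None:
        if (self.sd_beta < 0).any():
            raise ValidationError("sd_beta must be nonnegative")

    @classmethod
    def from_beta(cls, beta: BetaMatrix) -> "SourceStats":
        return cls(beta.beta.std(axis=1, ddof=1))


@dataclass(frozen=True)
class Region:
    """A run of probes on one chromosome, 1-based closed coordinates."""

    chrom: str
    start: int
    end: int
    probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"region start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValidationError("region start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_len(self, other: "Region") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class RegionSet:
    """Sorted, non-overlapping genomic regions with member probes."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start))
        for a, b in zip(self.regions, self.regions[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValidationError(
                    f"regions overlap: {a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
                )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    @property
    def probe_ids(self) -> set[str]:
        out: set[str] = set()
        for r in self.regions:
            out.update(r.probes)
        return out

    def chrom_styles(self) -> set[bool]:
        return {r.chrom.startswith("chr") for r in self.regions}


@dataclass
class EvalReport:
    """Confusion counts with derived rates; 0/0 rates are None, never 0."""

    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def _ratio(self, num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def precision(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    sensitivity = recall

    @property
    def specificity(self) -> float | None:
        if self.tn is None:
            return None
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float | None:
        if self.tn is None:
            return None
        total = self.tp + self.fp + self.fn + self.tn
        return self._ratio(self.tp + self.tn, total)

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "sensitivity": self.recall,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# readers / writers


def read_beta_matrix(path: str | Path, meta_path: str | Path | None = None) -> BetaMatrix:
    """Read a probes x samples beta matrix (TSV/CSV, row labels = probe ids).

    An optional sidecar table keyed by sample id supplies batch/group
    metadata. Values outside [0, 1] raise a :class:`ValidationError`
    naming the offending cell.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    meta = pd.DataFrame()
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep=_sep_for(meta_path), index_col=0)
        meta.index = meta.index.astype(str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df, meta)


def write_beta_matrix(bm: BetaMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    bm.beta.to_csv(path, sep=_sep_for(path), index_label="probe_id")
    if meta_path is not None and len(bm.sample_meta):
        bm.sample_meta.to_csv(meta_path, sep=_sep_for(meta_path), index_label="sample_id")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest CSV into a frame indexed by probe id.

    Mandatory columns: probe_id, chrom, pos (1-based), design_type
    (I/II). Optional: snp_af, nonspecific, island_len_bp. Rows come back
    sorted by (chrom, pos).
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing mandatory columns: {missing}")
    df["probe_id"] = df["probe_id"].astype(str)
    _check_unique(df["probe_id"], "probe ids")
    if (df["pos"] < 1).any():
        raise ValidationError("manifest positions must be >= 1 (1-based)")
    bad_design = set(df["design_type"].unique()) - {"I", "II"}
    if bad_design:
        raise ValidationError(f"unknown design types: {sorted(bad_design)}")
    for col in MANIFEST_OPTIONAL:
        if col not in df.columns:
            df[col] = False if col == "nonspecific" else np.nan
    df["nonspecific"] = df["nonspecific"].fillna(False).astype(bool)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").set_index("probe_id")
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep=_sep_for(path), index_label="probe_id")


def read_signal_matrix(m_path, u_path, p_path) -> SignalMatrix:
    frames = [pd.read_csv(p, sep=_sep_for(p), index_col=0) for p in (m_path, u_path, p_path)]
    for f in frames:
        f.index = f.index.astype(str)
        f.columns = f.columns.astype(str)
    return SignalMatrix(*frames)


def write_signal_matrix(sig: SignalMatrix, m_path, u_path, p_path) -> None:
    sig.M.to_csv(m_path, sep=_sep_for(m_path), index_label="probe_id")
    sig.U.to_csv(u_path, sep=_sep_for(u_path), index_label="probe_id")
    sig.detection_p.to_csv(p_path, sep=_sep_for(p_path), index_label="probe_id")


def read_reference_profile(path: str | Path, tissue: str | None = None) -> ReferenceProfile:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    name = tissue if tissue is not None else Path(path).stem
    return ReferenceProfile(name, df[["min_beta", "mean_beta", "max_beta"]])


def write_reference_profile(ref: ReferenceProfile, path: str | Path) -> None:
    ref.profile.to_csv(path, sep=_sep_for(path), index_label="probe_id")


def write_regions_bed(regions: RegionSet, path: str | Path) -> None:
    """Write regions as BED: chrom, start-1, end, probe ids joined by ','.

    Internal coordinates are 1-based closed; BED is 0-based half-open,
    so a region [100, 200] becomes the line ``chrom 99 200``.
    """
    with open(path, "w") as fh:
        for r in regions:
            name = ",".join(r.probes) if r.probes else "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def read_regions_bed(path: str | Path) -> RegionSet:
    """Read a BED file back into a 1-based closed RegionSet.

    Inverse of :func:`write_regions_bed`; also accepts 3-column BED
    from external DMR callers (no probe names).
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start0, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: non-integer coordinates") from exc
            probes: tuple[str, ...] = ()
            if len(parts) >= 4 and parts[3] not in (".", ""):
                probes = tuple(parts[3].split(","))
            regions.append(Region(parts[0], start0 + 1, end, probes))
    return RegionSet(regions)
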