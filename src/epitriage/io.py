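"""Reading, writing and QC of methylation-array matrices and their metadata.

The on-disk formats are plain delimited text: the beta matrix is a TSV with a
``probe_id`` first column and one column per sample; the probe manifest is a
TSV with columns ``probe_id, chrom, pos[, gene]``; region files are BED-like
TSVs with 1-based inclusive ``name, chrom, start, end`` columns (a documented
divergence from 0-based half-open BED); the sample sheet is a CSV.

beta values are methylation fractions in [0, 1].  M-values are the logit2
transform ``M = log2(beta / (1 - beta))``, computed with a clamping offset so
that boundary betas stay finite; M-values are the scale used for statistics,
betas the scale used for reporting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "Region",
    "QCReport",
    "read_manifest",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "read_regions",
    "qc_filter",
    "beta_to_m",
    "m_to_beta",
    "probes_in_region",
]

SEX_CHROMS = {"X", "Y"}


def _norm_chrom(c: object) -> str:
    return str(c).removeprefix("chr").upper()


@dataclass
class Region:
    """A named genomic interval, 1-based inclusive, optionally pinned to
    an explicit probe list (which then overrides the coordinates)."""

    name: str
    chrom: str = ""
    start: int = 0
    end: int = 0
    probe_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.probe_ids is None and self.start > self.end:
            raise ValueError(f"region {self.name!r}: start {self.start} > end {self.end}")


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions, with optional detection P-values."""

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("beta matrix contains missing values")
        if (arr < 0).any() or (arr > 1).any():
            r, c = np.argwhere((arr < 0) | (arr > 1))[0]
            raise ValueError(
                f"beta out of [0,1] at probe {v.index[r]!r}, sample {v.columns[c]!r}: {arr[r, c]}"
            )
        if self.detection_p is not None:
            self.detection_p = self.detection_p.reindex(index=v.index, columns=v.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, probes=None, samples=None) -> "BetaMatrix":
        v = self.values
        if probes is not None:
            v = v.loc[probes]
        if samples is not None:
            v = v[samples]
        p = None
        if self.detection_p is not None:
            p = self.detection_p.loc[v.index, v.columns]
        return BetaMatrix(values=v, detection_p=p)


@dataclass
class QCReport:
    """Audit trail of probe-level QC, reporting both detection-P dialects."""

    n_input: int
    n_removed_detection_any: int
    n_removed_sex: int
    n_retained: int
    n_flagged_cells: int = 0  # cells failing detection P (per-sample-mask dialect)
    removed_probes: list[str] = field(default_factory=list)


def read_manifest(path, sep: str = "\t") -> pd.DataFrame:
    """Read a probe manifest TSV (probe_id, chrom, pos[, gene]), indexed by probe_id."""
    man = pd.read_csv(path, sep=sep, dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos"}
    if missing := required - set(man.columns):
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if man["probe_id"].duplicated().any():
        raise ValueError("manifest contains duplicate probe ids")
    if (man["pos"] < 1).any():
        raise ValueError("manifest positions must be >= 1 (1-based)")
    if "gene" not in man.columns:
        man["gene"] = ""
    return man.set_index("probe_id")


def read_beta_matrix(path, manifest: pd.DataFrame | None = None, sep: str = "\t") -> BetaMatrix:
    """Read a delimited beta matrix; first column probe_id, header of sample ids.

    Malformed numeric cells raise with the offending row/column named.  Probes
    absent from the manifest are dropped with a warning listing the count.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    try:
        vals = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
            if bad.any():
                probe = raw.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"malformed numeric cell at probe {probe!r}, sample {col!r}: "
                    f"{raw.loc[probe, col]!r}"
                ) from None
        raise
    bad = (vals < 0) | (vals > 1)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"beta out of [0,1] at probe {vals.index[r]!r}, sample {vals.columns[c]!r}: "
            f"{vals.iat[r, c]}"
        )
    if manifest is not None:
        known = vals.index.isin(manifest.index)
        if not known.all():
            warnings.warn(
                f"{(~known).sum()} probes absent from manifest were dropped",
                stacklevel=2,
            )
            vals = vals.loc[known]
    return BetaMatrix(values=vals)


def write_beta_matrix(beta: BetaMatrix, path, sep: str = "\t", float_format: str = "%.6g") -> None:
    beta.values.to_csv(path, sep=sep, index_label="probe_id", float_format=float_format)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet CSV, indexed by sample_id."""
    sheet = pd.read_csv(path, dtype={"sample_id": str})
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample sheet contains duplicate sample ids")
    return sheet.set_index("sample_id")


def read_regions(path, sep: str = "\t") -> list[Region]:
    """Read a BED-like TSV of 1-based inclusive named regions."""
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str, "name": str})
    if df["name"].duplicated().any():
        raise ValueError("region names must be unique")
    return [
        Region(name=r["name"], chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]))
        for _, r in df.iterrows()
    ]


def qc_filter(beta: BetaMatrix, manifest: pd.DataFrame, p_cut: float = 0.05):
    """Remove failing probes: detection P > p_cut in ANY sample, or sex chromosomes.

    The any-sample removal dialect is the strictest reading of probe-level QC;
    the per-sample-mask alternative is quantified in the report
    (``n_flagged_cells``) so both dialects stay auditable.  Idempotent.

    Returns ``(filtered BetaMatrix, QCReport)``.
    """
    vals = beta.values
    man = manifest.reindex(vals.index)
    if man["chrom"].isna().any():
        missing = vals.index[man["chrom"].isna()].tolist()
        raise ValueError(f"probes absent from manifest: {missing[:5]}")
    on_sex = man["chrom"].map(_norm_chrom).isin(SEX_CHROMS).to_numpy()
    if beta.detection_p is not None:
        flagged = beta.detection_p.to_numpy(dtype=float) > p_cut
        fail_any = flagged.any(axis=1)
        n_cells = int(flagged.sum())
    else:
        fail_any = np.zeros(len(vals), dtype=bool)
        n_cells = 0
    drop = fail_any | on_sex
    kept = vals.loc[~drop]
    detp = beta.detection_p.loc[~drop] if beta.detection_p is not None else None
    report = QCReport(
        n_input=len(vals),
        n_removed_detection_any=int(fail_any.sum()),
        n_removed_sex=int((on_sex & ~fail_any).sum()),
        n_retained=len(kept),
        n_flagged_cells=n_cells,
        removed_probes=vals.index[drop].tolist(),
    )
    return BetaMatrix(values=kept, detection_p=detp), report


def beta_to_m(beta: BetaMatrix | pd.DataFrame, eps: float = 1e-6) -> pd.DataFrame:
    """logit2 transform, M = log2(b / (1 - b)), with b clamped to [eps, 1 - eps]."""
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    vals = beta.values if isinstance(beta, BetaMatrix) else beta
    b = np.clip(vals.to_numpy(dtype=float), eps, 1 - eps)
    return pd.DataFrame(np.log2(b / (1 - b)), index=vals.index, columns=vals.columns)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` (recovers the clamped beta)."""
    x = np.exp2(m.to_numpy(dtype=float))
    return pd.DataFrame(x / (1 + x), index=m.index, columns=m.columns)


def probes_in_region(manifest: pd.DataFrame, region: Region) -> list[str]:
    """Probes overlapping a 1-based inclusive region, ordered by position.

    If the region carries an explicit probe list, that list is returned
    verbatim.  An empty result warns rather than erroring.
    """
    if region.probe_ids is not None:
        return list(region.probe_ids)
    chrom = _norm_chrom(region.chrom)
    hit = (manifest["chrom"].map(_norm_chrom) == chrom) & manifest["pos"].between(
        region.start, region.end
    )
    sub = manifest.loc[hit].sort_values(["pos"], kind="mergesort")
    if sub.empty:
        warnings.warn(f"no probes in region {region.name!r}", stacklevel=2)
    return sub.index.tolist()
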