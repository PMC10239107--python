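"""Somatic-variant filtering, the VAF-window LOH caller, MLH1 second-hit
classification, MSI cutoffs and per-cluster gene-mutation enrichment.

Variant tables are MAF-like DataFrames with columns
``sample_id, chrom, pos, ref, alt, gene, filter_status, vaf_tumour,
vaf_germline, depth_tumour, consequence, origin``.

The LOH rule operates on germline-heterozygous sites (germline VAF in
[0.3, 0.7], inclusive): a site supports LOH when the tumour VAF has shifted
by more than 0.3 from the germline VAF *toward* homozygosity (toward 0 for
loss of the alternate allele, toward 1 for loss of the reference allele).
A window is called LOH when at least ``min_informative`` heterozygous sites
lie inside it and at least ``min_fraction`` of them support the shift.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import Region, _norm_chrom

__all__ = [
    "LOHCall",
    "filter_somatic",
    "germline_het",
    "loh_site",
    "region_loh",
    "second_hit",
    "msi_call",
    "mutation_matrix",
    "enrichment",
    "MSI_CUTOFFS",
]

VAF_MIN = 0.04  # minimum tumour VAF for a retained somatic call
DEPTH_MIN = 30  # minimum tumour coverage depth
HET_LOW, HET_HIGH = 0.3, 0.7  # inclusive germline heterozygosity window
LOH_SHIFT = 0.3  # strict: site supports LOH when the shift exceeds 0.3
_EPS = 1e-9  # guards the strict boundary against float noise (0.8 - 0.5 > 0.3)
MSI_CUTOFFS = {"WES": 0.245, "panel": 0.252}  # MSI-H iff score >= cutoff
MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")


@dataclass
class LOHCall:
    sample_id: str
    gene_or_region: str
    n_informative: int
    n_supporting: int
    loh: bool
    direction_summary: dict[str, int]


def filter_somatic(records: pd.DataFrame) -> pd.DataFrame:
    """Retain PASS somatic calls with VAF >= 0.04 and depth >= 30 (inclusive).

    Idempotent and order-preserving; germline-origin rows are untouched by
    the VAF filter but still must PASS.
    """
    somatic = records["origin"].eq("somatic") if "origin" in records else pd.Series(True, index=records.index)
    keep = (
        records["filter_status"].eq("PASS")
        & (records["vaf_tumour"] >= VAF_MIN)
        & (records["depth_tumour"] >= DEPTH_MIN)
    )
    return records[keep & somatic].copy()


def germline_het(vaf_germline: float) -> bool:
    """Heterozygous germline site: VAF within [0.3, 0.7], inclusive."""
    if not 0 <= vaf_germline <= 1:
        raise ValueError(f"VAF out of [0,1]: {vaf_germline}")
    return HET_LOW <= vaf_germline <= HET_HIGH

def loh_site(vaf_germline: float, vaf_tumour: float, require_direction: bool = True) -> bool:
    """Does a germline-het site support LOH in the tumour?

    True when |tumour VAF - germline VAF| > 0.3 (strict) and, by default, the
    shift points toward a homozygous state.  ``require_direction=False`` gives
    the pure-magnitude variant for comparison.  Calling this on a non-het
    site is an error.
    """
    if not germline_het(vaf_germline):
        raise ValueError(f"site is not germline-heterozygous (VAF {vaf_germline})")
    shift = vaf_tumour - vaf_germline
    if abs(shift) <= LOH_SHIFT + _EPS:
        return False
    if not require_direction:
        return True
    return (shift < 0 and vaf_tumour < vaf_germline) or (shift > 0 and vaf_tumour > vaf_germline)


def region_loh(
    records: pd.DataFrame,
    window: Region,
    sample_id: str | None = None,
    min_fraction: float = 0.5,
    min_informative: int = 2,
    require_direction: bool = True,
) -> LOHCall:
    """Aggregate site-level LOH evidence over a genomic window.

    Only germline-heterozygous sites inside the window are informative; the
    window is LOH when ``n_informative >= min_informative`` and the supporting
    fraction reaches ``min_fraction``.  Zero informative sites gives a
    non-informative (loh=False) call, never an error.
    """
    rec = records
    if sample_id is not None:
        rec = rec[rec["sample_id"] == sample_id]
    chrom = _norm_chrom(window.chrom)
    in_win = rec["chrom"].map(_norm_chrom).eq(chrom) & rec["pos"].between(window.start, window.end)
    sites = rec[in_win & rec["vaf_germline"].between(HET_LOW, HET_HIGH)]
    n_informative = len(sites)
    n_to_ref = n_to_alt = 0
    for _, row in sites.iterrows():
        if loh_site(row["vaf_germline"], row["vaf_tumour"], require_direction=require_direction):
            if row["vaf_tumour"] < row["vaf_germline"]:
                n_to_ref += 1
            else:
                n_to_alt += 1
    n_supporting = n_to_ref + n_to_alt
    loh = n_informative >= min_informative and n_supporting / max(n_informative, 1) >= min_fraction
    sid = sample_id if sample_id is not None else (rec["sample_id"].iloc[0] if len(rec) else "")
    return LOHCall(
        sample_id=str(sid),
        gene_or_region=window.name,
        n_informative=n_informative,
        n_supporting=n_supporting,
        loh=bool(loh),
        direction_summary={"to_hom_ref": n_to_ref, "to_hom_alt": n_to_alt},
    )


SECOND_HIT_CONSEQUENCES = (
    "missense",
    "stop_gained",
    "nonsense",
    "frameshift",
    "splice",
    "Ter",
    "fs",
)


def _is_damaging(consequence: str) -> bool:
    c = str(consequence)
    return any(tag.lower() in c.lower() for tag in SECOND_HIT_CONSEQUENCES)


def second_hit(mlh1_somatic: pd.DataFrame, loh: LOHCall) -> str:
    """Classify the tumour's second MLH1 hit: LOH, somatic_variant, both or none.

    ``mlh1_somatic`` holds the retained somatic records for one sample; a
    somatic-variant hit requires a truncating/splice/missense MLH1 record.
    """
    has_snv = bool(
        len(mlh1_somatic)
        and (
            mlh1_somatic["gene"].eq("MLH1")
            & mlh1_somatic["consequence"].map(_is_damaging)
        ).any()
    )
    has_loh = loh.loh
    if has_snv and has_loh:
        return "both"
    if has_loh:
        return "LOH"
    if has_snv:
        return "somatic_variant"
    return "none"


def msi_call(msi_score: float, platform: str) -> str:
    """MSI-H iff score >= 0.245 (WES) or >= 0.252 (panel), inclusive."""
    if platform not in MSI_CUTOFFS:
        raise ValueError(f"unknown platform {platform!r}; expected one of {sorted(MSI_CUTOFFS)}")
    return "MSI-H" if msi_score >= MSI_CUTOFFS[platform] else "MSS"


def mutation_matrix(
    records: pd.DataFrame,
    samples: list[str] | None = None,
    genes: list[str] | None = None,
):
    """Binary gene x sample indicator of >= 1 retained somatic mutation.

    Returns ``(matrix, tmb)`` where tmb counts all retained somatic records
    per sample (so tmb >= the matrix column sum restricted to panel genes).
    Genes absent from a platform's capture should be masked downstream, not
    treated as wild type.
    """
    retained = filter_somatic(records)
    if samples is None:
        samples = sorted(records["sample_id"].unique())
    tmb = retained.groupby("sample_id").size().reindex(samples, fill_value=0)
    tab = retained.groupby(["gene", "sample_id"]).size().unstack(fill_value=0)
    if genes is None:
        genes = sorted(tab.index)
    mat = (tab.reindex(index=genes, columns=samples, fill_value=0) > 0).astype(int)
    return mat, tmb


def fisher_2x2(a: int, b: int, c: int, d: int):
    """Two-sided Fisher exact P and Haldane-corrected odds ratio for a 2x2 table."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(p), float(odds)


def enrichment(matrix: pd.DataFrame, cluster_labels: pd.Series, cluster) -> pd.DataFrame:
    """Per-gene Fisher exact test of mutation status vs cluster membership.

    The 2x2 table per gene is (mutated/not) x (in-cluster/rest); P-values are
    two-sided, odds ratios Haldane-corrected when a cell is empty, and the
    result is sorted by P.  No multiplicity correction is applied (a raw
    P < 0.05 screen); at least two clusters must be present.
    """
    labels = cluster_labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("cluster_labels must cover every sample in the matrix")
    if labels.nunique() < 2:
        raise ValueError("need >= 2 clusters for an enrichment test")
    in_cluster = labels.eq(cluster).to_numpy()
    rows = []
    for gene, mut in matrix.iterrows():
        mvec = mut.to_numpy().astype(bool)
        a = int((mvec & in_cluster).sum())  # mutated, in cluster
        b = int((mvec & ~in_cluster).sum())  # mutated, rest
        c = int((~mvec & in_cluster).sum())
        d = int((~mvec & ~in_cluster).sum())
        p, odds = fisher_2x2(a, b, c, d)
        rows.append(
            {
                "gene": gene,
                "cluster": cluster,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "p_value": p,
                "direction": "enriched" if odds > 1 else "depleted",
            }
        )
    out = pd.DataFrame(rows).sort_values(["p_value", "gene"], kind="mergesort")
    return out.reset_index(drop=True)
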