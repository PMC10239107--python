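"""Per-case evidence gathering and subtype triage.

The triage cascade encodes the clinical subgroup definitions as an ordered,
auditable rule list over a named evidence block.  Constitutional evidence
outranks tumour-only evidence:

1. tumour MLH1 methylated + blood methylation > 10% + germline promoter
   cis-variant -> secondary_epimutation
2. as (1) without the cis-variant -> primary_epimutation
3. tumour methylated, blood <= 10%, and either a ddPCR-detected mosaic
   (> 1%) in a non-tumour tissue or at least two of {monoallelic tumour
   methylation, MLH1 second hit, epimutation-like cluster membership,
   APC promoter elevation} -> mosaic_epimutation_candidate
4. tumour methylated + CIMP-high or BRAF V600E + sporadic-like cluster +
   no MLH1 second hit -> sporadic_MLH1_methylated
5. MMR-deficient + germline MMR pathogenic variant, no tumour methylation
   -> lynch_like
6. MMR-deficient + two somatic MMR-gene hits, no methylation -> double_somatic
7. MMR-proficient, no methylation -> mmr_proficient
8. otherwise inconclusive

Contradictory evidence (a sporadic-like methylome with blood methylation
> 10%) short-circuits to inconclusive with a conflict report.  ``classify``
is a pure function of the evidence block; the rationale lists every rule that
fired, naming only evidence lines.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import registry, scores, somatic
from .ddpcr import DETECTION_PCT, AlleleReads, DropletCounts, MethylFraction, allelic_call, methyl_fraction
from .io import beta_to_m, qc_filter
from .clustering import assign_new_samples, consensus_cluster

__all__ = [
    "CaseBundle",
    "TriageReport",
    "gather_evidence",
    "classify",
    "run_cohort",
    "CLASSIFICATIONS",
    "TUMOUR_METHYLIGHT_PCT",
    "TUMOUR_MSHRM_PCT",
    "BLOOD_PCT",
]

TUMOUR_METHYLIGHT_PCT = 10.0  # tumour positive: MethyLight > 10% (strict)
TUMOUR_MSHRM_PCT = 5.0  # tumour positive: MS-HRM > 5% (strict)
BLOOD_PCT = 10.0  # full constitutional methylation: blood > 10%
APC_ELEVATED_BETA = 0.2

CLASSIFICATIONS = (
    "sporadic_MLH1_methylated",
    "primary_epimutation",
    "secondary_epimutation",
    "mosaic_epimutation_candidate",
    "lynch_like",
    "double_somatic",
    "mmr_proficient",
    "inconclusive",
)

EVIDENCE_KEYS = (
    "tumour_mlh1_methylated",
    "blood_methylation_pct",
    "germline_promoter_variant",
    "germline_mmr_pathogenic",
    "mmr_deficient",
    "cimp_high",
    "braf_v600e",
    "cluster",
    "epimutation_like_cluster",
    "sporadic_like_cluster",
    "mlh1_second_hit",
    "mosaic_ddpcr",
    "monoallelic_methylation",
    "apc_promoter_elevated",
    "msi_status",
    "n_somatic_mmr_hits",
)


@dataclass
class CaseBundle:
    """All per-case inputs the triage can consume; anything absent is None
    and surfaces as an "unknown" evidence line, never a silent default."""

    tumour_id: str
    tumour_beta: pd.Series | None = None  # beta per probe for the tumour sample
    methylight_tumour_pct: float | None = None
    mshrm_tumour_pct: float | None = None
    blood_beta: pd.Series | None = None
    blood_methylight_pct: float | None = None
    ddpcr: dict[str, MethylFraction] | None = None  # tissue -> quantification
    somatic_records: pd.DataFrame | None = None
    allele_reads: AlleleReads | None = None
    germline_promoter_variant: bool | None = None
    germline_mmr_pathogenic: bool | None = None
    mmr_deficient: bool | None = None
    msi_score: float | None = None
    platform: str | None = None


@dataclass
class TriageReport:
    sample_id: str
    classification: str
    evidence: dict
    rationale: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)


def _c_region_mean(beta: pd.Series) -> float | None:
    probes = registry.mlh1_c_region_probes()
    if not all(p in beta.index for p in probes):
        return None
    return float(beta.loc[probes].mean())


def gather_evidence(
    case: CaseBundle,
    manifest: pd.DataFrame | None = None,
    cluster_label=None,
    epimutation_cluster=None,
    sporadic_cluster=None,
) -> dict:
    """Compute the named evidence block for one case by delegating to the
    scoring, somatic and ddPCR modules.  Missing inputs yield None lines."""
    ev: dict = {k: None for k in EVIDENCE_KEYS}

    # tumour MLH1 methylation: array C-region if available, locus assays otherwise
    array_mean = _c_region_mean(case.tumour_beta) if case.tumour_beta is not None else None
    calls = []
    if array_mean is not None:
        calls.append(array_mean > scores.MLH1_POSITIVE_BETA)
    if case.methylight_tumour_pct is not None:
        calls.append(case.methylight_tumour_pct > TUMOUR_METHYLIGHT_PCT)
    if case.mshrm_tumour_pct is not None:
        calls.append(case.mshrm_tumour_pct > TUMOUR_MSHRM_PCT)
    ev["tumour_mlh1_methylated"] = any(calls) if calls else None

    # blood methylation on the percent scale (array beta x 100 or MethyLight)
    blood_vals = []
    if case.blood_beta is not None:
        bm = _c_region_mean(case.blood_beta)
        if bm is not None:
            blood_vals.append(100 * bm)
    if case.blood_methylight_pct is not None:
        blood_vals.append(case.blood_methylight_pct)
    ev["blood_methylation_pct"] = max(blood_vals) if blood_vals else None

    if case.tumour_beta is not None:
        try:
            ev["cimp_high"] = scores.cimp_call(case.tumour_beta.to_frame("s"), "s").status == "CIMP-high"
        except KeyError:
            pass
        if manifest is not None:
            apc = registry.region("APC_promoter")
            try:
                rm = scores.region_mean(
                    case.tumour_beta.to_frame("s"), manifest, apc, threshold=APC_ELEVATED_BETA
                )
                ev["apc_promoter_elevated"] = bool(rm.loc["s", "status"] == "positive")
            except ValueError:
                pass

    if case.somatic_records is not None and len(case.somatic_records):
        retained = somatic.filter_somatic(case.somatic_records)
        loh = somatic.region_loh(
            case.somatic_records, registry.region("MLH1_locus"), sample_id=case.tumour_id
        )
        ev["mlh1_second_hit"] = somatic.second_hit(retained[retained["gene"] == "MLH1"], loh)
        ev["braf_v600e"] = bool(
            (retained["gene"].eq("BRAF") & retained["consequence"].str.contains("V600E")).any()
        )
        ev["n_somatic_mmr_hits"] = int(retained["gene"].isin(somatic.MMR_GENES).sum())

    if case.ddpcr:
        ev["mosaic_ddpcr"] = any(m.detected for m in case.ddpcr.values())

    if case.allele_reads is not None:
        call = allelic_call(case.allele_reads)
        ev["monoallelic_methylation"] = (
            None if call == "indeterminate" else call.startswith("monoallelic")
        )

    if case.msi_score is not None and case.platform is not None:
        ev["msi_status"] = somatic.msi_call(case.msi_score, case.platform)

    ev["germline_promoter_variant"] = case.germline_promoter_variant
    ev["germline_mmr_pathogenic"] = case.germline_mmr_pathogenic
    ev["mmr_deficient"] = case.mmr_deficient
    ev["cluster"] = cluster_label
    if cluster_label is not None and epimutation_cluster is not None:
        ev["epimutation_like_cluster"] = cluster_label == epimutation_cluster
    if cluster_label is not None and sporadic_cluster is not None:
        ev["sporadic_like_cluster"] = cluster_label == sporadic_cluster
    return ev


def classify(evidence: dict, sample_id: str = "") -> TriageReport:
    """Apply the ordered triage cascade to an evidence block (pure function)."""
    ev = {k: evidence.get(k) for k in EVIDENCE_KEYS}
    rationale: list[str] = []
    conflicts: list[str] = []

    def t(key):  # evidence line is affirmatively true
        return ev[key] is True

    blood = ev["blood_methylation_pct"]
    blood_high = blood is not None and blood > BLOOD_PCT
    meth = t("tumour_mlh1_methylated")
    second = ev["mlh1_second_hit"] in ("LOH", "somatic_variant", "both")

    if t("sporadic_like_cluster") and blood_high:
        conflicts.append(
            "sporadic_like_cluster with blood_methylation_pct > 10 is contradictory"
        )
        return TriageReport(sample_id, "inconclusive", ev, rationale, conflicts)

    if meth and blood_high and t("germline_promoter_variant"):
        rationale.append(
            "tumour_mlh1_methylated, blood_methylation_pct > 10, germline_promoter_variant"
        )
        return TriageReport(sample_id, "secondary_epimutation", ev, rationale, conflicts)

    if meth and blood_high:
        rationale.append(
            "tumour_mlh1_methylated, blood_methylation_pct > 10, no germline_promoter_variant"
        )
        return TriageReport(sample_id, "primary_epimutation", ev, rationale, conflicts)

    if meth and not blood_high:
        mosaic_support = [
            k
            for k, v in (
                ("monoallelic_methylation", t("monoallelic_methylation")),
                ("mlh1_second_hit", second),
                ("epimutation_like_cluster", t("epimutation_like_cluster")),
                ("apc_promoter_elevated", t("apc_promoter_elevated")),
            )
            if v
        ]
        if t("mosaic_ddpcr"):
            rationale.append(
                f"tumour_mlh1_methylated, blood <= {BLOOD_PCT}%, mosaic_ddpcr > {DETECTION_PCT}%"
            )
            return TriageReport(
                sample_id, "mosaic_epimutation_candidate", ev, rationale, conflicts
            )
        if len(mosaic_support) >= 2:
            rationale.append(
                "tumour_mlh1_methylated, blood <= 10%, >=2 mosaic-support lines: "
                + ", ".join(mosaic_support)
            )
            return TriageReport(
                sample_id, "mosaic_epimutation_candidate", ev, rationale, conflicts
            )
        if (t("cimp_high") or t("braf_v600e")) and t("sporadic_like_cluster") and ev[
            "mlh1_second_hit"
        ] == "none":
            rationale.append(
                "tumour_mlh1_methylated, CIMP-high/BRAF-V600E, sporadic_like_cluster, "
                "no mlh1_second_hit"
            )
            return TriageReport(sample_id, "sporadic_MLH1_methylated", ev, rationale, conflicts)

    if not meth and t("mmr_deficient") and t("germline_mmr_pathogenic"):
        rationale.append("no tumour methylation, mmr_deficient, germline_mmr_pathogenic")
        return TriageReport(sample_id, "lynch_like", ev, rationale, conflicts)

    if (
        not meth
        and t("mmr_deficient")
        and ev["n_somatic_mmr_hits"] is not None
        and ev["n_somatic_mmr_hits"] >= 2
    ):
        rationale.append("no tumour methylation, mmr_deficient, >=2 somatic MMR-gene hits")
        return TriageReport(sample_id, "double_somatic", ev, rationale, conflicts)

    if ev["mmr_deficient"] is False and not meth:
        rationale.append("MMR-proficient, no tumour methylation")
        return TriageReport(sample_id, "mmr_proficient", ev, rationale, conflicts)

    rationale.append("no rule satisfied by the available evidence")
    return TriageReport(sample_id, "inconclusive", ev, rationale, conflicts)


def run_cohort(
    bundle,
    seed: int,
    k: int = 4,
    n_resamples: int = 300,
    vm_fraction: float = 0.10,
):
    """End-to-end triage of a cohort bundle.

    QC -> VM-probe selection on the reference tumours -> consensus clustering
    of the reference cohort at k -> assignment of unknown-subtype tumours by
    rerun-and-map -> per-case evidence and classification.

    Returns a dict with the per-sample reports plus the intermediate
    artefacts (selection, consensus result, assignments).
    """
    beta, qc_report = qc_filter(bundle.beta, bundle.manifest)
    sheet = bundle.sheet
    tumours = sheet.index[sheet["tissue"] == "tumour"].tolist()
    reference = [s for s in tumours if sheet.loc[s, "subtype_label"] != "unknown"]
    unknown = [s for s in tumours if s not in reference]

    sel = scores.select_variable_probes(beta.values[reference], fraction=vm_fraction)
    m_all = beta_to_m(beta.values.loc[sel.probe_ids, tumours])

    res = consensus_cluster(m_all[reference], [k], n_resamples=n_resamples, seed=seed)[k]
    # name the diagnostic clusters from the reference labels
    ref_subtype = sheet.loc[reference, "subtype_label"]
    epi_refs = ref_subtype.index[
        ref_subtype.isin(["primary_epimutation", "secondary_epimutation"])
    ]
    spo_refs = ref_subtype.index[ref_subtype == "sporadic_methylated"]
    epi_cluster = (
        int(res.assignments.loc[epi_refs].mode().iloc[0]) if len(epi_refs) else None
    )
    spo_cluster = (
        int(res.assignments.loc[spo_refs].mode().iloc[0]) if len(spo_refs) else None
    )

    labels = res.assignments.astype(object)
    assign_report = None
    if unknown:
        new_labels, assign_report = assign_new_samples(
            res, m_all, seed=seed + 1, n_resamples=n_resamples
        )
        labels = pd.concat([labels, new_labels])

    reports: dict[str, TriageReport] = {}
    for sid in tumours:
        case_row = bundle.cases.loc[sid] if sid in bundle.cases.index else None
        ddpcr_res = None
        if len(bundle.droplets):
            mine = bundle.droplets[bundle.droplets["sample_id"] == sid]
            if len(mine):
                ddpcr_res = {}
                for _, r in mine.iterrows():
                    counts = DropletCounts(
                        sample_id=sid,
                        tissue=r["tissue"],
                        n_pos_meth=int(r["n_pos_meth"]),
                        n_droplets_meth_channel=int(r["n_droplets_meth_channel"]),
                        n_pos_ref=int(r["n_pos_ref"]),
                        n_droplets_ref_channel=int(r["n_droplets_ref_channel"]),
                    )
                    ddpcr_res[r["tissue"]] = methyl_fraction(counts)
        reads = None
        if len(bundle.allele_reads):
            mine = bundle.allele_reads[bundle.allele_reads["sample_id"] == sid]
            if len(mine):
                r = mine.iloc[0]
                reads = AlleleReads(
                    sample_id=sid,
                    snp_id=str(r["snp_id"]),
                    count_allele_a=int(r["count_allele_a"]),
                    count_allele_b=int(r["count_allele_b"]),
                )
        recs = bundle.variants[bundle.variants["sample_id"] == sid]
        case = CaseBundle(
            tumour_id=sid,
            tumour_beta=beta.values[sid],
            methylight_tumour_pct=(
                float(case_row["methylight_tumour_pct"]) if case_row is not None else None
            ),
            mshrm_tumour_pct=(
                float(case_row["mshrm_tumour_pct"]) if case_row is not None else None
            ),
            blood_methylight_pct=(
                float(case_row["blood_methylight_pct"]) if case_row is not None else None
            ),
            ddpcr=ddpcr_res,
            somatic_records=recs if len(recs) else None,
            allele_reads=reads,
            germline_promoter_variant=(
                bool(case_row["germline_promoter_variant"]) if case_row is not None else None
            ),
            germline_mmr_pathogenic=(
                bool(case_row["germline_mmr_pathogenic"]) if case_row is not None else None
            ),
            mmr_deficient=bool(case_row["mmr_deficient"]) if case_row is not None else None,
            msi_score=float(case_row["msi_score"]) if case_row is not None else None,
            platform=str(case_row["platform"]) if case_row is not None else None,
        )
        ev = gather_evidence(
            case,
            manifest=bundle.manifest,
            cluster_label=labels.get(sid),
            epimutation_cluster=epi_cluster,
            sporadic_cluster=spo_cluster,
        )
        reports[sid] = classify(ev, sample_id=sid)

    return {
        "reports": reports,
        "qc": qc_report,
        "selection": sel,
        "consensus": res,
        "labels": labels,
        "epimutation_cluster": epi_cluster,
        "sporadic_cluster": spo_cluster,
        "assignment_report": assign_report,
    }


def reports_to_frame(reports: dict[str, TriageReport]) -> pd.DataFrame:
    rows = []
    for sid, rep in reports.items():
        row = {"sample_id": sid, "classification": rep.classification}
        row.update({k: rep.evidence.get(k) for k in EVIDENCE_KEYS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
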