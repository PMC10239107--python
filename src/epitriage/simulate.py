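"""Synthetic CRC cohort generator.

Generates cohorts carrying the statistical structure the analysis assumes,
with full ground truth, so every downstream stage is testable without any
external data:

* a beta matrix over background probes, planted variably-methylated (VM)
  probes with cluster-specific mean shifts, the MLH1 CpG island (including
  the four C-region probes), the five CIMP marker regions, a 16-probe APC
  promoter window, the LRRFIP2 singleton probe and a handful of sex-chromosome
  probes (QC fodder);
* tumour/germline variant tables with planted MLH1-window LOH segments,
  MLH1 second-hit point mutations and subtype-patterned driver mutations;
* droplet counts at known constitutional methylation fractions;
* methylated-epiallele allele read counts under mono-/bi-allelic methylation.

Per-probe betas are drawn from Beta(mu*kappa, (1-mu)*kappa), a mean/precision
parameterisation that keeps values inside [0, 1] without clipping artefacts;
the default precision kappa = 80 gives within-group SDs of roughly 0.05 at
mid-range means, matching the group SDs the scoring rules are designed for.

The default group sizes mirror a 38-tumour reference cohort (9 Lynch,
9 sporadic MLH1-methylated, 4 primary + 2 secondary epimutation, 5 double
somatic, 9 MMR-proficient) plus 6 diagnostically challenging tumours with a
mosaic-epimutation ground truth.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import registry
from .io import BetaMatrix, Region

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "CohortBundle",
    "generate_cohort",
    "plant_loh",
    "write_bundle",
    "read_bundle",
    "SUBTYPES",
]

SUBTYPES = (
    "lynch",
    "sporadic_methylated",
    "primary_epimutation",
    "secondary_epimutation",
    "double_somatic",
    "mmr_proficient",
    "challenging",
)

EXPECTED_CLASSIFICATION = {
    "lynch": "lynch_like",
    "sporadic_methylated": "sporadic_MLH1_methylated",
    "primary_epimutation": "primary_epimutation",
    "secondary_epimutation": "secondary_epimutation",
    "double_somatic": "double_somatic",
    "mmr_proficient": "mmr_proficient",
    "challenging": "mosaic_epimutation_candidate",
}

# somatic mutation probability per gene and subtype; "_default" covers the rest
GENE_PROBS: dict[str, dict[str, float]] = {
    "BRAF": {"sporadic_methylated": 1.0, "_default": 0.0},
    "RNF43": {"sporadic_methylated": 0.8, "_default": 0.15},
    "APC": {"sporadic_methylated": 0.15, "_default": 0.85},
    "KRAS": {"sporadic_methylated": 0.1, "mmr_proficient": 0.5, "double_somatic": 0.5, "_default": 0.7},
    "TCF7L2": {"sporadic_methylated": 0.1, "_default": 0.6},
    "KMT2C": {"sporadic_methylated": 0.1, "_default": 0.5},
    "ACVR2A": {"sporadic_methylated": 0.7, "_default": 0.1},
    "DCC": {"sporadic_methylated": 0.7, "_default": 0.1},
    "TCF7": {"sporadic_methylated": 0.7, "_default": 0.1},
    "B2M": {"sporadic_methylated": 0.7, "_default": 0.1},
    "LMO7": {"primary_epimutation": 0.6, "secondary_epimutation": 0.6, "challenging": 0.6, "_default": 0.05},
    "MYH9": {"primary_epimutation": 0.6, "secondary_epimutation": 0.6, "challenging": 0.6, "_default": 0.05},
    "FAN1": {"primary_epimutation": 0.6, "secondary_epimutation": 0.6, "challenging": 0.6, "_default": 0.05},
    "TET2": {"lynch": 0.6, "_default": 0.05},
    "BRCA2": {"lynch": 0.05, "mmr_proficient": 0.05, "double_somatic": 0.05, "_default": 0.4},
    "SETD2": {"lynch": 0.05, "mmr_proficient": 0.05, "double_somatic": 0.05, "_default": 0.4},
}

GENE_LOCI = {
    gene: ("7", 140_000_000 + 1_000_000 * i) for i, gene in enumerate(sorted(GENE_PROBS))
}
GENE_LOCI["MSH2"] = ("2", 47_630_000)

GENE_CONSEQUENCE = {"BRAF": "p.V600E (missense)", "KRAS": "p.G12D (missense)"}


def _means(default: float, **by_subtype: float) -> dict[str, float]:
    d = {s: default for s in SUBTYPES}
    d.update(by_subtype)
    return d


@dataclass
class CohortConfig:
    """Study-condition parameters of the generator (see module docstring)."""

    seed: int = 0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "lynch": 9,
            "sporadic_methylated": 9,
            "primary_epimutation": 4,
            "secondary_epimutation": 2,
            "double_somatic": 5,
            "mmr_proficient": 9,
            "challenging": 6,
        }
    )
    n_background_probes: int = 18000
    n_vm_probes: int = 2000
    n_sex_probes: int = 50
    kappa: float = 80.0
    # target mean beta per subtype for the scored regions
    mlh1_tumour_means: dict[str, float] = field(
        default_factory=lambda: _means(
            0.05,
            sporadic_methylated=0.55,
            primary_epimutation=0.77,
            secondary_epimutation=0.74,
            challenging=0.45,
        )
    )
    mlh1_constitutional_means: dict[str, float] = field(
        default_factory=lambda: _means(
            0.05, primary_epimutation=0.40, secondary_epimutation=0.39, challenging=0.06
        )
    )
    cimp_means: dict[str, float] = field(
        default_factory=lambda: _means(0.08, sporadic_methylated=0.45)
    )
    apc_means: dict[str, float] = field(
        default_factory=lambda: _means(
            0.19,
            lynch=0.33,
            sporadic_methylated=0.16,
            primary_epimutation=0.36,
            secondary_epimutation=0.36,
            double_somatic=0.20,
            challenging=0.45,
        )
    )
    lrrfip2_means: dict[str, float] = field(
        default_factory=lambda: _means(0.08, secondary_epimutation=0.5)
    )
    # VM-probe cluster structure: per-cluster overall mean and the block
    # elevation that separates the four clusters
    vm_cluster_means: dict[int, float] = field(
        default_factory=lambda: {1: 0.32, 2: 0.42, 3: 0.45, 4: 0.35}
    )
    vm_separation: float = 0.35
    # constitutional methylation fractions (percent) for ddPCR simulation
    mosaic_fractions: dict[str, float] = field(
        default_factory=lambda: {"blood": 4.5, "normal_mucosa": 2.3, "buccal": 6.5}
    )
    epimutation_constitutional_pct: float = 35.0
    n_droplets: int = 15000
    copies_per_droplet: float = 1.0
    purity: float = 0.8
    n_loh_sites: int = 6

    def validate(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        mean_dicts = [
            self.mlh1_tumour_means,
            self.mlh1_constitutional_means,
            self.cimp_means,
            self.apc_means,
            self.lrrfip2_means,
        ]
        for d in mean_dicts:
            for mu in d.values():
                if not 0 < mu < 1:
                    raise ValueError(f"target mean {mu} outside (0, 1)")
                if mu * self.kappa < 0.5 or (1 - mu) * self.kappa < 0.5:
                    raise ValueError(
                        f"infeasible mean {mu} for kappa={self.kappa}; increase kappa"
                    )


@dataclass
class CohortTruth:
    """Full ground truth for a generated cohort."""

    subtype: pd.Series  # tumour sample -> true subtype
    cluster: pd.Series  # tumour sample -> planted cluster (1..4)
    expected_classification: pd.Series
    second_hit: pd.Series  # tumour sample -> {"LOH","somatic_variant","none"}
    mosaic: pd.DataFrame  # sample_id, tissue, true_fraction_pct
    vm_probe_ids: list[str]
    region_targets: dict[str, dict[str, float]]


@dataclass
class CohortBundle:
    beta: BetaMatrix
    manifest: pd.DataFrame
    sheet: pd.DataFrame
    cases: pd.DataFrame
    variants: pd.DataFrame
    droplets: pd.DataFrame
    allele_reads: pd.DataFrame
    truth: CohortTruth
    config: CohortConfig


def _beta_draw(rng: np.random.Generator, mu: np.ndarray, kappa: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    return rng.beta(mu * kappa, (1 - mu) * kappa)


def _build_manifest(cfg: CohortConfig) -> pd.DataFrame:
    reg = registry.load_registry()
    rows: list[tuple[str, str, int, str]] = []
    for i in range(cfg.n_vm_probes):
        rows.append((f"vm_{i:05d}", "1", 1_000_000 + 1000 * i, ""))
    for i in range(cfg.n_background_probes):
        rows.append((f"bg_{i:05d}", "2", 1_000_000 + 500 * i, ""))
    for i in range(cfg.n_sex_probes):
        rows.append((f"sx_{i:04d}", "X", 1_000_000 + 1000 * i, ""))
    # MLH1 CpG island: the four C-region probes plus 38 flanking island probes
    island = reg["regions"]["MLH1_CpG_island"]
    c_probes = reg["mlh1_c_region_probes"]
    c_pos = [37_034_840, 37_034_850, 37_034_860, 37_034_870]
    for pid, pos in zip(c_probes, c_pos):
        rows.append((pid, island["chrom"], pos, "MLH1"))
    flank = np.linspace(island["start"], island["end"], 38).astype(int)
    for i, pos in enumerate(flank):
        rows.append((f"mlh1_isl_{i:02d}", island["chrom"], int(pos), "MLH1"))
    cimp_chrom = {"CACNA1G": "17", "RUNX3": "1", "SOCS1": "16", "NEUROG1": "5", "IGF2": "11"}
    for j, (gene, probes) in enumerate(reg["cimp_panel"].items()):
        for i, pid in enumerate(probes):
            rows.append((pid, cimp_chrom[gene], 50_000_000 + 10_000 * j + 100 * i, gene))
    apc = reg["regions"]["APC_promoter"]
    for i, pos in enumerate(np.linspace(apc["start"], apc["end"], 16).astype(int)):
        rows.append((f"apc_{i:02d}", apc["chrom"], int(pos), "APC"))
    lr = reg["regions"]["LRRFIP2_cg15103403"]
    rows.append(("cg15103403", lr["chrom"], lr["start"], "LRRFIP2"))
    man = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene"])
    return man.set_index("probe_id")


def plant_loh(
    window: Region,
    purity: float,
    rng: np.random.Generator,
    sample_id: str,
    n_sites: int = 6,
    loh: bool = True,
) -> pd.DataFrame:
    """Germline-het sites across a window, with or without a planted LOH segment.

    Heterozygous germline VAFs are drawn near 0.5 (truncated to [0.3, 0.7]).
    Under LOH each site's tumour VAF is displaced toward 0 or 1 by a fraction
    ``purity`` of the distance (so the site-level shift is about purity/2 and
    the >0.3 rule only fires for purity above ~0.6); otherwise the tumour VAF
    tracks the germline VAF.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    pos = np.linspace(window.start + 1000, window.end - 1000, n_sites).astype(int)
    vaf_g = np.clip(rng.normal(0.5, 0.02, n_sites), 0.3, 0.7)
    if loh:
        target = rng.integers(0, 2, n_sites).astype(float)  # lost allele per site
        vaf_t = vaf_g + purity * (target - vaf_g) + rng.normal(0, 0.01, n_sites)
    else:
        vaf_t = vaf_g + rng.normal(0, 0.02, n_sites)
    vaf_t = np.clip(vaf_t, 0.0, 0.999)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": window.chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "gene": "MLH1",
            "filter_status": "PASS",
            "vaf_tumour": vaf_t,
            "vaf_germline": vaf_g,
            "depth_tumour": rng.integers(80, 200, n_sites),
            "consequence": "intron",
            "origin": "germline",
        }
    )


def _somatic_record(sample_id, gene, rng, consequence=None):
    chrom, pos = GENE_LOCI.get(gene, ("9", 10_000_000))
    return {
        "sample_id": sample_id,
        "chrom": chrom,
        "pos": int(pos + rng.integers(0, 5000)),
        "ref": "C",
        "alt": "T",
        "gene": gene,
        "filter_status": "PASS",
        "vaf_tumour": float(rng.uniform(0.2, 0.45)),
        "vaf_germline": 0.0,
        "depth_tumour": int(rng.integers(60, 200)),
        "consequence": consequence or GENE_CONSEQUENCE.get(gene, "missense"),
        "origin": "somatic",
    }


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate a full cohort bundle (deterministic under ``config.seed``)."""
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    manifest = _build_manifest(cfg)
    reg = registry.load_registry()

    abbrev = {
        "lynch": "LS",
        "sporadic_methylated": "SP",
        "primary_epimutation": "PE",
        "secondary_epimutation": "SE",
        "double_somatic": "DS",
        "mmr_proficient": "MP",
        "challenging": "CH",
    }
    tumours: list[tuple[str, str, int]] = []  # (sample_id, subtype, index in group)
    for sub in SUBTYPES:
        for i in range(cfg.group_sizes.get(sub, 0)):
            tumours.append((f"{abbrev[sub]}{i:02d}_T", sub, i))

    # planted consensus-cluster structure: the first Lynch, double-somatic and
    # MMR-proficient tumours form a small fourth state (cluster 2), sporadic
    # tumours are cluster 3, epimutation-like tumours cluster 4, the rest 1
    cluster2 = {
        f"{abbrev[s]}00_T"
        for s in ("lynch", "double_somatic", "mmr_proficient")
        if cfg.group_sizes.get(s, 0) >= 2
    }

    def planted_cluster(sample_id: str, sub: str) -> int:
        if sample_id in cluster2:
            return 2
        if sub == "sporadic_methylated":
            return 3
        if sub in ("primary_epimutation", "secondary_epimutation", "challenging"):
            return 4
        return 1

    # normal mucosa companions for the constitutional-methylation groups
    normals: list[tuple[str, str]] = []
    for sub in ("primary_epimutation", "secondary_epimutation", "challenging"):
        if cfg.group_sizes.get(sub, 0):
            normals.append((f"{abbrev[sub]}00_N", sub))

    sample_ids = [t[0] for t in tumours] + [n[0] for n in normals]
    n_samples = len(sample_ids)
    subtype_of = {t[0]: t[1] for t in tumours} | {n[0]: n[1] for n in normals}
    is_tumour = {s: s.endswith("_T") for s in sample_ids}

    # --- target-mean matrix, probes x samples ----------------------------
    mu = np.empty((len(manifest), n_samples))
    probe_index = pd.Index(manifest.index)
    vm_ids = [p for p in probe_index if p.startswith("vm_")]
    vm_pos = probe_index.get_indexer(vm_ids)
    block = np.arange(len(vm_ids)) * 4 // max(len(vm_ids), 1) + 1  # blocks 1..4
    bg_ids = [p for p in probe_index if p.startswith("bg_")]
    bg_pos = probe_index.get_indexer(bg_ids)
    bg_base = rng.uniform(0.1, 0.9, len(bg_ids))
    bg_shift = {s: rng.normal(0.0, 0.01, len(bg_ids)) for s in SUBTYPES}
    sx_pos = probe_index.get_indexer([p for p in probe_index if p.startswith("sx_")])
    sx_base = rng.uniform(0.2, 0.8, len(sx_pos))
    island_ids = reg["mlh1_c_region_probes"] + [f"mlh1_isl_{i:02d}" for i in range(38)]
    island_pos = probe_index.get_indexer(island_ids)
    cimp_pos = {
        gene: probe_index.get_indexer(probes) for gene, probes in reg["cimp_panel"].items()
    }
    apc_pos = probe_index.get_indexer([f"apc_{i:02d}" for i in range(16)])
    lr_pos = probe_index.get_indexer(["cg15103403"])

    sep = cfg.vm_separation
    for j, s in enumerate(sample_ids):
        sub = subtype_of[s]
        col = np.empty(len(manifest))
        if is_tumour[s]:
            c = planted_cluster(s, sub)
            lo = cfg.vm_cluster_means[c] - sep / 4
            vm_mu = np.where(block == c, lo + sep, lo)
            mlh1_mu = cfg.mlh1_tumour_means[sub]
        else:
            vm_mu = np.full(len(vm_ids), 0.25)
            mlh1_mu = cfg.mlh1_constitutional_means[sub]
        col[vm_pos] = vm_mu
        col[bg_pos] = np.clip(bg_base + bg_shift[sub], 0.02, 0.98)
        col[sx_pos] = sx_base
        col[island_pos] = mlh1_mu
        for gene, posn in cimp_pos.items():
            col[posn] = cfg.cimp_means[sub] if is_tumour[s] else 0.08
        col[apc_pos] = cfg.apc_means[sub] if is_tumour[s] else 0.10
        col[lr_pos] = cfg.lrrfip2_means[sub] if is_tumour[s] else 0.08
        mu[:, j] = np.clip(col, 0.01, 0.99)

    values = _beta_draw(rng, mu, cfg.kappa)
    beta = BetaMatrix(values=pd.DataFrame(values, index=probe_index, columns=sample_ids))

    # --- sample sheet ----------------------------------------------------
    age_means = {
        "lynch": 39,
        "sporadic_methylated": 63,
        "primary_epimutation": 39,
        "secondary_epimutation": 40,
        "double_somatic": 45,
        "mmr_proficient": 39,
        "challenging": 45,
    }
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": ["tumour" if is_tumour[s] else "normal_mucosa" for s in sample_ids],
            "subtype_label": [
                "unknown" if subtype_of[s] == "challenging" else subtype_of[s]
                for s in sample_ids
            ],
            "age_dx": [
                float(np.round(rng.normal(age_means[subtype_of[s]], 8), 1)) for s in sample_ids
            ],
            "sex": rng.choice(["F", "M"], n_samples),
            "platform": "WES",
            "msi_score": [
                float(rng.uniform(0.05, 0.15))
                if subtype_of[s] == "mmr_proficient"
                else float(rng.uniform(0.30, 0.40))
                for s in sample_ids
            ],
        }
    ).set_index("sample_id")

    # --- variants: LOH windows, second hits, driver genes ----------------
    mlh1_window = registry.region("MLH1_locus")
    second_hit_plan: dict[str, str] = {}
    var_frames: list[pd.DataFrame] = []
    for sid, sub, i in tumours:
        if sub in ("lynch", "primary_epimutation", "secondary_epimutation", "challenging"):
            kind = "LOH" if i % 2 == 0 else "somatic_variant"
        else:
            kind = "none"
        second_hit_plan[sid] = kind
        var_frames.append(
            plant_loh(
                mlh1_window,
                cfg.purity,
                rng,
                sid,
                n_sites=cfg.n_loh_sites,
                loh=(kind == "LOH"),
            )
        )
        rows = []
        if kind == "somatic_variant":
            rows.append(
                _somatic_record(sid, "MLH1", rng, consequence="p.S131Ter (stop_gained)")
            )
        if sub == "double_somatic":
            rows.append(_somatic_record(sid, "MSH2", rng, consequence="p.R524Ter (stop_gained)"))
            rows.append(_somatic_record(sid, "MSH2", rng, consequence="missense"))
        for gene, probs in GENE_PROBS.items():
            if rng.random() < probs.get(sub, probs["_default"]):
                rows.append(_somatic_record(sid, gene, rng))
        # records that must fall to the somatic filters
        low = _somatic_record(sid, "GPR98", rng)
        low["vaf_tumour"] = 0.02
        rows.append(low)
        fail = _somatic_record(sid, "OBSCN", rng)
        fail["filter_status"] = "LowEVS"
        rows.append(fail)
        var_frames.append(pd.DataFrame(rows))
    variants = pd.concat(var_frames, ignore_index=True)

    # --- case-level measurements -----------------------------------------
    case_rows = []
    droplet_rows = []
    read_rows = []
    mosaic_truth = []
    for sid, sub, i in tumours:
        tum_mean = cfg.mlh1_tumour_means[sub]
        methylated = tum_mean > 0.2
        ml_t = float(np.clip(rng.normal(100 * tum_mean, 3), 0, 100)) if methylated else float(
            abs(rng.normal(0, 0.3))
        )
        hrm_t = float(np.clip(rng.normal(100 * tum_mean, 4), 0, 100)) if methylated else 0.0
        if sub in ("primary_epimutation", "secondary_epimutation"):
            blood_ml = float(np.clip(rng.normal(40, 5), 15, 90))
        elif sub == "challenging" and i in (1, 4):
            blood_ml = 1.0
        else:
            blood_ml = 0.0
        case_rows.append(
            {
                "sample_id": sid,
                "methylight_tumour_pct": ml_t,
                "mshrm_tumour_pct": hrm_t,
                "blood_methylight_pct": blood_ml,
                "germline_promoter_variant": bool(
                    sub == "secondary_epimutation" or (sub == "challenging" and i < 3)
                ),
                "germline_mmr_pathogenic": sub == "lynch",
                "mmr_deficient": sub != "mmr_proficient",
                "msi_score": float(sheet.loc[sid, "msi_score"]),
                "platform": "WES",
            }
        )
        # droplet counts for the constitutional-methylation workup
        if sub in ("primary_epimutation", "secondary_epimutation"):
            fractions = {
                "blood": cfg.epimutation_constitutional_pct,
                "normal_mucosa": cfg.epimutation_constitutional_pct,
            }
        elif sub == "challenging":
            fractions = (
                dict(cfg.mosaic_fractions)
                if i in (0, 1, 3)
                else {t: 0.0 for t in cfg.mosaic_fractions}
            )
        else:
            fractions = None
        if fractions:
            for tissue, pct in fractions.items():
                lam = cfg.copies_per_droplet
                lam_m = lam * pct / 100.0
                pos_m = int(rng.binomial(cfg.n_droplets, -np.expm1(-lam_m)))
                pos_r = int(rng.binomial(cfg.n_droplets, -np.expm1(-lam)))
                droplet_rows.append(
                    {
                        "sample_id": sid,
                        "tissue": tissue,
                        "n_pos_meth": pos_m,
                        "n_droplets_meth_channel": cfg.n_droplets,
                        "n_pos_ref": pos_r,
                        "n_droplets_ref_channel": cfg.n_droplets,
                    }
                )
                mosaic_truth.append({"sample_id": sid, "tissue": tissue, "true_fraction_pct": pct})
        # allele reads from the methylated-epiallele amplicon
        if sub in ("primary_epimutation", "secondary_epimutation", "challenging"):
            a = int(rng.binomial(200, 0.97))
            read_rows.append(
                {"sample_id": sid, "snp_id": "rs1800734", "count_allele_a": a, "count_allele_b": 200 - a}
            )
        elif sub == "sporadic_methylated":
            a = int(rng.binomial(200, 0.5))
            read_rows.append(
                {"sample_id": sid, "snp_id": "rs1800734", "count_allele_a": a, "count_allele_b": 200 - a}
            )

    cases = pd.DataFrame(case_rows).set_index("sample_id")
    droplets = pd.DataFrame(droplet_rows)
    allele_reads = pd.DataFrame(read_rows)

    tum_ids = [t[0] for t in tumours]
    truth = CohortTruth(
        subtype=pd.Series({t[0]: t[1] for t in tumours}, name="subtype"),
        cluster=pd.Series({t[0]: planted_cluster(t[0], t[1]) for t in tumours}, name="cluster"),
        expected_classification=pd.Series(
            {t[0]: EXPECTED_CLASSIFICATION[t[1]] for t in tumours}, name="classification"
        ),
        second_hit=pd.Series(second_hit_plan, name="second_hit").reindex(tum_ids),
        mosaic=pd.DataFrame(mosaic_truth),
        vm_probe_ids=vm_ids,
        region_targets={
            "mlh1_tumour": dict(cfg.mlh1_tumour_means),
            "mlh1_constitutional": dict(cfg.mlh1_constitutional_means),
            "cimp": dict(cfg.cimp_means),
            "apc": dict(cfg.apc_means),
        },
    )
    return CohortBundle(
        beta=beta,
        manifest=manifest,
        sheet=sheet,
        cases=cases,
        variants=variants,
        droplets=droplets,
        allele_reads=allele_reads,
        truth=truth,
        config=cfg,
    )


def write_bundle(bundle: CohortBundle, outdir) -> None:
    """Write a cohort bundle as plain delimited text plus a JSON truth file."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.beta.values.to_csv(out / "beta.tsv", sep="\t", index_label="probe_id")
    bundle.manifest.to_csv(out / "manifest.tsv", sep="\t", index_label="probe_id")
    bundle.sheet.to_csv(out / "sample_sheet.csv", index_label="sample_id")
    bundle.cases.to_csv(out / "cases.csv", index_label="sample_id")
    bundle.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    bundle.droplets.to_csv(out / "droplets.csv", index=False)
    bundle.allele_reads.to_csv(out / "allele_reads.csv", index=False)
    truth = {
        "subtype": bundle.truth.subtype.to_dict(),
        "cluster": {k: int(v) for k, v in bundle.truth.cluster.items()},
        "expected_classification": bundle.truth.expected_classification.to_dict(),
        "second_hit": bundle.truth.second_hit.to_dict(),
        "mosaic": bundle.truth.mosaic.to_dict(orient="records"),
        "vm_probe_ids": bundle.truth.vm_probe_ids,
        "region_targets": bundle.truth.region_targets,
        "config": {
            k: v for k, v in dataclasses.asdict(bundle.config).items()
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def read_bundle(indir) -> CohortBundle:
    """Read back a bundle written by :func:`write_bundle`."""
    from pathlib import Path

    from .io import read_beta_matrix, read_manifest, read_sample_sheet

    ind = Path(indir)
    manifest = read_manifest(ind / "manifest.tsv")
    beta = read_beta_matrix(ind / "beta.tsv", manifest)
    sheet = read_sample_sheet(ind / "sample_sheet.csv")
    cases = pd.read_csv(ind / "cases.csv").set_index("sample_id")
    variants = pd.read_csv(ind / "variants.tsv", sep="\t", dtype={"chrom": str})
    droplets = pd.read_csv(ind / "droplets.csv")
    allele_reads = pd.read_csv(ind / "allele_reads.csv")
    t = json.loads((ind / "truth.json").read_text())
    cfg_kwargs = t["config"]
    cfg_kwargs["vm_cluster_means"] = {int(k): v for k, v in cfg_kwargs["vm_cluster_means"].items()}
    truth = CohortTruth(
        subtype=pd.Series(t["subtype"], name="subtype"),
        cluster=pd.Series(t["cluster"], name="cluster"),
        expected_classification=pd.Series(t["expected_classification"], name="classification"),
        second_hit=pd.Series(t["second_hit"], name="second_hit"),
        mosaic=pd.DataFrame(t["mosaic"]),
        vm_probe_ids=t["vm_probe_ids"],
        region_targets=t["region_targets"],
    )
    return CohortBundle(
        beta=beta,
        manifest=manifest,
        sheet=sheet,
        cases=cases,
        variants=variants,
        droplets=droplets,
        allele_reads=allele_reads,
        truth=truth,
        config=CohortConfig(**cfg_kwargs),
    )
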