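"""Differential methylation: per-CpG statistics and region calling.

Per probe, a Welch two-sample t-test on M-values compares the two groups;
P-values are Benjamini–Hochberg adjusted across all tested probes and effect
sizes are reported as the group-mean beta difference (group2 - group1).

Regions are called with a seed-and-merge procedure: probes passing the FDR
cut seed regions, adjacent seeds within ``max_gap_bp`` on one chromosome
merge, and a region is kept when it spans at least ``min_cpgs`` probes and its
mean |delta beta| exceeds ``delta_cut``.  A combined region P-value comes from
Stouffer's method over the member probes' one-sided P-values oriented by the
region's direction of change:

    p_region = 1 - Phi( sum_i z_i / sqrt(m) ),   z_i = Phi^{-1}(1 - p_i)

This is deliberately a documented variant of kernel-smoothing region callers:
the filters (FDR, |delta beta|, gap, minimum CpGs) are explicit and the
combined P is exact under independence, at the cost of ignoring spatial
correlation between neighbouring probes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["DMR", "probe_stats", "call_dmrs", "stouffer_p"]


@dataclass
class DMR:
    chrom: str
    start: int
    end: int  # 1-based inclusive
    n_cpgs: int
    mean_delta_beta: float
    stouffer_p: float
    direction: str  # "hyper_in_group1" | "hyper_in_group2"
    probe_ids: list[str]


def probe_stats(
    m: pd.DataFrame,
    beta: pd.DataFrame,
    group_labels: pd.Series,
    group1: str,
    group2: str,
    manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-probe Welch t statistics (group2 vs group1) on M-values.

    Returns a DataFrame with columns ``t_stat, p_value, fdr_q, delta_beta``
    (delta on the beta scale, group2 - group1) plus ``chrom, pos`` when a
    manifest is supplied, sorted by genomic position in that case.
    """
    s1 = group_labels.index[group_labels == group1]
    s2 = group_labels.index[group_labels == group2]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"need >= 2 samples per group (got {len(s1)} vs {len(s2)})")
    m1, m2 = m[s1].to_numpy(float), m[s2].to_numpy(float)
    t, p = stats.ttest_ind(m2, m1, axis=1, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    delta = beta[s2].mean(axis=1) - beta[s1].mean(axis=1)
    out = pd.DataFrame(
        {"t_stat": t, "p_value": p, "fdr_q": q, "delta_beta": delta.to_numpy(float)},
        index=m.index,
    )
    out.index.name = "probe_id"
    if manifest is not None:
        out["chrom"] = manifest.reindex(out.index)["chrom"]
        out["pos"] = manifest.reindex(out.index)["pos"].astype(int)
        out = out.sort_values(["chrom", "pos"], kind="mergesort")
    return out


def stouffer_p(one_sided_p: np.ndarray) -> float:
    """Stouffer combination of one-sided P-values: 1 - Phi(sum z / sqrt(m))."""
    z = stats.norm.isf(np.asarray(one_sided_p, dtype=float))
    return float(stats.norm.sf(z.sum() / np.sqrt(len(z))))


def call_dmrs(
    stats_df: pd.DataFrame,
    max_gap_bp: int = 1000,
    min_cpgs: int = 2,
    fdr_cut: float = 0.01,
    delta_cut: float = 0.2,
) -> list[DMR]:
    """Merge FDR-significant probes into differentially methylated regions.

    ``stats_df`` must carry ``chrom, pos, fdr_q, delta_beta, t_stat, p_value``
    and be sorted by (chrom, pos); unsorted input raises.  Emitted regions
    satisfy ``n_cpgs >= min_cpgs`` and ``|mean delta beta| > delta_cut``.
    """
    required = {"chrom", "pos", "fdr_q", "delta_beta", "t_stat", "p_value"}
    if missing := required - set(stats_df.columns):
        raise ValueError(f"stats missing columns: {sorted(missing)}")
    for _, grp in stats_df.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("stats must be sorted by (chrom, pos)")

    seeds = stats_df[stats_df["fdr_q"] < fdr_cut]
    dmrs: list[DMR] = []
    for chrom, grp in seeds.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > max_gap_bp)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            block = grp.iloc[a : b + 1]
            if len(block) < min_cpgs:
                continue
            mean_delta = float(block["delta_beta"].mean())
            if abs(mean_delta) <= delta_cut:
                continue
            sign = 1.0 if mean_delta > 0 else -1.0
            # one-sided member P in the region's direction, halved from the
            # two-sided Welch P (t is group2 - group1)
            t_vals = block["t_stat"].to_numpy(float)
            p_two = block["p_value"].to_numpy(float)
            p_one = np.where(sign * t_vals >= 0, p_two / 2, 1 - p_two / 2)
            dmrs.append(
                DMR(
                    chrom=str(chrom),
                    start=int(block["pos"].min()),
                    end=int(block["pos"].max()),
                    n_cpgs=len(block),
                    mean_delta_beta=mean_delta,
                    stouffer_p=stouffer_p(p_one),
                    direction="hyper_in_group2" if sign > 0 else "hyper_in_group1",
                    probe_ids=block.index.tolist(),
                )
            )
    return dmrs


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Tabulate DMRs as 1-based inclusive intervals."""
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "n_cpgs": d.n_cpgs,
                "mean_delta_beta": d.mean_delta_beta,
                "stouffer_p": d.stouffer_p,
                "direction": d.direction,
            }
            for d in dmrs
        ]
    )
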