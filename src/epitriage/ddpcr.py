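"""Droplet digital PCR quantification of low-level MLH1 promoter methylation.

A droplet is positive when it received at least one target copy, so under
random partitioning the mean copies per droplet follows the limiting-dilution
(Poisson) correction

    lambda = -ln(1 - n_pos / n_total).

The methylated fraction is ``lambda_meth / (lambda_meth + lambda_unmeth)``.
Two assay conventions are supported: ``total_ref`` (default), where the
reference channel measures total bisulphite-converted copies so
``lambda_unmeth = lambda_ref - lambda_meth``; and ``two_channel``, where the
reference channel independently measures unmethylated copies.  Mosaic
methylation is called detected when the point estimate exceeds 1% (strict)
and the confidence interval excludes zero.

Allele-level calls from methylated-epiallele amplicon reads distinguish
monoallelic (one allele >= 90% of reads) from biallelic (both alleles near
parity) methylation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DropletCounts",
    "MethylFraction",
    "AlleleReads",
    "poisson_lambda",
    "methyl_fraction",
    "allelic_call",
    "simulate_droplets",
    "DETECTION_PCT",
]

DETECTION_PCT = 1.0  # detected iff fraction > 1% (strict) with CI excluding 0


@dataclass
class DropletCounts:
    sample_id: str
    tissue: str
    n_pos_meth: int
    n_droplets_meth_channel: int
    n_pos_ref: int
    n_droplets_ref_channel: int

    def __post_init__(self) -> None:
        for pos, tot in (
            (self.n_pos_meth, self.n_droplets_meth_channel),
            (self.n_pos_ref, self.n_droplets_ref_channel),
        ):
            if tot <= 0:
                raise ValueError("droplet totals must be positive")
            if not 0 <= pos <= tot:
                raise ValueError(f"positives {pos} outside 0..{tot}")


@dataclass
class MethylFraction:
    sample_id: str
    tissue: str
    lambda_meth: float
    lambda_ref: float
    fraction_pct: float  # 100 * lambda_meth / (lambda_meth + lambda_unmeth)
    ci_low: float
    ci_high: float
    detected: bool
    quantifiable: bool = True
    mode: str = "total_ref"


@dataclass
class AlleleReads:
    sample_id: str
    snp_id: str
    count_allele_a: int
    count_allele_b: int

    def __post_init__(self) -> None:
        if self.count_allele_a < 0 or self.count_allele_b < 0:
            raise ValueError("allele counts must be non-negative")


def poisson_lambda(n_pos: int, n_total: int) -> float:
    """Mean target copies per droplet from the positive-droplet fraction."""
    if not 0 <= n_pos <= n_total or n_total <= 0:
        raise ValueError(f"invalid droplet counts ({n_pos}/{n_total})")
    if n_pos == n_total:
        raise ValueError("all droplets positive: saturated assay, lambda undefined")
    return -math.log1p(-n_pos / n_total)


def _lambda_var(n_pos: int, n_total: int) -> float:
    """Delta-method variance of the lambda estimate."""
    p = n_pos / n_total
    return p / (n_total * (1 - p))  # var(p_hat) / (1 - p)^2 with var = p(1-p)/n


def methyl_fraction(
    counts: DropletCounts,
    threshold_pct: float = DETECTION_PCT,
    mode: str = "total_ref",
    ci_method: str = "delta",
    n_boot: int = 2000,
    seed: int | None = None,
    conf: float = 0.95,
) -> MethylFraction:
    """Estimate the percent methylation with a 95% CI and a detection call.

    ``ci_method`` is ``"delta"`` (log-scale normal propagation, default) or
    ``"bootstrap"`` (droplet resampling, seeded).  Zero reference-channel
    positives makes the fraction non-quantifiable.
    """
    lam_m = poisson_lambda(counts.n_pos_meth, counts.n_droplets_meth_channel)
    lam_r = poisson_lambda(counts.n_pos_ref, counts.n_droplets_ref_channel)
    if counts.n_pos_ref == 0:
        return MethylFraction(
            counts.sample_id, counts.tissue, lam_m, lam_r,
            fraction_pct=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            detected=False, quantifiable=False, mode=mode,
        )

    def _fraction(lm: float, lr: float) -> float:
        denom = lr if mode == "total_ref" else lm + lr
        if mode not in ("total_ref", "two_channel"):
            raise ValueError(f"unknown mode {mode!r}")
        if denom <= 0:
            return 0.0
        return float(np.clip(100.0 * lm / denom, 0.0, 100.0))

    frac = _fraction(lam_m, lam_r)
    zq = stats.norm.ppf(0.5 + conf / 2)
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        bm = rng.binomial(counts.n_droplets_meth_channel,
                          counts.n_pos_meth / counts.n_droplets_meth_channel, size=n_boot)
        br = rng.binomial(counts.n_droplets_ref_channel,
                          counts.n_pos_ref / counts.n_droplets_ref_channel, size=n_boot)
        bm = np.minimum(bm, counts.n_droplets_meth_channel - 1)
        br = np.minimum(br, counts.n_droplets_ref_channel - 1)
        lm = -np.log1p(-bm / counts.n_droplets_meth_channel)
        lr = -np.log1p(-br / counts.n_droplets_ref_channel)
        fr = np.array([_fraction(a, b) for a, b in zip(lm, lr)])
        lo, hi = np.quantile(fr, [(1 - conf) / 2, 0.5 + conf / 2])
    elif ci_method == "delta":
        if counts.n_pos_meth == 0:
            # one-sided exact bound on the methylated channel
            p_up = 1 - ((1 - conf) / 2) ** (1 / counts.n_droplets_meth_channel)
            lo, hi = 0.0, _fraction(-math.log1p(-p_up), lam_r)
        else:
            var_log = _lambda_var(counts.n_pos_meth, counts.n_droplets_meth_channel) / lam_m**2
            var_log += _lambda_var(counts.n_pos_ref, counts.n_droplets_ref_channel) / lam_r**2
            half = zq * math.sqrt(var_log)
            lo = float(np.clip(frac * math.exp(-half), 0, 100))
            hi = float(np.clip(frac * math.exp(half), 0, 100))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    detected = bool(frac > threshold_pct and lo > 0)
    return MethylFraction(
        counts.sample_id, counts.tissue, lam_m, lam_r,
        fraction_pct=frac, ci_low=float(lo), ci_high=float(hi),
        detected=detected, quantifiable=True, mode=mode,
    )


def allelic_call(
    reads: AlleleReads,
    min_total: int = 50,
    mono_cut: float = 0.9,
    bi_cut: float = 0.65,
) -> str:
    """Mono- vs bi-allelic methylation from methylated-epiallele reads.

    monoallelic_A/B when that allele carries >= ``mono_cut`` of reads;
    biallelic when both allele fractions lie within [1 - bi_cut, bi_cut]
    (near-parity); anything between the bands, or a total below
    ``min_total``, is indeterminate.
    """
    total = reads.count_allele_a + reads.count_allele_b
    if total < min_total:
        return "indeterminate"
    fa = reads.count_allele_a / total
    if fa >= mono_cut:
        return "monoallelic_A"
    if 1 - fa >= mono_cut:
        return "monoallelic_B"
    if 1 - bi_cut <= fa <= bi_cut:
        return "biallelic"
    return "indeterminate"


def simulate_droplets(
    true_fraction_pct: float,
    copies_per_droplet: float,
    n_droplets: int,
    seed: int | None,
    sample_id: str = "sim",
    tissue: str = "blood",
    mode: str = "total_ref",
) -> DropletCounts:
    """Draw seeded droplet counts at a known methylated fraction.

    Positives per channel are Binomial(n, 1 - exp(-lambda_channel)) with the
    total copies-per-droplet split by ``true_fraction_pct``.  Under
    ``total_ref`` the reference channel sees all copies; under
    ``two_channel`` it sees only unmethylated copies.
    """
    if not 0 <= true_fraction_pct <= 100:
        raise ValueError("fraction must be in [0, 100]")
    if copies_per_droplet <= 0 or n_droplets <= 0:
        raise ValueError("copies_per_droplet and n_droplets must be positive")
    rng = np.random.default_rng(seed)
    lam_m = copies_per_droplet * true_fraction_pct / 100.0
    lam_r = copies_per_droplet if mode == "total_ref" else copies_per_droplet - lam_m
    pos_m = int(rng.binomial(n_droplets, -math.expm1(-lam_m)))
    pos_r = int(rng.binomial(n_droplets, -math.expm1(-lam_r)))
    return DropletCounts(
        sample_id=sample_id,
        tissue=tissue,
        n_pos_meth=pos_m,
        n_droplets_meth_channel=n_droplets,
        n_pos_ref=pos_r,
        n_droplets_ref_channel=n_droplets,
    )
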