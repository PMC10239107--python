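"""Region-level methylation scoring.

Implements the locus rules used throughout the triage workflow:

* MLH1 C-region score — mean beta over the four regulatory-region probes;
  a sample is MLH1-methylation positive when that mean exceeds 0.2 (strict).
* CIMP call — each of the five marker-gene regions is positive when the mean
  beta of its probes exceeds 0.2; CIMP-high requires >= 3 of 5 positive regions.
* Generic region means (e.g. the APC promoter window).
* Selection of the most variably methylated probes (clustering features):
  per-probe sample SD of beta across reference tumours, top ``fraction`` kept.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import registry
from .io import BetaMatrix, Region, probes_in_region

__all__ = [
    "RegionScore",
    "CimpCall",
    "VariableProbeSelection",
    "mlh1_c_region_score",
    "cimp_call",
    "region_mean",
    "select_variable_probes",
    "MLH1_POSITIVE_BETA",
    "CIMP_REGION_BETA",
    "CIMP_MIN_POSITIVE",
]

MLH1_POSITIVE_BETA = 0.2  # strict: positive iff mean beta > 0.2
CIMP_REGION_BETA = 0.2
CIMP_MIN_POSITIVE = 3  # CIMP-high iff >= 3 of the 5 regions positive


@dataclass
class RegionScore:
    sample_id: str
    region_name: str
    mean_beta: float
    status: str  # "positive" | "negative"


@dataclass
class CimpCall:
    sample_id: str
    n_positive_regions: int
    status: str  # "CIMP-high" | "negative"
    region_means: dict[str, float] = field(default_factory=dict)


@dataclass
class VariableProbeSelection:
    probe_ids: list[str]  # sorted by SD descending, ties by probe_id
    sd_per_probe: pd.Series  # SD over reference samples, all probes
    fraction: float
    degenerate: bool = False  # selection boundary fell inside an SD tie


def _values(beta: BetaMatrix | pd.DataFrame) -> pd.DataFrame:
    return beta.values if isinstance(beta, BetaMatrix) else beta


def _sample_mean(vals: pd.DataFrame, probes: list[str], sample_id: str, what: str) -> float:
    missing = [p for p in probes if p not in vals.index]
    if missing:
        raise KeyError(f"{what}: probe(s) missing after QC: {missing}")
    return float(vals.loc[probes, sample_id].mean())


def mlh1_c_region_score(beta: BetaMatrix | pd.DataFrame, sample_id: str) -> RegionScore:
    """Mean beta across the four MLH1 C-region probes; positive iff > 0.2."""
    vals = _values(beta)
    mean = _sample_mean(vals, registry.mlh1_c_region_probes(), sample_id, "MLH1 C-region")
    status = "positive" if mean > MLH1_POSITIVE_BETA else "negative"
    return RegionScore(sample_id=sample_id, region_name="MLH1_C_region", mean_beta=mean, status=status)


def cimp_call(beta: BetaMatrix | pd.DataFrame, sample_id: str) -> CimpCall:
    """CpG-island methylator phenotype: >= 3 of 5 marker regions with mean beta > 0.2."""
    vals = _values(beta)
    means = {
        gene: _sample_mean(vals, probes, sample_id, f"CIMP region {gene}")
        for gene, probes in registry.cimp_panel().items()
    }
    n_pos = sum(m > CIMP_REGION_BETA for m in means.values())
    status = "CIMP-high" if n_pos >= CIMP_MIN_POSITIVE else "negative"
    return CimpCall(sample_id=sample_id, n_positive_regions=n_pos, status=status, region_means=means)


def region_mean(
    beta: BetaMatrix | pd.DataFrame,
    manifest: pd.DataFrame,
    region: Region,
    samples: list[str] | None = None,
    threshold: float = MLH1_POSITIVE_BETA,
) -> pd.DataFrame:
    """Per-sample unweighted mean beta over a region's probes.

    Returns a DataFrame indexed by sample with columns ``mean_beta`` and
    ``status`` (positive iff mean > ``threshold``, strict).  Raises on an
    empty region.
    """
    vals = _values(beta)
    probes = [p for p in probes_in_region(manifest, region) if p in vals.index]
    if not probes:
        raise ValueError(f"region {region.name!r} contains no probes in the matrix")
    sub = vals.loc[probes]
    if samples is not None:
        sub = sub[samples]
    means = sub.mean(axis=0)
    return pd.DataFrame(
        {"mean_beta": means, "status": (means > threshold).map({True: "positive", False: "negative"})}
    )


def select_variable_probes(
    beta: BetaMatrix | pd.DataFrame,
    fraction: float = 0.10,
    n_probes: int | None = None,
) -> VariableProbeSelection:
    """Top probes by sample SD (n-1 denominator) of beta across reference samples.

    Selection count is ``round(fraction * n_probes)`` unless ``n_probes`` is
    given explicitly (exact-count replication mode).  Ties are broken by
    probe_id lexicographic order, making the selection fully deterministic and
    permutation-invariant; a tie straddling the selection boundary is flagged
    ``degenerate``.
    """
    vals = _values(beta)
    if vals.shape[1] < 2:
        raise ValueError("need >= 2 reference samples to compute SDs")
    if n_probes is None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        n_probes = int(round(fraction * len(vals)))
    if not 0 < n_probes <= len(vals):
        raise ValueError(f"selection count {n_probes} outside 1..{len(vals)}")
    sd = vals.std(axis=1, ddof=1)
    order = sd.to_frame("sd").reset_index(names="probe_id")
    order = order.sort_values(["sd", "probe_id"], ascending=[False, True], kind="mergesort")
    chosen = order.head(n_probes)
    degenerate = False
    if n_probes < len(order):
        degenerate = bool(chosen["sd"].iloc[-1] == order["sd"].iloc[n_probes])
    return VariableProbeSelection(
        probe_ids=chosen["probe_id"].tolist(),
        sd_per_probe=sd,
        fraction=n_probes / len(vals),
        degenerate=degenerate,
    )
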