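"""Built-in registry of the MLH1/CIMP/APC probe lists and hg19 coordinates.

The registry ships as a versioned JSON data file so that the probe lists used
for scoring are auditable and replaceable without code changes.
"""
from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .io import Region

__all__ = [
    "load_registry",
    "mlh1_c_region_probes",
    "cimp_panel",
    "region",
]


@lru_cache(maxsize=1)
def load_registry() -> dict:
    """Return the raw registry dictionary (cached)."""
    with resources.files("epitriage.data").joinpath("regions.json").open() as fh:
        return json.load(fh)


def mlh1_c_region_probes() -> list[str]:
    """The four CpG probes covering the regulatory C region of the MLH1 promoter."""
    return list(load_registry()["mlh1_c_region_probes"])


def cimp_panel() -> dict[str, list[str]]:
    """Marker-gene -> probe list for the five-region CIMP panel."""
    return {k: list(v) for k, v in load_registry()["cimp_panel"].items()}


def region(name: str) -> Region:
    """Look up a named genomic region (1-based inclusive hg19)."""
    entry = load_registry()["regions"][name]
    return Region(name=name, chrom=entry["chrom"], start=entry["start"], end=entry["end"])
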