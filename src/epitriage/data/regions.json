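{
  "version": 1,
  "coordinate_system": "1-based inclusive, hg19",
  "mlh1_c_region_probes": ["cg23658326", "cg11600697", "cg21490561", "cg00893636"],
  "cimp_panel": {
    "CACNA1G": ["cg18337803", "cg20467136", "cg23614229", "cg11262815"],
    "RUNX3": ["cg06377278", "cg27095256"],
    "SOCS1": ["cg06220235"],
    "NEUROG1": ["cg04620091"],
    "IGF2": ["cg16977706"]
  },
  "regions": {
    "MLH1_CpG_island": {"chrom": "3", "start": 37033539, "end": 37036377},
    "MLH1_locus": {"chrom": "3", "start": 37000000, "end": 37100000},
    "APC_promoter": {"chrom": "5", "start": 112072926, "end": 112073958},
    "LRRFIP2_cg15103403": {"chrom": "3", "start": 37110355, "end": 37110355}
  }
}
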