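# Methods

This note documents the models, parameter choices and limitations behind
`epitriage`. Thresholds follow the printed clinical rules they encode; every
choice the rules leave open is listed here with its default and rationale.

## Scales and transforms

β is the methylation fraction at a CpG probe, in [0, 1]. All statistics run
on M-values, M = log2(β/(1−β)), which are closer to homoscedastic across the
β range; β remains the reporting scale. The transform clamps β to
[ε, 1−ε] with ε = 1e−6 so boundary values stay finite; the inverse recovers
the clamped β to 1e−12.

Genomic coordinates are 1-based inclusive hg19 throughout, including the
BED-like region files (a deliberate divergence from 0-based half-open BED,
matching how the intervals are printed in the clinical literature). Strand
is ignored: array probes are strand-collapsed.

## Probe QC

A probe is removed when its detection P exceeds 0.05 in **any** sample, or
when it maps to a sex chromosome. The any-sample dialect is the strictest
reading of "removed from all analyses"; since the alternative (masking only
the failing cells) changes downstream sample sizes, the QC report counts
both (`n_removed_detection_any` and `n_flagged_cells`) so the choice stays
auditable. The filter is idempotent.

## Region scoring

* **MLH1 C-region**: unweighted mean β of the four regulatory-region probes;
  positive iff mean > 0.2. All "greater than" thresholds in the package are
  strict, as printed (0.2 exactly is negative).
* **CIMP**: each of five marker regions (4 *CACNA1G* probes, 2 *RUNX3*,
  1 each *SOCS1*/*NEUROG1*/*IGF2*) scores its probe-mean β; a region is
  positive above 0.2 and the sample is CIMP-high with ≥ 3 of 5 positive.
* **Variably methylated (VM) probes**: per-probe sample SD of β (n−1
  denominator) across the reference tumours, top `round(fraction × n)` kept
  (default fraction 0.10). SD is computed on β rather than M because the
  group-level summaries the selection feeds are reported on the β scale.
  Ties break lexicographically by probe id, so the selection is
  deterministic and permutation-invariant; a tie across the selection
  boundary is flagged. An exact-count mode (`n_probes=...`) exists for
  replicating published probe counts that are not an exact round fraction.

## Consensus clustering

Each of `n_resamples` (default 1000) rounds draws 80% of samples without
replacement (no feature subsampling by default) and clusters them with the
base clusterer — average-linkage hierarchical clustering on Euclidean
distance over M-values by default; k-means is available. Consensus
c_ij = co-clustered/co-sampled; final assignments cut the average-linkage
tree of 1 − c at k. With subsample fraction 1 and the deterministic base
clusterer, the consensus matrix provably equals the 0/1 co-membership of a
single run — used as a small-n oracle in the tests. A required seed feeds
one NumPy generator stream; identical seeds give bit-identical results.

**Choosing k.** Two documented criteria over a k range:

* `delta_area` (default): area under the CDF of off-diagonal consensus
  values (equal to 1 − mean c); chosen k is the smallest beyond which every
  relative area gain falls below `tol` (default 0.1).
* `pac`: proportion of ambiguous clustering — the share of consensus values
  strictly inside (0.1, 0.9); chosen k is the largest with PAC ≤ 0.02.

The Δ-area elbow cannot resolve a genuine cluster holding only a few of
dozens of samples: its area gain (proportional to the pair fraction it
re-polarises) is the same size as the forced-split noise seen past the true
k. PAC instead asks whether *every* pair is still decisively together or
apart, which stays exactly zero at the true k on separable data and jumps
when a homogeneous group is force-split. Cohorts in this problem domain
contain exactly such small groups, so the pipeline-level k report uses PAC;
both curves are always reported. Indistinguishable samples yield k = 1 with
a degenerate flag; data where neither rule resolves yield the maximum k
flagged low-confidence.

**New samples** are assigned by re-running consensus clustering on the
combined cohort at the reference k and mapping the new clusters to reference
labels by majority overlap of the reference samples (a cluster with no
reference members maps to "novel"). Reference samples whose mapped label
disagrees with their reference assignment are reported, never silently
accepted. A PCA projection (centered, full SVD, deterministic up to sign)
serves as the independent visual check on the clusters.

## Differential methylation

Per probe: Welch two-sample t on M-values (group2 − group1), two-sided P,
Benjamini–Hochberg FDR across all tested probes, and Δβ on the β scale.
Regions: probes with q < `fdr_cut` (default 0.01) seed regions; seeds within
`max_gap_bp` (default 1000) on a chromosome merge; a region is emitted when
it has ≥ `min_cpgs` (default 2) and |mean Δβ| > `delta_cut` (default 0.2).
The combined region P is Stouffer's 1 − Φ(Σzᵢ/√m) with zᵢ from one-sided
member P-values oriented by the region's direction (the one-sided P is half
the Welch two-sided P on the oriented side).

This is deliberately a seed-and-merge caller, not a kernel-smoothing one:
the filters are the explicit scientific criteria, and the Stouffer P is
exact under independence. The cost is that spatial correlation between
neighbouring probes is ignored (the combined P is anti-conservative for
dense, correlated probes) and that region counts are not comparable 1:1
with smoothing-based callers. Isolated significant probes fail `min_cpgs`
and stay in the probe-level table — single-CpG findings are reported there,
not as regions. Region-level multiplicity is not re-adjusted beyond the
probe-level BH; this is configurable and logged.

## Somatic analysis

* **Retention filter**: PASS status, tumour VAF ≥ 0.04, depth ≥ 30× — both
  minima inclusive, as "minimum of" phrasing implies.
* **LOH**: germline heterozygosity window [0.3, 0.7] inclusive; a site
  supports LOH when the tumour VAF shifts by strictly more than 0.3 from the
  germline VAF (a 1e−9 guard keeps the strict boundary exact under binary
  floating point: 0.8 − 0.5 must not count). The shift's direction (toward 0
  or 1) is recorded; for shifts this large from a heterozygous baseline the
  direction constraint is implied by the magnitude, and a pure-magnitude
  mode is exposed for comparison. Window aggregation — ≥ 2 informative sites
  and ≥ 50% supporting — is this package's choice (the underlying rule is
  site-level); both parameters are configurable and logged in the call.
  The site-level displacement equals roughly purity/2, so the rule cannot
  fire below ~60% tumour purity; the generator documents this floor.
* **Second hit**: LOH / somatic_variant / both / none, where a variant hit
  requires a retained truncating, splice or missense MLH1 record.
* **MSI**: MSI-H at score ≥ 0.245 (WES) or ≥ 0.252 (panel), inclusive.
* **Enrichment**: per gene, a two-sided Fisher exact test of (mutated vs
  not) × (in-cluster vs rest); odds ratios take a Haldane +0.5 correction
  when a cell is empty; no multiplicity correction (a raw P < 0.05 screen,
  matching how such gene screens are reported). Genes absent from a
  platform's capture should be masked, not scored wild-type.

## ddPCR quantification

λ = −ln(1 − n_pos/n_total) per channel (saturated channels error). The
methylated fraction defaults to the `total_ref` convention — the reference
channel measures total bisulphite-converted copies, so
fraction = λ_meth/λ_ref — because that matches assays whose reference
amplicon is methylation-independent; a `two_channel` mode
(λ_meth/(λ_meth+λ_ref)) covers paired methylated/unmethylated assays. The
convention is recorded in every result. CIs: log-scale delta method by
default (variance of log λ per channel summed; exact one-sided bound when
the methylated channel has zero positives), or a seeded droplet bootstrap
(default 2000 resamples). Detection requires fraction > 1% (strict) *and*
a CI excluding zero. At 15,000 droplets the estimator's bias is negligible
against its Monte-Carlo SE and the delta CI holds 95% ± 2% coverage from
0.5% to 13.4% — verified by simulation in the test suite.

**Allelic calls** from methylated-epiallele reads: monoallelic when one
allele carries ≥ 90% of reads, biallelic when both allele fractions lie in
[0.35, 0.65], indeterminate between the bands or below 50 total reads. The
two bands are intentionally separated: a 70/30 split is evidence for
neither sole amplification nor parity, and forcing it into either call
would overstate the assay. All three cutoffs are configurable.

## Synthetic cohorts

Per-probe β values are drawn from Beta(μκ, (1−μ)κ): mean μ, precision κ.
κ = 80 (default) gives within-group SDs of ≈ 0.03–0.06 across the β range,
the scale at which the 0.2 thresholds and group comparisons here are
meaningful; κ is validated so μκ ≥ 0.5 (means too extreme for the precision
raise an error suggesting larger κ). Defaults mirror a 38-tumour reference
cohort — 9 Lynch, 9 sporadic-methylated, 4 + 2 primary/secondary
epimutation, 5 double-somatic, 9 MMR-proficient — plus 6 challenging
tumours with mosaic-epimutation ground truth, labelled "unknown" in the
sample sheet so the pipeline cannot peek.

Planted structure: C-region tumour means 0.77/0.74/0.55/0.45 for
primary/secondary/sporadic/challenging and ~0.05 elsewhere; constitutional
(normal-mucosa) means 0.40/0.39 only for the epimutation groups; CIMP
regions at 0.45 only for sporadic tumours; APC promoter 0.33–0.45 for
Lynch/epimutation/challenging vs 0.16–0.20 otherwise; 2000 VM probes in
four blocks whose per-cluster elevation (+0.35 on a quarter of the probes)
reproduces overall VM means of 0.32/0.42/0.45/0.35 for the four planted
clusters — including a deliberately tiny 3-sample cluster — over an
18,000-probe background with small (σ = 0.01) subtype-level shifts plus
sex-chromosome probes as QC fodder. Variant tables plant MLH1-window LOH
(purity 0.8 by default) or truncating MLH1 second hits for the carrier-like
groups, two somatic MSH2 hits for double-somatic cases, subtype-patterned
driver mutations (BRAF/RNF43 sporadic-skewed; APC/KRAS/TCF7L2/KMT2C
carrier-skewed), and records that must fail the retention filters. Droplet
counts are generated at known constitutional fractions (35% for full
epimutation; 4.5/2.3/6.5% blood/mucosa/buccal for mosaic cases; 0 for the
rest) and allele reads at 97:3 (monoallelic) or 50:50 (biallelic) splits.

What the generator does **not** emulate: array chemistry (type I/II probe
effects, dye bias, batch effects), spatially correlated CpG blocks (probes
are independent given μ), tumour purity gradients in the methylome, FFPE
artefacts, or subclonal VAF structure beyond the single LOH displacement.
Passing tests therefore demonstrate that the statistical machinery recovers
planted truth under the assumed noise model — not that real cohorts are this
clean. The truth record is always written beside the data; tests never
re-infer truth.

## Triage cascade

Evidence is a named block of boolean/score lines, each either computed by a
module or `None` ("unknown" — never a silent default). The cascade, in
order of precedence (constitutional evidence outranks tumour-only):

1. tumour methylated ∧ blood > 10% ∧ promoter cis-variant → secondary
   epimutation;
2. tumour methylated ∧ blood > 10% → primary epimutation;
3. tumour methylated ∧ blood ≤ 10% ∧ (ddPCR mosaic detected in any
   non-tumour tissue ∨ ≥ 2 of {monoallelic methylation, MLH1 second hit,
   epimutation-like cluster, APC promoter elevated}) → mosaic candidate;
4. tumour methylated ∧ (CIMP-high ∨ BRAF V600E) ∧ sporadic-like cluster ∧
   no second hit → sporadic MLH1-methylated;
5. unmethylated ∧ MMR-deficient ∧ germline MMR pathogenic → Lynch-like;
6. unmethylated ∧ MMR-deficient ∧ ≥ 2 somatic MMR hits → double somatic;
7. unmethylated ∧ MMR-proficient → MMR-proficient;
8. otherwise inconclusive.

A sporadic-like methylome with blood methylation > 10% is contradictory and
short-circuits to inconclusive with a conflict report. The ≥ 2-of-4 backup
in rule 3 covers mosaic carriers without ddPCR data; two independent lines
were chosen as the minimum because any single line (e.g. cluster membership
alone) has plausible alternative explanations. `classify` is a pure
function of the evidence block and its rationale cites only evidence-line
names, so every call is reproducible and auditable from the report alone.
Blood methylation compares `max(MethyLight %, 100 × array β)` against the
10% rule; tumour positivity accepts array C-region > 0.2, MethyLight > 10%
or MS-HRM > 5% (all strict).

"Epimutation-like" and "sporadic-like" clusters are named from the
reference cohort as the modal cluster of the epimutation and sporadic
training samples respectively.

## Problem sizes and numerics

Default desk-scale conditions: ~20,000 probes (not array-scale 770k), 44
tumours, 1000 resamples for stand-alone clustering and 300 within the
end-to-end pipeline, 15,000 droplets per ddPCR well, 50–200 simulation
replicates for detection-rate estimates. These sizes keep the full suite
and the acceptance script fast while leaving every statistical conclusion
(recovery ARI, coverage, detection rates) well-resolved. All randomness
flows through explicitly passed NumPy generator seeds; pipeline reruns at a
fixed seed are bit-identical, and report numbers are stable to 1e−9 across
platforms.

## Known limitations

* The DMR caller's independence assumption makes the Stouffer P
  anti-conservative on dense probe clusters; counts are not comparable with
  kernel-smoothing callers.
* The Δ-area k rule under-resolves clusters of a few samples (see above);
  PAC is the recommended criterion for such cohorts.
* The LOH rule is blind below ~60% tumour purity by construction of the
  0.3-shift threshold.
* The triage cascade encodes subgroup definitions as deterministic rules;
  borderline evidence (e.g. blood methylation near 10%) flips calls at the
  stated thresholds rather than degrading gracefully.
* ddPCR quantification assumes ideal random partitioning; droplet-volume
  variation and rain are not modelled.
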