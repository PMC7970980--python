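# Methods

This note documents the models, rules and numerical choices behind
`btnscreen`, and what the synthetic-data tests do and do not establish
about real data.

## The diagnostic model

Bivalve transmissible neoplasia (BTN) is diagnosed here by the chain used
in the mussel literature: flow-cytometry screening → tissue genotyping →
chimerism logic → lineage assignment. Two premises carry the whole
argument. First, a transmissible cancer makes its host a genetic chimera:
the hemolymph, where neoplastic cells proliferate, is dominated by the
cancer's alleles, while solid host tissue (foot) retains the host
genotype. Second, because the cancer is a clone, the "extra" hemolymph
alleles are identical across unrelated diseased individuals. A BTN call
therefore requires both lines of evidence; either alone is insufficient
(chimerism can be mimicked by colony-sampling noise, and allele sharing
alone by common host polymorphism).

## Flow cytometry (`flowploidy`)

Input is a pre-gated 1-D event list (scatter gating and doublet removal
are upstream instrument steps and are not modeled). The analysis is:

* **Histogram**: default 128 bins over [0, max intensity]. 128 bins keeps
  a ~2 % diploid residue resolvable beside a dominant aneuploid peak at a
  5 % CV; 256 bins spread minority peaks too thin.
* **Peak seeding**: iterative masked argmax on the lightly smoothed
  (Gaussian, σ = 1.5 bins) counts — take the highest unmasked bin,
  estimate σ from its half-height width, mask ±3σ, repeat. A single
  prominence threshold cannot simultaneously find a 96 % peak and a 2 %
  peak; iterative masking can. Candidates at a mask edge (shoulders) are
  discarded.
* **Gating**: every bin is assigned to the nearest seed in z-score units,
  within 3σ; per-peak mean, σ and event fraction are recomputed from the
  assigned raw counts; seeds with mean ratio < 1.05 merge; seeds holding
  < `min_fraction` (default 0.01) of events are dropped and their bins
  reassigned. Fractions sum to ≤ 1 — events outside every gate stay
  unassigned.
* **Ploidy**: the diploid anchor is the lowest-mean peak holding ≥ 1 % of
  events (not the largest peak — in heavy disease the diploid residue can
  be under 10 %, and at the extreme of the modeled range, 2 %). Every peak
  gets r = 2·μ/μ_anchor.
* **Labels**: a peak within ±0.3 n of 4.0 is *tetraploid* only if it holds
  < 5 % of events; that label exists to excuse the small normally
  proliferating (G2/M) admixture of healthy animals, and a large near-4 n
  population is disease, not proliferation — observed disease ploidies
  (3.7–5.2 n) straddle 4 n, so excusing by proximity alone would wave
  heavy near-tetraploid disease through as healthy. All other non-anchor
  peaks are *aneuploid*.
* **Diagnosis**: DN-suggested iff an aneuploid peak holds ≥ 5 % of events
  (`min_aneuploid_fraction`); healthy if only diploid ± small tetraploid;
  a ≥ 5 % tetraploid mass with no aneuploid peak is flagged
  `ambiguous-proliferative` rather than forced into either class.

Seeded simulations at 10,000 events, CV 5 %, recover the aneuploid
fraction within ±2 percentage points and the relative ploidy within
±0.1 n across the grid fraction ∈ {12…98 %} × ploidy ∈ {3.7, 4.5, 5.2} n,
with ≥ 99 % healthy specificity over 500 replicates. Real instruments add
debris, S-phase bridging between 2n and 4n, and non-Gaussian tails, none
of which are modeled; passing these tests shows the estimator is correct
for well-formed mixtures, not that it is robust to instrument artifacts.

## Allele calling (`allelecall`)

Colonies with identical sequences are grouped. A group below
`min_colonies` (default 2) is excluded as a presumed PCR/cloning artifact
**unless** the identical sequence occurs in another experiment of the
study (*singleton rescue*, switchable). Rescue is the only reading
consistent with the bundled survey table, which retains several
single-colony alleles exactly when they recur in another tissue or
individual; it is sound because artifact sequences are essentially never
identical across independent experiments, while a real low-frequency
template (a minority host allele under a dominant cancer allele) recurs
naturally. Frequencies are computed over retained ("major-sequence")
colonies only.

Homopolymer merging collapses allele pairs that differ only at sites
inside or adjacent to a single-base run of ≥ 6 bp (slipped-strand
mispairing), into the higher-count allele.

Mixed chromatograms are decomposed into dominant/minority sequences; in
hemolymph the dominant signal is attributed to the cancer candidate only
when the reconstructed minority equals the same individual's foot allele.
Beyond 30 % mixed sites the major/minor assignment is unreliable and the
read is rejected (the threshold is a package convention).

Microsatellite fragment enrichment (hemolymph share ≥ `enrichment_ratio` ×
foot share) is always graded *inconclusive-evidence*: the same fragments
segregate in healthy hosts.

## Chimerism and BTN calls (`chimera`)

`extra_alleles` uses strict frequency inequality (hemolymph > foot,
margin 0 by default) because the case-series observation is "always more
frequent in the hemolymph"; the margin parameter exists to absorb colony
sampling noise at a sensitivity cost. Note the deliberate consequence:
with two independent 16-colony experiments per tissue, healthy controls
are frequently "chimeric" by sampling jitter alone — which is exactly why
BTN positivity additionally requires the extra alleles to match the
shared cancer genotype. Specificity tests assert zero BTN positives on
uninfected cohorts, not zero nominal chimerism.

The shared cancer genotype takes, per locus, the extra alleles identical
across ≥ `min_support` diseased individuals — all of them for small case
series, relaxed to ⌈N/2⌉ from N = 6 (a documented heuristic; universality
across four animals was the original evidence standard). Mitochondrial and
nuclear loci are pooled for evidence counting but reported per locus, and
diseased individuals are additionally grouped by their mitochondrial extra
alleles: one nuclear genotype with two mito haplotype groups is the
expected structure of a lineage carrying two mitochondrial haplotypes.

Mitochondrial sexing calls *male* iff any mantle 16S allele is closer to
an M-mtDNA than to an F-mtDNA reference (or within `max_m_distance` of an
M reference when a threshold is preferred). On artifact-free synthetic
cohorts inferred sex equals the generator's truth for every specimen.

## Lineage, networks, recombination (`lineage`)

* **p-distance**: mismatching columns over columns where both sequences
  carry a base (`-`, `N`, `?`, `.` treated as missing; pairwise deletion).
  No model correction (JC/HKY) — the diagnostic claims rest on identity or
  near-identity, where corrections are irrelevant.
* **Assignment**: nearest panel reference wins; ties across lineages are
  reported as *ambiguous* rather than broken arbitrarily; `novel` flags a
  best distance above `novel_threshold` (default 0.03 ≈ the largest
  observed cancer-to-reference divergence, 16/622 ≈ 2.6 %).
* **Network**: the union of all minimum spanning trees (computed by a
  Kruskal level-set construction and verified against exhaustive MST
  enumeration on ≤ 6 haplotypes), with every k-step edge expanded through
  k−1 inferred median nodes so each drawn edge is one substitution. This
  is a parsimony-style approximation of the TCS statistical-parsimony
  network; the 95 % connection limit is exposed only as an optional
  `max_connection_steps` (default: unlimited, network connected).
* **Recombination scan**: windows (default 50 bp, step 10) are assigned to
  the parent the query matches better; assignment flips are refined by
  maximising the 2×2 χ² of (left/right × matches-F/matches-M) over
  parent-informative sites. Because the statistic is constant between
  informative sites, the reported breakpoint is the centre of the
  maximising plateau. At 3–6 % parent divergence the mean absolute error
  is well under half a window; two recombinants built on the same interval
  report identical breakpoints, which is the comparison the lineage
  argument needs (only equality of breakpoints is interpreted, never
  their absolute coordinates).

## Synthetic cohorts (`simcohort`)

Defaults are the study conditions of the screening survey the pipeline
models: 226 specimens, prevalence 10/226 (≈ 4.4 %), neoplastic fraction
uniform on [0.12, 0.98], relative ploidy uniform on [3.7, 5.2] n, 16
colonies per cloning experiment, 10,000 flow events (CV 5 %, 2 % healthy
tetraploid admixture), cancer nuclear pair 21 substitutions apart, and by
default two clones sharing the nuclear pair but differing in their
mitochondrial haplotype. Choices the source material does not fix, made
once: host within-locus diversity Poisson with mean 4 pairwise
substitutions per ~600 bp locus (matching the 0.3–1.5 % host allele
divergences observed); per-colony artifact rate 0.15 (the observed
minor-clone share across cloning experiments spans 0–25 %); control-region
recombination breakpoints at (200, 400) of 622 (coordinates are never
interpreted, only compared); M-mtDNA references 8 % divergent from F.

Modeling assumptions: one cancer genome equivalent per neoplastic cell, so
allele weight equals cell fraction p (aneuploid dosage is not modeled —
the relative DNA content of cancer cells in PCR templates is unknown, and
this is the flagged simplification most likely to differ from reality);
foot infiltration 0 by default (no heteroplasmy was seen in foot tissue in
the modeled survey; configurable for sensitivity analyses); hosts
mitochondrially homoplasmic per somatic tissue; substitutions only, no
indels (alignment is taken as given); artifact sequences forced unique
study-wide so the singleton-exclusion rule is well-posed. Coordinates are
0-based, half-open throughout. Identical configuration (including seed)
reproduces byte-identical cohorts and pipeline reports.

## Bundled data

`data/table1.tsv` is the colony-count survey of four diseased mussels with
the printed frequencies preserved; integrity is checked by SHA-256 at
load. The printed frequencies of two experiments (J161/EF1α/foot and
J181/CR/hemolymph) are consistent only with a total-clone denominator
while all others use the major-clone denominator; the fixture keeps the
printed values verbatim and the package always computes frequencies over
retained colonies. Allele *sequences* for the fixture are generated
deterministically (`io_.table1_sequences`) as synthetic stand-ins that
preserve the documented relationships (G–H 21 substitutions; G–G1 1;
COI-1–COI-2 6; CR-1–CR-1′ 3; D–7 a single swap at the 9 bp poly-A tract;
recombinant cancer CRs). `data/reference_panel_synthetic.fasta` is the
matching synthetic reference panel; `data/accessions.tsv` names the
GenBank namespace of the real alleles. The pipeline never fetches
anything.

## Problem sizes in tests and the acceptance script

The default suite uses 10,000-event flow simulations (500 replicates for
specificity), 200-replicate cloning recovery runs at 16 and 64 colonies,
100 seeded recombinants for breakpoint error, exhaustive MST enumeration
up to 6 haplotypes, and cohorts up to 1,000 specimens for the DUI
invariant — sizes chosen so the whole suite runs in well under a minute
while keeping Monte-Carlo standard errors far below the asserted
tolerances. The acceptance script recomputes its numbers at the study's
own scales (23-colony experiment; 10,000-event specimens).

## Known limitations

* No cell-cycle (S-phase) bridge, debris or fluorescence compensation in
  the flow model; recovery results bound estimator error, not instrument
  robustness.
* Chromatogram decomposition assumes two templates; three-way mixtures
  are rejected rather than resolved.
* The recombination scanner assumes exactly two parents and reports
  single-crossover-style segmentations; mosaic alleles with short
  conversion tracts below the window scale are not detectable.
* Lineage assignment is distance-based; it cannot separate lineages whose
  panel references are themselves nearly identical at a locus (reported
  as ambiguous instead).
* The strict enrichment rule flags nominal chimerism in noisy controls by
  design; interpret chimerism only jointly with the shared-genotype
  evidence.
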