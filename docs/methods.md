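# Methods

## Scope and data model

`pedexome` implements the analysis stack of a family-based rare-variant
prioritization study: QC of genotypes and sites, affecteds-only
parametric two-point linkage, IBD-segment delineation among affected
relatives, and three prioritization tiers. Variants are stored biallelic
(multi-allelic records split on read, with alleles of a different alt
recoded as reference in each split record), 1-based, and normalized —
parsimony-trimmed always, fully left-aligned when a reference sequence is
supplied. Half-calls are treated as missing: a lone observed allele
carries no usable information for segregation logic. A variant absent
from the population frequency database passes rarity filters (absence is
itself evidence of rarity) and carries a `maf_missing` flag into every
report. Coordinates are opaque keys; no liftover is performed.

## Quality filters

Defaults are the study thresholds, bit-exact and config-overridable:
genotype depth ≥ 5 and GQ ≥ 20 (genotypes failing are set missing, the
site is kept — downstream segregation logic handles missingness); site
VQSLOD > 0 strictly, with sites lacking a score retained and flagged;
35 bp mappability exactly 1 and 20 bp mappability ≥ 0.5; sample call
rate ≥ 0.98 and marker call rate ≥ 0.95; a generic cross-platform rule
requiring presence in ≥ 60% of samples pooled over platform batches.
Genotype- and site-level filters commute, which the suite checks.
Duplicate-read removal happens upstream of the VCF (in the caller's QC)
and is documented here rather than reimplemented.
LD pruning is greedy within 50-marker windows stepping by 5: while any
kept pair has dosage r² > 0.5 (Pearson over complete pairs), the member
with the lower call rate is dropped, ties broken by dropping the later
marker — a deterministic convention the upstream tool leaves unspecified.

## Linkage model

A diallelic disease locus (frequency q, penetrances f₀,f₁,f₂) is placed
at recombination fraction θ from a codominant marker with known allele
frequencies. Defaults q = 10⁻⁴ and (0, 1, 1) encode the rare-dominant,
no-phenocopy model; all three are exposed. With `affecteds_only=True`
(default) unaffected and unknown phenotypes contribute a likelihood
factor of 1. The per-individual latent state is an *unordered* pair of
(disease allele, marker allele) haplotypes — transmission probabilities
are symmetric in the two haplotypes, so nothing is lost and the state
count is 2k(2k+1)/2 for k marker alleles. Founder priors assume linkage
equilibrium; marker allele frequencies must be supplied (estimating them
from a handful of founders is biased, so the choice is explicit).

The likelihood is evaluated exactly by Elston–Stewart peeling: nuclear
families are eliminated in an order where each clique shares at most one
pivot individual with the remainder (`Pedigree.peeling_order`), and each
child is summed out by contracting through the state→gamete transmit
matrix (M V Mᵀ) rather than materializing the states³ tensor. Factors are
rescaled after each elimination, accumulating the log, so large
pedigrees do not underflow. Pedigrees with marriage or consanguinity
loops are rejected rather than approximated, keeping the engine exact.

LOD(θ) = log₁₀ L(θ) − log₁₀ L(0.5) on the grid
{0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5} (a conventional two-point
reporting grid). A θ with zero likelihood ratio (obligate recombinant at
θ = 0) is reported as the finite sentinel −99 to keep tables well
formed; a family whose genotypes are impossible even at θ = 0.5
contributes 0. Per-family LODs sum exactly to the total. LOD > 2 regions
are maximal runs of consecutive passing markers, with bounds extended to
the flanking non-passing markers (clamped at scan ends) — without a
genetic map, flanking-marker bounds are the reproducible choice.
Multipoint linkage is out of scope: the tiers rest on family-specific
parametric scores, which two-point peeling provides exactly.

An important structural bound: under the affecteds-only dominant model
each affected non-founder contributes at most a factor 2 to the
likelihood ratio, so LOD ≤ (n_affected − 1)·log₁₀2. LOD > 2 therefore
requires at least 8 affected members; this drives the design of the
recovery study below.

## IBD segments

A marker is "shared" in a family when some founder haplotype label is
carried by every genotyped affected (labels come from the simulator or
an external phasing step — haplotype reconstruction itself is not
reimplemented). The window rule reads "> 50% of a 10-SNP window" as
strictly greater, i.e. ≥ 6/10 — an alternating 5/10 profile calls
nothing, which the suite pins down. A marker is positive if *any*
covering window passes (max over windows), which yields contiguous,
order-stable segments; whether the original rule centers windows is
ambiguous, and the max-over-windows reading is adopted. Segment bounds
are the first/last positive marker positions, not interpolated
midpoints. Chromosomes with fewer markers than the window fall back to a
single whole-chromosome window and flag their segments.

## Prioritization

Tier 1 (known genes, MAF ≤ 2% inclusive) does not require segregation:
the tables this tier mirrors include variants seen in a single affected
relative, which the source discusses as possible contributing alleles.
Tier 2 (LOD > 2 regions, MAF ≤ 1%) requires segregation — every
sequenced affected with a non-missing call carries the variant — and
annotates CADD ≥ 15 as a flag rather than filtering on it, because the
published linkage-region table retains two low-CADD missense changes.
Tier 3 (cross-family, MAF ≤ 1%, CADD ≥ 15 hard) clusters genes hit in
≥ 2 families and excludes genes already on the known-gene list; without
that exclusion a known gene with segregating rare damaging variants in
two families would re-enter a tier meant for novel candidates. All MAF
comparisons are inclusive. "Known loci" means gene bodies, not windows
around association peaks.

## The packaged fixture

The three published result tables ship as TSV data. Reconstructing
analyzable genotypes from printed carrier counts requires one choice:
carriers are coded heterozygous; non-carrier affecteds are homozygous
reference for tier-1 rows (described as not fully segregating) but
*missing* for tier-2/3 rows, whose variants are described as segregating
in all evaluable affecteds — their individual genotypes are not
published. The LOD > 2 region fixture is a synthetic reconstruction
(`lod_regions_synthetic.tsv`): the true bounds are unpublished, so the
intervals simply span the reported variant positions. Family pedigrees
are minimal sibships of the printed size; none of the tier counts depend
on deeper structure.

## Synthetic data generator

The simulator emulates the study design: three-generation multiplex
families (a founder couple, six gen-2 children who marry in unrelated
spouses, five grandchildren per couple), a dominant causal variant
planted on one founder haplotype with q = 10⁻⁴ and penetrances (0, 1, 1),
and affected members marked sequenced. Founder haplotypes carry unique
labels; each meiosis transmits a strand mosaic switching with the
inter-marker θ, so IBD is known exactly. Affection is sampled once from
the penetrances (not conditioned on family size); an optional
rejection-sampling floor (`min_affected`, default 10) enforces a minimum
affected count, mirroring ascertainment of heavily affected families
without biasing transmission.

The default linkage panel is 15 microsatellite-style markers with 10
equifrequent alleles every 2 Mb at adjacent θ = 0.02. High marker
polymorphism matters: with the LOD bound above, recovery hinges on the
causal-flanking markers being informative in the founders. The planted
variant is annotated at its anchor marker's map position, consistent
with the zero recombination between them that the genotypes embody.
`min_affected = 10` places the recovery study in the upper half of the
emulated 4–16 affecteds-per-family range, where LOD > 2 is robustly
attainable (at 8 affecteds the theoretical maximum is 2.11, leaving no
margin for uninformative meioses). Background variants draw population
frequencies from a mixture (25% common, uniform 2–30%; 75% rare,
log-uniform 3·10⁻⁵–10⁻²) so rarity filters have both classes to act on;
CADD is bimodal around the 15 threshold and one fifth of consequences
are non-qualifying. Genotype-error and missingness overlays default to
zero and are switched on by tests that need them (e.g. the 1%-error
concordance calibration).

What the simulator does not emulate: realistic human LD structure,
allele-frequency spectra tied to real populations, sequencing reads, or
annotation errors. Passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not robustness to real
exome artefacts.

The IBD window rule presumes array-dense markers; tests of the segment
caller run the generator at 100 kb spacing (adjacent θ = 0.001), where
the planted locus falls inside a called segment in effectively every
replicate, while the sparse microsatellite panel serves the linkage
stage.

## Verification strategy

Every nontrivial computation has an independent oracle in the test
suite: the peeling likelihood against a naive full-joint-table
enumeration (one tensor axis per individual, ordered diplotypes — a
different state representation on purpose), checked to 10⁻¹⁰ relative
error over thousands of random pedigree/genotype configurations; the
closed-form ten-meiosis cross (LOD(0) = 10·log₁₀2 exactly, obligate
recombinant → sentinel); kinship against inheritance-vector enumeration;
indel normalization against `bcftools norm` on random indels; the window
caller against explicit per-window loops; and binomial calibration
checks for recombination and penetrance sampling. The end-to-end
recovery study (100 replicates) asserts the planted variant reaches the
linkage-region tier in ≥ 95% of replicates with < 5 background genes per
family; measured values are ~98–100% and ~0.05.

## Numerical and degenerate-case conventions

Likelihood scaling per elimination step; −∞ log-likelihood for
structurally impossible genotypes (returned as probability 0, never an
exception); all-missing genotypes give a flat LOD of 0; empty report
tiers summarize as zeros, not absent keys; marker frequency vectors must
sum to 1 within 10⁻⁹. Problem sizes in the acceptance script (12
pedigrees × 40 configurations for the peeling check, 500 profiles for
the window check, 100 recovery replicates) were chosen as the smallest
runs that exercise each property convincingly.

## Known limitations

Loop pedigrees are unsupported (exactness over coverage). Two-point
linkage only — the multipoint machinery of the original analysis (and
its aggregated multipoint peak) is deliberately out of scope, so
family LOD values from multipoint-informed runs are not re-derivable.
X-linked models, liability classes, and marker-based relatedness
estimation are not implemented. Sex is taken from the pedigree file;
no intensity-based inference. The published families' real genotypes are
unavailable, so their family-specific LOD values enter only through the
synthetic region fixture.
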