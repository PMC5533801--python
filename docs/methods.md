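# Methods

`radcapkit` re-creates, at desk scale, the computational arc of a
ddRAD-locus target-capture study: reduced-representation loci are
catalogued from RAD assemblies of one or two probe-design species, 120-mer
capture probes are tiled over curated templates, captured reads from many
related species (modern and museum specimens) are processed, mapped or
assembled into a cross-species reference, genotyped under hard filters, and
summarised with population-genetic statistics.  Every stage is validated
against a synthetic-data generator whose truth is known exactly.

## The synthetic experiment (`simdata`)

The generator emulates the study design rather than any particular genome:

* **Loci.** `n_loci` ancestral sequences drawn uniformly over A/C/G/T, each
  140–220 bp with a fixed 6 bp restriction half-site at both ends (an
  EcoRI/PstI-style double digest).  No indels are generated anywhere, so
  closed-form expectations exist for every downstream check.
* **Divergence.** Species haplotypes derive from the ancestor under an
  equal-rates substitution model, parameterised directly as the per-site
  substitution probability (`species_divergences`, default 0.02/0.05/0.08
  for three species — the within-genus range over which capture is expected
  to work, with efficiency loss beyond ~5%).
* **Individuals.** Diploid genotypes add heterozygous sites at rate
  `theta_het` (default 0.005/site) on one allele.
* **Allele dropout.** An allele whose restriction half-site carries m
  substitutions is lost from a ddRAD library with probability
  1−(1−d)^m (`dropout_per_substitution`, default 1.0).  This is the
  restriction-site-polymorphism mechanism behind RAD missing data; capture
  libraries are sonicated genomic DNA and ignore dropout.
* **Coverage.** `coverage_mean` is the expected number of *fragments* per
  locus per individual (default 20).  Mean aligned depth in X is lower by
  the fragment/locus length ratio (~0.75) and, in capture mode, by the
  divergence factor 2^(−div/`capture_halflife`) (half-life default 0.05
  substitutions/site).  Capture coverage is floored at one fragment per
  individual and locus: enrichment decays with divergence but does not
  silently delete loci, which is what makes the ddRAD-vs-capture missing
  data contrast strict.
* **Fragments.** Capture mode draws sonication-style inserts,
  length ~ Normal(min(170, 0.75·locus), 25) clipped to [80, min(locus,
  220)], uniform start, random strand.  The mean scales down for short
  loci so insert lengths do not pile up at the locus boundary — important
  because duplicate marking keys on (start, length, strand) and boundary
  pile-ups would create coincidental false duplicates.  ddRAD mode emits
  the whole restriction fragment (by construction identical across copies,
  which is why the study design can only de-duplicate capture data).
* **Duplicates.** A fraction `duplicate_fraction` of emitted fragments are
  exact PCR copies of existing fragments (same coordinates and template,
  fresh sequencing errors; museum damage is copied with the template, as
  deamination precedes amplification).
* **Museum mode.** Insert lengths ~ Normal(`fragmentation_mean`=70,
  mean/4) clipped to ≥40 bp, and terminal deamination applied in the
  fragment's emitted orientation: C→T at 5′ position p (1-based) with
  probability δ·λ^(p−1), G→A mirrored from the 3′ end (defaults δ=0.3,
  λ=0.5 — a strongly damaged historic extract).
* **Errors and qualities.** Per-base substitution errors at `error_rate`
  (default 0.01, matching a mid-quality desktop sequencing run); quality
  strings are constant at Q = −10·log₁₀(error rate) (museum capped at
  Q30) so the caller's quality-derived error model agrees with the
  generating process.
* **Determinism.** All randomness flows from `numpy.random.default_rng`
  seeded by the config seed plus a per-stage constant; identical configs
  give byte-identical outputs.

What the generator does *not* emulate: coalescent genealogies (species are
star-shaped from the ancestor), indels, GC- or motif-dependent capture
bias, position-dependent error profiles, index hopping.  Passing tests
therefore demonstrate the pipeline's correctness and calibration under a
clean substitution-only regime, not robustness to every artefact of real
libraries.

## Catalogue construction and probe design (`catalog`)

Within-sample reads are greedily clustered (seeds by descending abundance,
ties lexicographic; membership requires ≥95% identity *and* ≤3
mismatches).  Consensus columns where two bases each exceed 25% of depth
become IUPAC ambiguities; clusters with more than 50% ambiguous columns
are discarded as paralog stacks.  Across samples, consensi cluster at 95%
(single-species) or 85% (combined); loci with the same column heterozygous
in more than four individuals, or any column showing more than three
distinct bases, are flagged as shared-heterozygosity paralogs.  Loci
present in multiple assemblies are synonymized (≥90% identity over ≥55% of
the shorter locus, transitive closure; the survivor keeps the longer
consensus and the union of per-sample alleles).  Pairwise similarity above
the same 90%/55% rule flags both partners; mononucleotide runs ≥10 bp or a
DUST-style triplet score >2 flag low complexity; loci matching a supplied
mitochondrial genome (≥80% identity over ≥50% of length, either strand)
are flagged but kept — mitochondrial templates are legitimate probe
targets.  Candidates require no discard flag and presence in ≥10
individuals (single-species) or ≥20 (combined).  Probes are 120-mers tiled
at 60 bp steps with the final probe right-anchored at (length−120):
templates of 121–180 bp take exactly two probes, which is what makes 2,366
templates in that band yield 4,732 probes.

Identity is everywhere matches ÷ alignment columns (computed with edlib;
with no indels in play, edit distance equals mismatch count).  All
similarity searches are strand-aware: consensus orientation is arbitrary
after assembly, so k-mer candidate lookup and window identity both check
the reverse complement.

## Read processing (`readproc`)

3′ bases under Q20 and configurable adapter suffixes are trimmed; any mate
with mean Phred <33 discards the pair (the threshold is unusually strict
and is exposed as a parameter).  The contaminant screen indexes canonical
31-mers of the supplied references and removes pairs in which either mate
shares ≥50% of its canonical k-mers — a keep/remove decision only, no
taxonomic labels.  Merging scans for the longest 3′ overlap ≥20 bp with
≤10% mismatches (exact 16-mer seeding with an exhaustive fallback),
resolves overlap bases to the higher-quality call, truncates to 220 bp,
and in ddRAD-catalogue mode drops fragments <140 bp.  Demultiplexing
accepts one mismatch per index and requires sheet indexes mutually ≥3
mismatches apart; ambiguous pairs stay unassigned.  Every stage counts
input = kept + discarded.

## Mapping, duplicates, reference building (`capture`)

Mapping seeds candidate loci from a 15-mer index and verifies placements
on both strands with edlib; the score is read length − 2·edit distance and
maQ = min(60, best − second best), so a unique hit scores 60 and a perfect
tie 0.  Records with maQ <5 are excluded.  Duplicates are fragments
identical in (sample, locus, start, insert length, strand); the
highest-summed-quality member survives, deterministically.

The assembly-based reference clusters merged modern-sample reads greedily
at 90% identity with length-descending seeds, drops clusters under 40
reads, computes majority consensi, and merges over-split clusters whose
consensi overlap ≥120 bp at ≥85% identity (transitive closure, longest
consensus kept).  Divergent species typically form sibling clusters per
locus that this merge step reunites.  Reciprocal best hit between consensi
and the probe-template set (identity floor 0.75, matching the ~12%
divergence probes tolerate) labels loci on/off-target; consensi matching
the mitochondrial reference, or whose halves best-hit different templates
(chimeras), are flagged and excluded.

## Variant calling and hard filters (`variants`)

Per site and sample, diploid genotype likelihoods use P(base|hom) = 1−e
for the matching allele, e/3 otherwise, and a half-half emission for
heterozygotes, with e from mean base quality and a flat genotype prior;
GQ is the phred gap to the runner-up.  Site QUAL is the phred-scaled
probability that every sample is homozygous reference.  Annotations: QD =
QUAL ÷ summed depth of alt-carrying samples; MQ = RMS mapping quality; FS
= −10·log₁₀ of the two-sided Fisher exact p of the 2×2 strand×allele
table (0 on degenerate margins); ReadPosZ = Wilcoxon rank-sum z of alt vs
ref distances from the nearer read end.  Hard filters: QD <4, MQ <18,
QUAL <40, FS >60, fewer than 8 samples at ≥5X, and (for sites with any
heterozygous call) ReadPosZ < −12; only biallelic PASS sites are kept,
with per-filter failure counts.  "Phred quality" is read as site QUAL
(genotype quality is also emitted); the haplotype-score annotation of one
specific caller has no closed form here and is deliberately not
implemented.  Summaries report ts/tv (transitions A↔G, C↔T; an infinite
marker when no transversions), deamination-direction candidates, and
per-species / per-locus SNP counts.

Under the flat prior, one alt read among ~5 at e=0.01 genuinely favours a
heterozygote — the model's honest behaviour at low depth.  Calibration
claims are therefore made at ~20X aligned depth, where the caller reaches
≥99% allele-aware concordance with truth on simulations.

## Museum-DNA handling (`damage`)

Damage profiles count reference-C→read-T mismatches by 5′ position and
reference-G→read-A by 3′ distance (positions 1–25) in the fragment's
emitted orientation, and fit f(p) = δ·λ^(p−1) by weighted least squares.
The background mismatch rate is estimated from interior positions (≥10
from both ends); a fitted δ below twice background reports "no damage
detected", and profiles with under 1000 informative positions are marked
unreliable.  Samples under 2.0X mean target coverage are excluded from
population analysis; A260/A280 ≤1.0 and concentration ≤30 ng/µL attach
rule-of-thumb warnings only.  The deamination filter removes whole variant
sites whose major→minor direction is C→T or G→A — deamination is
directional, so T→C and A→G sites stay — uniformly for modern and museum
samples.  Major alleles are defined by global frequency with ties resolved
toward the reference; a per-species mode is available.

## Population statistics (`popstats`)

Genotypes live in a samples × sites dosage matrix (0/1/2, −1 missing).
Site filters drop sites with >10% missing data or MAF <0.05 (a site at
exactly 0.05 is kept; fixed sites always go).  LD pruning slides a
50-site window in steps of 5 and, while any pair exceeds r² = 0.5, drops
the member with more missing data (ties: lower MAF, then later position) —
window and step are conventional defaults.  Fst is the Weir & Cockerham
(1984) variance-component estimator: per biallelic site the among-
population (a), among-individual (b) and within-individual (c) components
from n̄, n_c, p̄, s², h̄; global θ is the ratio of sums Σa/Σ(a+b+c), not the
mean of per-site ratios.  PCA mean-imputes missing genotypes per site,
centres, scales by √(p(1−p)), drops zero-variance sites, and fixes each
component's sign so its largest-magnitude loading is positive.  Observed
heterozygosity is reported site-wise (mean ± SD); locus sharing counts a
locus as present in a species when at least one individual of that species
is genotyped there.

## Validation studies and problem sizes

`radcapkit.evaluation` packages the studies the test suite and
`scripts/acceptance.py` run; sizes were chosen so the full battery
completes in a few minutes on one CPU:

* probe tiling arithmetic on 2,366 templates (exact);
* locus recovery: 300 loci (200 probed), 3 species × 8 individuals, 20
  fragments/locus — ≥95% of loci recovered as single reference loci, ≥95%
  correct on/off-target labels;
* missing-data contrast: 120 loci × 18 samples, strict per-sample
  ddRAD > capture missingness;
* duplicate recovery at injected fraction 0.30, tolerance ±0.02;
* Weir–Cockerham: two hand-computed toy matrices to 1e-12 and a panmictic
  2×50-sample, 500-site pool with |θ| < 0.01;
* hard-filter boundary suite straddling every threshold;
* museum study: δ=0.3, λ=0.5 recovered within 10%, the directional filter
  removing ≥90% of damage-induced sites while retaining ≥98% of true
  non-directional sites, and an exactly-zero θ shift on undamaged data
  with no directional sites;
* genotype concordance: 100 loci × 16 samples at ~20X aligned depth and
  1% error, ≥99% allele-aware concordance over called genotypes (sites the
  caller never emits count as hom-ref; no-coverage genotypes count as
  missing, not wrong).

## Numerical and design notes

* Tie-breaks are deterministic throughout (lexicographic sequence or id
  order); re-running any stage on its own output is a no-op where the
  contract says so (duplicate marking, site filters).
* Degenerate inputs: empty read sets produce empty outputs; an empty
  surviving cluster set raises an explicit empty-reference error; Fisher
  tables with a zero margin score FS = 0; monomorphic sites contribute
  nothing to θ.
* The spec-level flag vocabulary's `redundant` is realised as the
  informational `redundant_resolved` on merge survivors: synonymized loci
  remain eligible probe templates, only paralog/low-complexity flags
  discard.
* Coordinates are 0-based half-open internally; SAM and VCF emission
  convert to 1-based.

## Known limitations

Greedy clustering is order-dependent by design (made deterministic, not
optimal); paralogs more similar than the purge thresholds to their twin
are indistinguishable from alleles; the k-mer prefilters can miss
pathological mutation spacings that destroy all shared 15-mers (irrelevant
for random substitution patterns); multi-allelic sites are emitted but not
genotyped beyond the primary alt; museum genotyping at <5X remains
miscalibrated under the flat prior and is the reason the coverage QC and
deamination filter exist.
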