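# radcapkit

A desk-scale toolkit for **ddRAD-locus target-capture** studies: the
combination of reduced-representation sequencing (ddRADseq) with in-solution
hybridisation capture that lets one probe panel, designed from RAD
assemblies of one or two species, recover orthologous loci across a whole
genus — including degraded museum specimens.  It is written for population
geneticists who want to design such an experiment, process its reads, and
validate every computational step offline against simulations with known
truth.

The toolkit covers the full arc:

1. **`simdata`** — synthetic multi-species experiments: restriction loci,
   species divergence, heterozygosity, restriction-site allele dropout,
   divergence-dependent capture efficiency, PCR duplicates, museum-style
   fragmentation and terminal deamination, all with recorded truth.
2. **`catalog`** — a miniature RAD assembler: within-/across-sample greedy
   clustering with IUPAC consensus, shared-heterozygosity and similarity
   paralog purges (90% identity over ≥55% of length), low-complexity and
   mitochondrial screens, redundancy synonymisation, candidate selection
   (≥10/≥20 individuals) and 120-mer probe tiling at 60 bp step.
3. **`readproc`** — quality trimming (mean Phred ≥33), canonical k-mer
   contaminant screening, best-overlap read merging (≤220 bp fragments),
   dual-index demultiplexing.
4. **`capture`** — seed-and-extend mapping with margin-based maQ (≥5
   retained), PCR-duplicate marking by fragment identity (locus, start,
   insert length, strand), assembly-based reference construction (90%
   clusters, ≥40 reads, 120 bp/85% overlap merge, reciprocal-best-hit
   on/off-target labels), per-sample coverage/GC/heterozygous-read-rate
   metrics.
5. **`variants`** — diploid likelihood genotyping with the hard-filter
   battery (QD <4, MQ <18, QUAL <40, FS >60, <8 samples at 5X, read-position
   rank z < −12, biallelic only) and ts/tv / deamination summaries.
6. **`damage`** — empirical deamination profiles with exponential fit
   f(p) = δ·λ^(p−1), <2.0X sample exclusion, and the directional C→T/G→A
   site filter applied uniformly to modern and museum samples.
7. **`popstats`** — missing-data/MAF site filters, LD pruning,
   **Weir–Cockerham (1984) Fst** from variance components
   (θ = Σa / Σ(a+b+c)), locus-sharing histograms, allele-frequency-scaled
   PCA.

A `radcapkit` command-line interface wraps each stage
(`simulate`, `readproc`, `catalog`, `probes`, `map`, `refbuild`, `call`,
`damage`, `qc`, `stats`) over standard text formats (FASTQ/FASTA, TSV
sample sheets, SAM, VCF 4.2).

## Worked example

Simulate a two-species capture experiment with 20% PCR duplicates, map,
de-duplicate, genotype and summarise:

```python
from radcapkit.simdata import SimulationConfig, simulate_truth, emit_reads
from radcapkit.readproc import merge_all
from radcapkit.capture import map_reads, mark_duplicates
from radcapkit.variants import call_variants, hard_filter, variant_summaries
from radcapkit.popstats import (sites_to_matrix, site_filters, ld_prune,
                                wc_fst, diversity_and_sharing)

cfg = SimulationConfig(seed=42, n_loci=60, n_individuals_per_species=8,
                       species_divergences={"edw": 0.02, "ver": 0.05},
                       coverage_mean=30, duplicate_fraction=0.2)
truth = simulate_truth(cfg)
pairs, sheet = emit_reads(truth, cfg, "capture")
merged, _, counts = merge_all(pairs)

reference = {r.id: r.seq for r in truth.ancestral_loci}
alignments = []
for sample in sorted({p.read1.id.split(":")[1] for p in pairs}):
    reads = [m for m in merged if m.id.split(":")[1] == sample]
    recs, _ = map_reads(reads, reference, sample=sample)
    alignments.extend(recs)
mark_duplicates(alignments)

sites = call_variants(alignments, reference)
passed, fails = hard_filter(sites)
samples = [s for s, _ in cfg.individuals]
matrix = ld_prune(site_filters(
    sites_to_matrix(passed, samples, dict(cfg.individuals))))
fst = wc_fst(matrix)
div = diversity_and_sharing(matrix)
```

which prints, when each step is reported:

```
22764 read pairs from 60 loci, 767 ddRAD dropout events recorded
merged 22763/22764 pairs
22728 alignments, duplicate rate 0.205
8127 candidate sites, 549 PASS {'depth': 183, 'QUAL': 5858, 'biallelic': 3408, 'QD': 6481}
ts/tv = 0.65
57 SNPs after MAF/missing/LD pruning; global Fst = 0.510; mean observed het = 0.14
```

Reading the numbers: the duplicate rate (0.205) recovers the injected 0.2;
the hard filters discard low-confidence and multi-allelic candidates
(counts per filter shown); ts/tv ≈ 0.65 sits near the 0.5 expectation of
the equal-rates mutation model used by the simulator (real data runs
higher); and with two species at 2% and 5% divergence most passing SNPs
are species-diagnostic, hence the large Weir–Cockerham θ — a panmictic
pool gives θ ≈ 0 (see the reproduction script).

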