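# Methods

## The quantification model

A sample of volume *V* liters is filtered, and three foreign
internal-standard genomes are added at known molecule counts *S*<sub>a</sub>
immediately before DNA extraction. After sequencing, each standard's mean
depth of coverage *S*<sub>cov</sub> (total bases mapped / genome length)
yields a per-standard recovery ratio *R*<sub>cov</sub> = *S*<sub>cov</sub> /
*S*<sub>a</sub>, in units of ×-coverage per molecule added, so that any
reference genome observed at coverage *M*<sub>cov</sub> was present at
*M*<sub>a</sub> = *M*<sub>cov</sub> / *R*<sub>cov</sub> molecules, and at
*M*<sub>a</sub>/*V* genomes L⁻¹. The read-count formulation,
*r*<sub>read</sub> = reads / (genome length × *S*<sub>a</sub>), plays the
same role for gene-level counts: a taxon's genome equivalents are its
single-copy marker (recA-type) reads divided by (marker gene length ×
*r*<sub>read</sub>). For constant read length ℓ, *R*<sub>cov</sub> =
*r*<sub>read</sub> × ℓ holds exactly, which the tests assert to
floating-point precision.

Assumptions: standards and sample DNA are extracted, fragmented, sequenced
and mapped with equal efficiency per base; one marker copy per genome (so
one marker read packet ≡ one genome); polyploidy and replication forks are
ignored. Losses during extraction and library preparation affect standards
and sample alike and therefore cancel — that is the point of spiking before
extraction.

**Aggregation across standards.** Per-standard ratios are combined by
arithmetic mean, with the per-standard values retained for QC; equal
weighting keeps a single aberrant standard from dominating, and a standard
with zero recovered signal is dropped from the mean with a warning rather
than zeroing the calibration. If *all* standards recover nothing the ratio
is 0 and flagged unusable.

**Completeness.** MAG abundance divides coverage by the *assembled* MAG
size, matching how the standards themselves are calibrated; mean depth over
the assembled fraction is an unbiased per-base depth regardless of
completeness, so no correction is applied by default. An explicit
`completeness_percent` option averages coverage over the
completeness-corrected size instead (scaling the estimate by
completeness/100) for users who want reads-per-complete-genome semantics.
Separately, `estimated_complete_size` reports assembled size /
(completeness/100) — e.g. 1.99 Mbp at 95.29% complete → 2.09 Mb.

## Gene copy numbers per genome equivalent

For a taxon *T* and gene role *g* (nitrate reductase *narB*, nitrite
transporter *focA*, ammonium transporter *amt*), reads are first restricted
to those whose taxonomic label equals *T* in **both** annotation systems
(exact match after case-folding; no rank-aware logic). This dual-consensus
filter discards any read misannotated in either system, at the cost of also
discarding correctly-but-inconsistently annotated reads — a conservative
trade the copy-number ratio is robust to, since numerator and denominator
are filtered identically.

With length normalisation on (default), each read contributes
1/(its subject gene's length), so

copies per genome equivalent = Σ<sub>gene reads</sub> 1/ℓ<sub>gene</sub> ÷
Σ<sub>marker reads</sub> 1/ℓ<sub>marker</sub>,

which reduces to (gene reads / gene length) / (marker reads / marker
length) for uniform lengths and is exactly unbiased under the simulator's
sampling model. The un-normalised plain read ratio is available behind the
same flag (off), since some depth-profile analyses use the raw ratio; both
are reported by the CLI. log₂-scaled values accompany the linear ones;
**log₂(0) is left undefined** — a sample with zero gene reads keeps
copies = 0 and is excluded from log-space output with a recorded reason, and
the wide matrix renders it as a missing cell in log space but 0 in linear
space. Zero *marker* reads is a different failure (the whole ratio is
undefined) and is flagged distinctly.

## The synthetic community generator

The generator emulates the sampled system end to end: community genomes at
known cells L⁻¹ (one genome per cell), a volume filtered, spiked standards
at known molecules, and sequencing as multinomial read allocation with
per-source probability ∝ molecules × genome length. Read starts are uniform
on [1, L − ℓ + 1] (full-length reads, no circularity), so total bases are
conserved exactly. A read is assigned to a gene iff its midpoint lies inside
the gene interval; genes are placed non-overlapping with an edge margin of
at least one read length, so the expected fraction of a genome's reads
hitting a gene of length *l* is exactly *l*/(L − ℓ + 1) — proportional to
plain gene length with a denominator common to every gene on the genome.
This midpoint-rule idealisation replaces translated homology search
deliberately: it makes the length-normalised estimators exactly unbiased
and keeps every oracle analytic. Annotation error corrupts, with the
configured probability, exactly one of a read's two taxonomy labels
(system chosen uniformly; replacement is the cyclically next label in that
system's pool), which is precisely the error mode the consensus filter
rejects.

What the generator does **not** model: sequencing error and quality scores,
paired-end structure, GC or fragmentation bias, homologous sequence between
community members, chimeric or duplicate reads, effective gene length
extension by partial alignments. Passing tests therefore demonstrate the
estimators' correctness under ideal mapping and annotation, not robustness
to those real-data artifacts; on real data the practitioner's mapping and
annotation pipeline owns that layer, and its tabular outputs are this
package's inputs.

**Default study conditions.** The default community mirrors a subarctic
HNLC surface sample: a focal genus at 5 × 10⁷ cells L⁻¹ (the
deep-chlorophyll-maximum peak scale) dominated by two populations carrying
two ammonium transporters and no nitrate/nitrite genes, a minor
nitrate/nitrite-capable ecotype at 6% of the genus, two background genomes
with full nitrogen gene sets, three standards at 1.5–2.5 × 10⁷ molecules,
2 L filtered, 150 bp reads. Genome sizes are scaled down (50 kb community
members, 20 kb standards, ~1 kb marker) so that simulations at 10⁵–3 × 10⁵
reads give per-genome marker counts of ~10³ — the same counting statistics
regime as real libraries — while running in seconds; every estimator is
scale-free in genome length, so the scaling changes variance, not
expectation.

## Downstream statistics

* **f-ratio**: nitrate uptake / (nitrate + ammonium uptake); undefined (and
  rejected) when both rates are zero.
* **N:Fe**: nanomolar nitrate / nanomolar dissolved iron; regressions use
  log₁₀(N:Fe) as the predictor, OLS via statsmodels, two-sided slope
  p-value; stations with nonpositive iron are excluded.
* **Group comparison**: Welch's unequal-variance t test, two-sided.
* **PCA**: columns z-scored (population sd) since copy numbers and N:Fe are
  on different scales; deterministic signs by forcing each component's
  largest-magnitude loading positive; variance explained renormalised to
  sum to 1 over returned components.
* **Agreement**: OLS of estimate on reference plus the mean estimate/
  reference ratio as a direct bias measure against the 1:1 line.
* **GC%**: 100 × (G+C)/(A+C+G+T), ambiguity codes excluded from numerator
  and denominator (standard assembly-stats convention); size counts non-gap
  bases; case-, wrap- and order-invariant.

## Numerical and interface choices

* All tables are TSV with `#` comment lines; every output file carries a
  header comment with tool version, config hash and seed; JSON summaries
  embed the same provenance keys.
* The assignment table's first six columns are (read_id, subject_gene_id,
  subject_genome_id, role, taxon_a, taxon_b); a trailing
  `subject_gene_length` column carries the length needed for
  normalisation. Reads in no annotated gene appear with role `other` and
  gene id `intergenic`, so per-genome read counts are conserved.
* Determinism: one integer seed fixes community construction, read
  sampling and label corruption (separate child streams); identical seeds
  give byte-identical outputs.
* Degenerate inputs fail loudly with named entities: a standard missing
  from the depth table, a zero-length reference, an oversized gene
  complement, duplicate (sample, role) matrix entries.

## Problem sizes used in the shipped checks

Simulation-backed tests and the acceptance script run the default community
at 3 × 10⁵ reads, two-population designs at 1–2 × 10⁵ reads, an 8-sample
concentration ladder at 10⁵ reads per sample, 100 seeded replicates of the
25-station regression, and a 23-sample batch at 5 × 10³ reads for the
exclusion bookkeeping — sizes chosen so the whole battery completes in
well under a minute while keeping relative sampling errors in the few-percent
range the tolerances assume.

## Known limitations

Single-copy-marker counting inherits any true marker copy-number variation;
the consensus filter's exact-match semantics require both taxonomy systems
to use the same genus-level label string; the completeness-corrected
abundance variant assumes the missing genome fraction recruits no reads;
and the generator's idealised mapping means real-data biases (GC,
duplicates, homology) must be handled upstream.
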