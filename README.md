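# spikequant

Internal-standard ("spike-in") quantitative metagenomics for absolute
abundances of microbial populations and per-genome gene content.

Ordinary shotgun metagenomics yields relative abundances only. If a known
quantity of foreign genomic DNA — internal standards — is added to a sample
before extraction, the standards' sequencing recovery calibrates the whole
library and every population can be expressed in absolute, volumetric units
(genomes per liter of water filtered). `spikequant` implements that
calibration and the analyses that sit on top of it, for microbial ecologists
and biological oceanographers working with spiked metagenome datasets
(marine time series, HNLC-region surveys, and similar).

## The model

For each internal-standard genome spiked at a known molecule count *S*<sub>a</sub>,
mean depth of coverage *S*<sub>cov</sub> (total bases mapped divided by genome
length) gives the **coverage-based recovery ratio**

> *R*<sub>cov</sub> = *S*<sub>cov</sub> / *S*<sub>a</sub>

and any genome (e.g. a metagenome-assembled genome, MAG) observed at mean
coverage *M*<sub>cov</sub> in the same library was present at

> *M*<sub>a</sub> = *M*<sub>cov</sub> / *R*<sub>cov</sub>

molecules in the sample; dividing by the volume filtered gives genomes L⁻¹.
The read-count analogue, *r*<sub>read</sub> = reads / (genome length × *S*<sub>a</sub>),
converts single-copy marker gene (recA) read counts into **genome
equivalents** of a taxon: genome equivalents = marker reads /
(marker length × *r*<sub>read</sub>). For constant read length ℓ the two
calibrations obey *R*<sub>cov</sub> = *r*<sub>read</sub> × ℓ exactly.

On top of this the package computes taxon-restricted **gene copy numbers per
genome equivalent** — the ratio of a gene's length-normalised read abundance
to the marker's, restricted to reads whose taxonomy agrees in *both* of two
annotation systems (e.g. NCBI and GTDB; the dual-consensus filter) — plus the
downstream ecology: f-ratios, completeness-corrected genome sizes, assembly
statistics, copy-number-versus-log₁₀(N:Fe) regression, Welch's t test,
standardized PCA, and estimate-versus-reference agreement. A synthetic
community generator with complete ground truth (known cells L⁻¹, known
spike-in molecules, configurable annotation error) backs every estimator
with a testable oracle.

## Worked example

```python
import spikequant as sq

design = sq.default_design(seed=1, total_reads=300_000)
genomes, standards, truth = sq.build_community(design)
_, assignments, depths = sq.simulate_sample(genomes, standards, truth,
                                            with_sequences=False)

ratio = sq.recovery_ratios(depths, assignments, standards)
meta = sq.SampleMetadata("station_p_5m", volume_filtered=2.0)
total = sq.marker_abundance(assignments, 1000, ratio, meta, taxon="Synechococcus")
print(f"recovery: R_cov = {ratio.r_cov:.3e} x-coverage per molecule")
print(f"total Synechococcus: {total.per_liter:.3e} genomes/L (truth 5.0e7)")
for mag in ("syn_sp1", "syn_sp2"):
    est = sq.mag_abundance(depths, mag, ratio, meta)
    print(f"{mag}: {est.per_liter:.3e} genomes/L")
for role in ("nitrate_reductase", "nitrite_transporter", "ammonium_transporter"):
    res = sq.copy_number(assignments, "Synechococcus", role)
    print(f"{role}: {res.copies_per_genome:.3f} copies per genome equivalent")
```

prints

```
recovery: R_cov = 2.112e-06 x-coverage per molecule
total Synechococcus: 4.962e+07 genomes/L (truth 5.0e7)
syn_sp1: 2.810e+07 genomes/L
syn_sp2: 1.923e+07 genomes/L
nitrate_reductase: 0.062 copies per genome equivalent
nitrite_transporter: 0.053 copies per genome equivalent
ammonium_transporter: 2.038 copies per genome equivalent
```

The default community places the focal genus at 5 × 10⁷ cells L⁻¹; the
marker-based estimate lands within 1% of that truth, the two dominant
populations are recovered at their designed concentrations via coverage, the
ammonium-transporter copy number reads out near the two copies built into
each dominant genome, and the nitrate-reductase copy number reads out near
0.06 — the one-copy minor ecotype making up 6% of the population. A
subcommand CLI wraps the same pipeline:

```sh
spikequant all --seed 1 --outdir out/      # simulate -> standards -> quantify
                                           #   -> gene-copy -> stats
spikequant quantify --assignments a.tsv --depths d.tsv --truth t.tsv --out ab.tsv
```

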