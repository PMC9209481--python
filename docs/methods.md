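# Methods

## Scope and data model

The package analyses somatic mutation calls from deep targeted sequencing of
normal epithelia. It consumes a gene panel (coding sequences with single-base
flanking context and a gene-set label: driver, immune or housekeeping), a
mutation table (sample, gene, 1-based CDS position, ref/alt, VAF, optional
phase tag), a reference mutation catalogue used for substitution-class
priors, an impact-score table, a sample sheet and, for the consensus module,
barcoded amplicon reads. Variant calling itself is out of scope: the pipeline
starts from a called mutation table (or a minimal VCF).

Coordinates are 1-based within the CDS on the coding strand; trinucleotide
context is taken on the coding strand (edge positions use the stored flanks)
and only then collapsed onto the 96 pyrimidine-centred substitution classes.
Preserving orientation before the collapse is what allows the
transcriptional strand-bias analyses.

## Consequence annotation and phase merging

Consequences come from the standard genetic code: synonymous (amino acid,
including stop, unchanged), nonsense (non-stop → stop), stoploss (stop →
non-stop) and missense. Stop-loss changes count as nonsynonymous but belong
to neither the missense nor the nonsense submetric; this is configurable in
site counting but is the default everywhere.

Mutations in the same sample and gene within 10 bp of each other (inclusive)
are flagged as proximal. Whether two flagged calls were observed on the same
reads is carried by a machine-readable `phase_tag` (replacing manual
curation); runs of adjacent same-tag SNVs are merged into DNV/MNV records
whose VAF is the arithmetic mean of the members — the mean is our choice
(symmetric and order-independent); no convention is established for merged
VAFs. Absent tags mean "not co-read".

## dN/dS

For each scope (gene, gene set, or all genes pooled) every possible
single-base substitution of the CDS is enumerated and assigned a class and a
consequence, giving per-class synonymous/missense/nonsense/stop-loss site
counts. With class priors `P_i` (raw class frequencies of a reference
catalogue, no pseudo-counts),

    dN/dS = (n/s) / (Σ N_i P_i / Σ S_i P_i).

The one-sided binomial test treats each observed mutation as an independent
draw with nonsynonymous probability `π = Σ N_i P_i / (Σ N_i P_i + Σ S_i P_i)`
and computes `P[X ≥ n]` for `X ~ Binomial(n+s, π)`. dMiss/dS and dNons/dS
replace the numerator sites and counts accordingly (s unchanged). Per-gene
tests use gene-specific site counts. When a scope has no synonymous
mutations the ratio is reported as undefined (NaN) but the binomial test
still applies. BH adjustment is applied per metric within each grouping
family (all per-gene dN/dS p-values together, etc.); calls use q < 0.1. The
family choice is a documented convention and configurable through the
`fdr`/grouping arguments.

Using raw catalogue class frequencies as per-site priors implicitly assumes
the catalogue's trinucleotide composition resembles the analysed panel's;
this is the method's own approximation. On the synthetic panels used here
(uniform base composition) the induced bias of the neutral dN/dS is ~3%,
verified by the calibration tests.

## Impact-score selection

Scores in [0, 1] are an input artifact (per gene, position and alternate
base), standing in for an external predictor such as PolyPhen-2; computing
real predictor scores is out of scope. For each scope the observed scores of
nonsynonymous SNVs present in the table are compared to an expected-score
sample: random point mutations drawn among the scope's *scored*
substitutions with probability proportional to the prior of their class
(default 100,000 draws). Restricting both sides to scored substitutions
keeps observed and null comparable; sampling all point mutations instead is
available by supplying a fully scored table. The one-sided Wilcoxon rank-sum
test (exact for tie-free samples with both sides ≤ 50, tie-corrected normal
approximation otherwise) asks whether observed scores are stochastically
larger; the effect size is Δ = median(observed) − median(expected). Scopes
without scored observed mutations are omitted and listed in a coverage
report. BH calls at 10% FDR as above.

## Clonality

Clone size (mm²) = 2 × VAF × biopsy area (mm²), assuming diploid cells
heterozygous for the mutation (the factor 2 is configurable in principle;
copy-number-aware corrections are out of scope). Circular punch biopsies of
diameter d have area π(d/2)²: 19.63 mm² at 5 mm, 3.14 mm² at 2 mm, 0.785 mm²
at 1 mm. (Note that a "detectable clone" quoted as these same areas equates
the smallest *fully clonal* detectable patch with the biopsy area itself,
not with 2 × VAF_min × area; the package reports biopsy areas as such.)
Each called mutation in a positively selected gene counts as one clone;
nested or overlapping clones are not resolved, so occupancy
(100 × Σ clone sizes / Σ sampled area) is reported unclamped with a warning
above 100%. Samples without a known area are excluded from clone inference
and listed in the report. Clone frequency is (clones / Σ area in mm²) × 100
per cm²; algebraically, occupancy = frequency × mean clone size / 100.

## UV diagnostics and signatures

A C>T substitution (after strand normalization, also G>A) is in dipyrimidine
context if either neighbour of the mutated pyrimidine, on the
pyrimidine-bearing strand, is C or T; sidedness is deliberately symmetric.
Strand bias compares counts of substitutions with the pyrimidine on the
coding vs template strand; two Poisson counts with equal exposure are
compared conditionally, i.e. an exact binomial test of the coding count out
of the total against 0.5 — two-sided for the overall C>T bias, one-sided
(greater) for the directional coding-strand CC>TT claim. Both choices are
arguments of the respective functions.

Signature refitting solves a non-negative least-squares problem between the
spectrum's class frequencies and the signature matrix columns and
renormalizes exposures to proportions. The shipped signature matrix is
synthetic (a UV-like column concentrated on C>T with a 5' pyrimidine, a flat
background, a C>A-heavy and a T>C-heavy column) so that no external
catalogue needs downloading; real matrices (e.g. COSMIC) can be supplied as
TSV with class labels in the first column.

## Barcode consensus

Families need ≥ 10 reads. Families of 10–20 reads must be unanimous; a
family of exactly 20 falls under the unanimity rule (the relaxed rule starts
strictly above 20). Families of > 20 reads accept the plurality read
sequence if it accounts for ≥ 90% of reads; plurality ties reject. Identity
is whole-read by default; a per-base majority mode with the same thresholds
is available behind a flag. A single discordant read in a 10–20-read family
rejects the family (strict unanimity). Hotspot VAF is the fraction of
accepted consensus reads carrying the alternate base at each hotspot
position. The bundled hotspot definitions are synthetic stand-ins for the
RPL13A/DPH3 promoter amplicons: names carry the genomic windows of the real
assays, but the reference sequences are generated (containing the CTTCCGG
ETS motif with its CC dinucleotide as the mutant positions).

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions
the rest of the package is validated under. Defaults: a 153-gene panel (101
driver, 32 immune, 20 housekeeping) of random CDS of 150–600 codons; 12
samples from 5 mm punch biopsies with 76 mutations each; VAFs log-uniform
over [0.0023, 0.11]; a substitution spectrum mixing a UV-like class profile
with a uniform background (weight 0.5, giving ~55–60% C>T with ≳95% of them
at dipyrimidines); a 1.24× coding-strand weight for pyrimidine-centred
substitutions; phased CC>TT dinucleotide pairs injected at rate 0.04 per
mutation with the dipyrimidine on the coding strand with probability 0.824;
driver-gene nonsynonymous acceptance weight w = 2 plus a weight-preserving
tilt of driver missense mass toward high-impact substitutions
(`impact_weight = 4`, i.e. factor 1 + 4·score renormalized within driver
missense so that w alone controls the nonsynonymous excess).

Mutations are drawn class-first: a substitution class with the configured
probability, then a site uniformly within the class, then selection
reweighting — so the neutral limit w = 1 is exact, and priors estimated from
a generated catalogue recover the configured class weights exactly. The
reference catalogue uses an independent random stream from the study
mutations, mirroring the decoupling of tumour-derived priors from the
analysed calls. Impact scores follow Beta distributions configurable per
gene set (default Beta(0.5, 1.5) for all genes: mostly benign, median ≈
0.09). Barcoded reads derive from mutant or wild-type templates per the true
hotspot VAF; the default error model gives each read one random substituted
base with probability 0.005 ("per-read" mode; an independent per-base mode
is available). Family mutant status uses one uniform draw per family, making
VAF estimates monotone in the true VAF under a shared seed.

What the generator does **not** emulate: non-uniform mutation burden across
genes (real burden concentrates in a few drivers like *NOTCH1*, so per-gene
power at desk scale is limited and set-level statistics are the primary
readout); gene length and composition heterogeneity of real panels;
sequencing depth, mapping and calling artefacts; copy-number changes
invalidating the diploid VAF→size conversion; clone nesting/overlap; and
realistic signature catalogues. Passing tests therefore demonstrate the
statistical machinery and its calibration, not performance on real reads.

## Numerical and testing choices

- Deterministic sub-streams per generator stage are spawned from the single
  config seed (`numpy` SeedSequence); every output is a pure function of
  (config, seed).
- NNLS refitting is convex, so no initialisation or tie-break issues arise;
  all-zero spectra and zero signature columns are rejected.
- Degenerate inputs raise informative errors rather than returning NaN:
  empty catalogues, zero strand counts, zero synonymous prior mass, empty
  observed score sets, empty barcode families.
- Exact rank-sum enumeration is used only for tie-free samples of ≤ 50 on
  both sides; larger or tied samples use the tie-corrected normal
  approximation.
- Calibration and power suites use panels of ~8–12 genes of 80–150 codons
  with 50 replicates of 500–600 mutations, and consensus suites use 5,000
  (recovery) / 10,000 (suppression) families — sizes chosen so the full test
  suite runs in well under a minute per suite while keeping Monte-Carlo
  error far below the tested tolerances.

## Known limitations

- Per-site priors from raw class frequencies carry the context-composition
  approximation described above.
- The binomial selection null ignores overdispersion between samples and
  recurrent-site artefacts.
- The clone model counts each called mutation as one clone and cannot
  resolve nested lineages; occupancy can exceed 100% in dense inputs.
- Indels are out of scope end to end; the phase-merge rule handles only
  substitution runs.
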