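# Methods

## Scope and coordinate model

All intervals are 0-based, half-open, on the forward genomic strand; GFF3
(1-based, closed) is converted at the boundary and converted back on
write. Count tracks are strand-specific dense arrays of read-end counts.
Every per-gene analysis works on a transcript-local 5'→3' view (minus-strand
genes are reverse-complemented and reindexed on extraction), so the
statistics below are strand-agnostic.

## PARS score

`PARS(i) = log2((V1_rpM(i) + 1) / (AT1_rpM(i) + 1))`, with each library
scaled to reads per million mapped before the pseudocount is applied. The
+1 on the rpM scale damps low-coverage positions and avoids division by
zero; it is configurable. Replicates are combined by position-wise count
summation before scoring. Counts are assigned to the read's first (5')
nucleotide — the position immediately 3' of the cleavage bond — with no
half-position bookkeeping.

Masking: adenines carry no single-strand evidence (RNase A cuts C/U, T1
cuts G) and are always missing. Positions with zero counts in both
digestions score 0 and are tagged `no_data`; they stay in mean profiles but
are excluded from GC-on-nonzero computations, since a zero score there is
an artifact of no coverage rather than balanced cleavage.

Transcript load = (ΣV1 + ΣAT1 counts over the transcript, all replicates) /
effective length (annotated length minus masked nucleotides). The
coverage filter keeps load ≥ 1.0; the boundary is inclusive — the threshold
is stated without strictness anywhere, and inclusivity is the choice that
keeps a transcript whose evidence exactly meets the stated minimum.

## Metagene profiles

Genes are aligned at the first nucleotide of the start or stop codon
(offset 0; negative offsets 5'). Per offset the profile records the mean
over contributing (non-missing) genes, the number contributing, and the GC
fraction over positions with non-zero, non-missing scores. The window is a
parameter (default ±100 nt): wide enough to cover the UTR features of
interest (docking window at −30..−12, pre-stop structure) with margin,
since no canonical width exists.

## Pausing statistic

A structured stretch is any 10-nt CDS window with ≥ 6 positions of positive
PARS (missing adenines count as non-positive — the conservative choice).
Overlapping qualifying windows merge into one maximal stretch by extent
overlap (starts i, j merge when j < i + window); merging prevents one
physical structure from being counted once per overlapping window and can
be disabled. A mean-score variant (window mean ≥ t with ≥ k non-zero
entries) is provided for sensitivity analyses.

For each stretch, RPF1 and RPF2 are raw footprint 5'-end counts over the
29 nt immediately 5' and 3' of the merged extent; both flanks must lie in
the CDS. L1 = RPF1/(RPF1+RPF2) and L2 = 1 − L1, so L1 + L2 = 1 exactly for
every evaluable stretch; stretches with no flank reads are flagged
unevaluable. The downstream flank is 29 nt to mirror the upstream flank
(the flank length is exposed as a parameter). Pausing calls are stretches
whose L1 percentile rank (strict) exceeds 80 with L1 > L2. The rank
statistic is L1; L1/L2 and L1−L2 order identically since L1+L2=1. Ties at
the boundary fail the strict inequality. Note that under a symmetric null
the top quintile of L1 lies almost surely above 0.5, so the expected
selected fraction is ≈ (100 − percentile)%, not half of it.

Transmembrane-domain distance: codons (= amino acids) from the last residue
of the nearest upstream helix to the codon holding the stretch's first
nucleotide; negative when the stretch precedes every helix. Helix
coordinates are an input — no topology prediction is performed.

## Shine–Dalgarno scan

Every 8-mer window of the ≤ 25 nt immediately upstream of the start codon
is hybridized against the anti-SD (3'-UCCUCCAC-5', configurable) with the
nearest-neighbor RNA–RNA duplex model (ViennaRNA `duplexfold`, Turner 2004
parameters, 37 °C, intermolecular pairing only; no intramolecular folding
of the upstream region). Each window's energy is assigned to its 8th
(3'-most) base; the global minimum defines the SD, with ties resolved to
the 3'-most window — where functional SDs act. Spacing counts nucleotides
strictly between the 7th SD base and the start codon, which puts the
canonical optimum at 7–8 nt. Classes: strong < −8.5, medium [−8.5, −4.4),
weak [−4.4, −2), none ≥ −2 kcal/mol; the half-open boundaries make the
partition total. Absolute energies shift by a few tenths of kcal/mol
between parameter sets, so comparisons against published values carry a
±0.3 kcal/mol tolerance; under this model the weak AAGG motif in a
non-complementary context scans to −2.6 kcal/mol.

Controls: exhaustive enumeration of all 4⁸ = 65,536 8-mers, or i.i.d.
uniform-base sampling, with seeded subsampling. Translation efficiency is
RPF rpkM per mRNA rpkM; its association with SD strength is reported as a
Pearson correlation with MHE and a chi-square of the top-30%-translated
genes across the four classes against class-size expectations.

## Periodicity

The DFT is taken on the cross-gene mean profile (per-gene spectra are
available behind a flag), mean-subtracted, over inclusive offset regions —
e.g. 10..99 nt downstream of the start (90 positions, preserving frame and
excluding initiation). The one-sided power is normalized so that its sum
over non-zero frequencies equals the variance of the input (Parseval),
making spectra comparable across region lengths. Frame analysis bins
footprint 3'-ends of 23–25-nt reads (per length) mapping within the CDSs
of the most expressed genes by position modulo 3 in the frame fixed by the
annotated stop codon; deviation from uniform is KL divergence, base 2 —
bits, with KL(delta) = log2 3 ≈ 1.585 as the natural ceiling.

## Replicate noise model

With n total reads for a gene split between two replicates, the ratio
r1/n has SD(n) = sqrt(p(1−p)/n + s²): binomial counting noise plus a
constant excess (biological) variance s². (The expression is a variance
sum; this is the only reading with the correct binomial limit.) Genes are
binned logarithmically by n (default 20 bins; bins with < 10 genes drop)
and the bin statistic is the sample SD of the ratio. The SDs identify p
only through p(1−p) — the curve is symmetric in p ↔ 1−p and nearly flat
around 0.5 — so p is estimated as the pooled read split Σr1/Σn (its
maximum-likelihood estimator under binomial partitioning) and s alone is
fit to the bin SDs by least squares. Technical replicates are dominated by
counting noise and fix s = 0.

The read-count threshold is the smallest n with p(1−p)/n ≤ α·s² (technical
variance at most α of biological; default α = 0.05), reported both as total
and per-replicate (n/2) counts. α is exposed rather than hard-coded: for a
fit of p = 0.47, s = 0.16, a 120-total-read cutoff corresponds to α ≈ 0.08,
so published cutoffs cannot be assumed to encode exactly 5%.

## Termination

Readthrough = mean per-nt footprint density over offsets +3..+27 (inclusive,
25 positions) past the stop codon's last base, divided by the mean per-nt
CDS density. Genes in the overlapping operon class are excluded
(terminating and initiating ribosomes are indistinguishable there), as are
genes under the coverage threshold (default 60 reads) or with a 3'UTR
shorter than the window. The downstream in-frame stop-codon frequency scans
a 9-codon (27-nt) window — matching the readthrough window; the true
window behind published frequencies is unstated, so it is a parameter and
flagged as an interpretation. Stop-anchored metagenes stratify by stop
codon and/or operon context, with Mann–Whitney comparisons of per-gene
mean PARS over a pre-stop window (default −30..−4 nt, covering both the
structured block a few nt 5' of the stop and the footprint-enrichment
zone).

## Cleavage signatures

Input positions mark the nucleotide 5' of the scissile bond (offset 0);
published site lists do not always state their convention, so a global
offset shift is exposed. Site-anchored profiles average PARS and GC
(non-zero rule) over −w..+w with minus-strand sites flipped; base-frequency
matrices span −10..+10 with columns summing to 1. Class comparisons use the
per-site mean PARS over a region (default −8..+2 nt) on defined positions
only, requiring ≥ 5 defined positions per site, under a two-sided
Mann–Whitney test.

## Synthetic data: what it emulates, and what it does not

The generator is the package's test bed, not a sequencing simulator. One
chromosome carries operon and singleton transcription units on both
strands; "overlapping" operon junctions use positive gaps of 5–25 nt
(< 30 nt, the class boundary) because genuinely overlapping ORFs would have
to share sequence with independently planted features. Structure is a
binary paired/unpaired mask — no thermodynamic folding — with background
pairing probability 0.45, an extra +0.25 at codon position 1 (the planted
3-nt periodicity), a forced-unpaired docking window at −30..−12, one fully
paired 15-nt CDS stretch per gene (low-adenine sequence so the detector can
see ≥ 6 scored positions per window), a paired 6-nt block 4–8 nt 5' of the
stop for 70% of UAA genes, and optional RNase-E-like signatures (paired
−8..−2, A/U unpaired cut site).

Counts are independent Poisson draws per position (not multinomial per
transcript; library size is defined post hoc as the track total): V1 at
rate `coverage × abundance` on paired positions and ε on the rest; A/T1
likewise on unpaired G/C/U, never on adenines when ε = 0. Defaults —
20× coverage at the median gene, ε = 0.1 of the signal rate, log-normal
abundance (σ = 1) — put the median transcript load well above the 1.0
filter so the filter is exercised meaningfully. Footprints (23–25 nt)
place 5'-ends uniformly along the CDS, ×κ (default 4) over the 29 nt
upstream of a pause stretch for 15% of genes, with 3'-ends snapped to a
(0.7, 0.2, 0.1) frame distribution; UGA genes leak footprints into
+3..+27 at 5% of CDS density, UAA genes do not. Shine–Dalgarno elements are
rejection-sampled against the package's own scan so the planted class
labels are self-consistent by construction.

Deliberately absent: sequencing errors, adapters, rRNA contamination,
mappability structure, nuclease sequence preferences beyond base identity,
RNA folding kinetics, and coupling between structure and expression.
Passing tests therefore demonstrate that the statistics recover what they
are defined to measure under the stated noise model — not that real
libraries satisfy that model.

## Numerical choices and degenerate inputs

Percentile ranks use the strict ("percent below") convention; KS,
Mann–Whitney, chi-square and Pearson statistics come from scipy. The noise
fit is bounded least squares (s ∈ [0, 0.5]). Empty gene sets, empty site
lists, single-class chi-squares, zero library sizes, s = 0 thresholds and
regions outside profile windows raise errors; zero-coverage stretches,
genes without TM annotation and sites on unscored transcripts are flagged
or skipped with counts rather than silently dropped. Annotation records
whose CDS length is not a multiple of 3 are excluded once, with a warning,
and never reappear downstream. All stochastic stages consume explicit
seeds; the generator derives independent child streams from one seed, so
every output is byte-reproducible.

## Problem sizes

The test suite and worked examples use 15–200 genes (60–150 codons each),
20–50× probing coverage, 5,000 genes for noise-model recovery, and the
full 65,536-sequence enumeration for the 8-mer control; these sizes give
the property checks comfortable statistical margins while keeping any
single test in seconds.

## Known limitations

The L1 percentile selection is a ranking heuristic, not a calibrated test;
its selected fraction under the null tracks the percentile cut. PARS
scores conflate cleavage accessibility with structure and inherit the
usual in-vitro caveats. The MHE scan treats the upstream region as
unfolded and scores intermolecular pairing only. Operon contexts rely on
supplied operon identifiers; no operon inference is attempted. The noise
model describes replicate partitioning only — it is not a dispersion model
for differential analysis.
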