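# parstools

Analysis of the bacterial mRNA structurome from parallel analysis of RNA
structure (PARS), ribosome profiling and RNA-seq.

In PARS, protein-free mRNA is digested in parallel with the double-strand
specific RNase V1 and the single-strand specific RNases A + T1; sequencing
the cleavage fragments gives, per nucleotide, how often each position was
cut in either regime. The per-position structure score is

```
PARS(i) = log2( (V1_rpM(i) + 1) / (AT1_rpM(i) + 1) )
```

with counts scaled to reads per million mapped (rpM). Positive scores mark
preferentially double-stranded nucleotides. Adenines are masked (RNase A
cuts C/U, RNase T1 cuts G, so no single-strand evidence exists for A), and
transcripts are kept only when their *load* — combined probing readouts per
effective nucleotide — reaches 1.0.

On top of the score track the package implements the downstream statistics
used to interrogate structure-function relationships in *E. coli*:

* **Pausing** — CDS windows of 10 nt with ≥ 6 positive-PARS positions are
  structured stretches; footprint counts over the 29 nt flanks give
  `L1 = RPF1 / (RPF1 + RPF2)`, `L2 = 1 − L1`, and stretches above the 80th
  L1 percentile with `L1 > L2` are pausing calls (with transmembrane-helix
  distance annotation).
* **Shine–Dalgarno scan** — minimum hybridization free energy (MHE) of
  every 8-mer in the 25 nt upstream of a start codon against the 16S rRNA
  anti-SD (3'-UCCUCCAC-5'), via the nearest-neighbor RNA–RNA duplex model
  (ViennaRNA, 37 °C); classes strong (< −8.5 kcal/mol), medium (−8.5…−4.4),
  weak (−4.4…−2), none (≥ −2), plus exhaustive/sampled random 8-mer
  controls and translation-efficiency association.
* **Periodicity** — DFT power spectra of metagene PARS profiles,
  per-codon-position means, and the Kullback–Leibler divergence (bits) of
  footprint 3'-end reading frames from uniform.
* **Replicate noise model** — binomial read partitioning between
  replicates, `SD(n) = sqrt(p(1−p)/n + s²)`, fit over log-spaced
  total-count bins; inverts to a minimum read-count threshold.
* **Termination** — stop-codon-stratified metagenes, readthrough
  (footprint density at +3..+27 past the stop over the CDS mean), and
  downstream in-frame stop-codon frequencies by operon context
  (overlapping < 30 nt to the next operon gene, non-overlapping ≥ 30 nt).
* **Cleavage signatures** — site-anchored PARS/GC metagenes and base
  frequency matrices around endonuclease cut sites (RNase E cuts unpaired
  A/U-rich sites preceded by structure).

A seeded synthetic-data generator (`parstools.simulate`) builds a toy
genome with operons, UTRs, graded SD strengths, a known per-nucleotide
paired/unpaired mask with planted features (unpaired docking window at
−30..−12, paired CDS stretches and pre-stop blocks, cleavage signatures),
and all four count-track types — so every stage is testable against ground
truth without downloads.

## Worked example

```python
import parstools as pt
from parstools.simulate import SimConfig, simulate_dataset
from parstools.pausing import detect_stretches, l1_l2, select_pausing
from parstools.sd import mhe_scan
from parstools.noise import fit_noise, select_threshold, simulate_replicate_counts

ds = simulate_dataset(SimConfig(seed=11, n_genes=120))
pars = pt.pars_score(ds.v1, ds.at1, ds.truth.genome)
passing = pt.load_filter(ds.v1, ds.at1, ds.truth.transcripts)
print(f"transcripts passing load filter: {len(passing)}/{len(ds.truth.transcripts)}")

ev = [l1_l2(ds.rpf_5p, rec, s)
      for rec in passing for s in detect_stretches(pars, rec)]
sel, rep = select_pausing(ev)
print(f"structured stretches: {rep['n_evaluable']} evaluable, "
      f"{rep['n_selected']} pausing calls (KS p = {rep['ks_pvalue']:.3g})")

a = mhe_scan("C" * 10 + "AAGG" + "C" * 11)
print(f"SD scan: best 8-mer {a.best_8mer}, MHE {a.mhe} kcal/mol, "
      f"class {a.sd_class}, spacing {a.spacing} nt")

r1, r2 = simulate_replicate_counts(5000, p=0.5, s=0.15, seed=1)
fit = fit_noise(r1, r2)
print(f"noise fit: p = {fit.p:.3f}, s = {fit.s:.3f}, "
      f"threshold (alpha=0.05) = {select_threshold(fit, 0.05)} total reads")
```

prints

```
transcripts passing load filter: 120/120
structured stretches: 496 evaluable, 99 pausing calls (KS p = 0.0192)
SD scan: best 8-mer AAGGCCCC, MHE -2.6 kcal/mol, class weak, spacing 8 nt
noise fit: p = 0.505, s = 0.149, threshold (alpha=0.05) = 227 total reads
```

Every gene passes the load filter at 20× coverage; about a fifth of the
detected structured stretches clear the percentile cut (the generator
plants real pauses at 15% of genes, κ = 4); the AAGG weak-SD motif scans to
−2.6 kcal/mol; and the noise fit recovers the planted excess biological
standard deviation s = 0.15, translating into a ≈227-total-read threshold
at which counting variance is 5% of biological variance.

The same analyses run from the shell:

```sh
parstools simulate --seed 11 --out data/
parstools run --config run.yaml        # score, metagene, noise, pausing,
                                       # periodicity, sd, termination, cleavage
```

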