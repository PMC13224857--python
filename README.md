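# loopquant

Allele-resolved 4C-seq contact quantification with companion statistics for
allelic imbalance, bisulfite methylation, qPCR expression and smFISH
transcription-site calling — plus a synthetic-data module that generates
every input with known ground truth, so the whole pipeline is testable
without external downloads.

## What it does

- **`loopquant.locus`** — DNA sequences, SNV tables, restriction digests.
  Builds the double-digest fragment map (primary enzyme defines fragments,
  default DpnII `GATC`; secondary enzyme flags "blind" fragments lacking an
  internal site, default Csp6I `GTAC`). Coordinates are 0-based half-open;
  fragments begin at motif starts and tile the sequence exactly.
- **`loopquant.fourc`** — 4C-seq processing: anchored primer demultiplexing
  (≤2 mismatches by default), trimming to the primary restriction site,
  allele splitting at a mate-read SNV, fragment counting by exact boundary
  match, counts-per-million normalization over valid non-viewpoint
  fragments, centered rolling-mean smoothing (window 21), and region-level
  quantification by fragment midpoint.
- **`loopquant.allelic`** — allele assignment by comparing per-read
  alignment scores against the two parental genomes (ties unassigned),
  size-factor-normalized allelic proportions, a simplified
  negative-binomial Wald test of the allele × condition interaction, and
  per-CpG C/(C+T) methylation fractions from allele-split bisulfite
  amplicon reads.
- **`loopquant.qpcr`** — ΔCt, 2^−ΔΔCt fold changes relative to the
  geometric mean of a reference condition, mixed-model condition tests
  (replicate as random intercept; LRT statistic with an exact
  balanced-block reference), and Benjamini–Hochberg correction.
- **`loopquant.smfish`** — cell/nucleus segmentation (Otsu + watershed on
  max projections), 3D spot detection with iterative Gaussian-mask
  localization after local background subtraction, per-cell spot
  assignment, and active transcription-site calling at ≥2.5 RNA
  equivalents (single-RNA unit = median cytoplasmic spot intensity).
- **`loopquant.simulate`** — synthetic diploid locus (SNV every ~135 bp on
  average, shared restriction landscape), 4C libraries from a
  distance-decay + loop-enrichment contact model with allele-specific loop
  strengths, negative-binomial allelic count tables, Ct tables with
  per-replicate random intercepts, and 3D image stacks with planted
  Gaussian spots. Every generator is a pure function of its seed.

## Tests

```sh
python -m pytest -q tests/
```

Unit and property tests run per module; `tests/test_acceptance.py` holds the
full-size end-to-end criteria (digest oracle on 1,000 random sequences,
100k-read demultiplex conservation, contact-recovery and statistical
calibration simulations, smFISH planted-spot recovery, methylation hand
tallies). The whole suite takes a few minutes on one CPU.

## CLI

The `loopquant` entry point groups the analysis stages:

```sh
# generate a synthetic locus and 4C library with ground truth
loopquant simulate locus --seed 1 --out locus/
loopquant simulate 4c --seed 1 --n-reads 100000 --loop-129 4 --out lib/

# 4C processing
loopquant fourc demux lib/reads_R1.fastq lib/reads_R2.fastq \
    --viewpoint lib/viewpoint.json --out demux/
loopquant fourc count aln.tsv --fragments lib/fragments.bed --out counts.tsv
loopquant fourc track counts.tsv --fragments lib/fragments.bed \
    --viewpoint-fragment 384 --window 21 --out tracks/vp
loopquant fourc quantify counts.tsv --fragments lib/fragments.bed \
    --regions lib/regions.bed --viewpoint-fragment 384 --out quants.tsv

# allelic statistics
loopquant allelic assign scores.tsv --out assigned.tsv
loopquant allelic proportion counts_table.tsv --out proportions.tsv
loopquant allelic test counts_table.tsv --out imbalance.tsv
loopquant allelic methylation reads.tsv --cpg 10 --cpg 20 \
    --snp 0:A:G --snp 40:C:T --out methylation.tsv

# qPCR
loopquant qpcr foldchange ct_table.tsv --reference control --out fc.tsv
loopquant qpcr test ct_table.tsv --out tests.tsv

# smFISH
loopquant smfish detect fish.tif --out spots.tsv
loopquant smfish classify nuclear.tif fish.tif --probe MS2 --out calls.tsv
```

Alignment of trimmed 4C reads and of bisulfite amplicons is delegated to
external aligners in real use; the package consumes SAM/BAM (via pysam) or
plain alignment tables. A naive exact-match placer for synthetic reads
ships in `loopquant.simulate` for test closure only.

## Notes and caveats

- The allelic imbalance test is a deliberately simplified stand-in for a
  DESeq2-style analysis (moment-estimated common NB dispersion, Wald test
  with a small-sample t reference). It is validated by its own simulation
  calibration, not by equivalence to any external package.
- The synthetic contact model is a minimal power-law-decay × loop-factor
  construction, sufficient for recovering relative contact changes; it is
  not a polymer simulation.
- The synthetic diploid locus keeps SNVs out of restriction motifs so both
  haplotypes share one fragment map (sidestepping liftover); real F1
  genomes require per-allele maps and coordinate lifting.
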