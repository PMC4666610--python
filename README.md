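# gbmas — genotyping by multiplexed amplicon sequencing

`gbmas` is a toolkit for calling trait-linked marker genotypes from
multiplexed amplicon sequencing, the assay style used for marker-assisted
selection (MAS) in crops such as hexaploid bread wheat. Dozens of
locus-specific PCR amplicons (80–200 nt), each carrying one or more
annotated SNP/indel sites, are pooled per sample, tagged with a 10–12 nt
sample barcode through a two-step fusion-primer PCR, sequenced in bulk, and
genotyped from **favorable-allele read fractions**. The package covers the
whole desk side of the assay:

* **panel model** (`gbmas.panel`) — marker panel TSV + reference-amplicon
  FASTA, sample sheet with control annotations, full invariant validation;
* **fusion primers** (`gbmas.primers`) — first-PCR tailed primers
  (M13 tail + forward, truncated P1/B adapter + reverse) and second-PCR
  barcoded fusion primers (A adapter + barcode + M13 tail);
* **read simulator** (`gbmas.simulate`) — synthetic barcoded FASTQ with
  known truth: homoeolog co-amplification, substitution errors,
  per-marker depth variation, null alleles, contaminant spike-in;
* **read sorting** (`gbmas.sort`) — barcode demultiplexing and
  forward-primer marker assignment by prefix Hamming matching;
* **alignment** (`gbmas.align`) — deterministic banded affine-gap
  alignment of each read to its reference amplicon and per-site base
  extraction (A/C/G/T, or N for a gap/absence);
* **calling** (`gbmas.call`) — per-site A/C/G/T/N pileups, percent
  favorable allele, control-anchored cutoffs, genotype calls, call rates
  and cross-assay concordance.

## The model

A primer pair in a polyploid may amplify the target locus alone
(*genome-specific*), or together with one or two homoeologous copies
(*semi-* / *non-genome-specific*). With c co-amplified genome copies and
equal template amplification, a site's expected favorable-allele read
percentage is purely combinatorial:

    E[% favorable] = 100 · (# favorable alleles) / (2c)

which gives, for a target genome that is hom-favorable / het / hom-wild:

| specificity (c)       | AA  | AT   | TT |
|-----------------------|-----|------|----|
| genome-specific (1)   | 100 | 50   | 0  |
| semi-specific (2)     | 50  | 25   | 0  |
| non-specific (3)      | 33⅓ | 16⅔  | 0  |

Wild-type homoeologs dilute the signal, so no universal cutoff exists.
Instead each run must include known homozygous-positive controls; the
**minimum** percent favorable among the in-run control replicates is the
cutoff, and a sample is called homozygous positive when its percent is
**equal to or greater** than that cutoff, homozygous negative below it.
Sites with fewer than 10 accepted reads are no-calls. Dominant
presence/absence markers (indel or alien-fragment markers whose wild-type
allele yields no amplicon) are never negative: reads present means
positive, zero reads is a *putative* null (flagged — indistinguishable
from PCR failure).

## Worked example

Simulate a small run (6 samples × 4 markers, mean depth 120, substitution
rate 0.005, 3 % contaminant reads) and analyse it:

```bash
gbmas simulate --seed 42 --outdir sim --n-markers 4 --n-samples 6 \
    --depth 120 --depth-dispersion 0 --error-rate 0.005 --contaminant-fraction 0.03
gbmas run --fastq sim/reads.fastq --panel-tsv sim/panel.tsv \
    --panel-fasta sim/panel.fasta --sample-sheet sim/samples.tsv --outdir out
```

`out/report.txt` reconciles every read:

```
reads in:                 2969
  assigned to samples:    2875
  unassigned barcode:     94
  ambiguous barcode:      0
  assigned to markers:    2868
  unassigned marker:      7
  ambiguous marker:       0
  rejected alignments:    0
  reads in pileups:       2868
```

The 94 unassigned reads are the contaminant spike (no valid barcode);
7 more lost their primer prefix to simulated errors. `out/cutoffs.tsv`
shows the control-anchored cutoffs tracking primer specificity — ~99 %
for the genome-specific marker M001, ~48 % for semi-specific M002, ~25 %
for non-specific M003 (theory: 100, 50, 33⅓, each minus sampling noise at
depth ≈120):

```
marker_id  site_id  cutoff_percent      control_samples
M001       SNP18    99.16666666666667   S02,S05
M002       SNP24    48.739495798319325  S03,S04,S05
M003       SNP39    25.210084033613445  S03,S04,S06
```

and `out/genotype_calls.tsv` holds one call per sample/marker/site:

```
sample_id  marker_id  site_id  depth  percent_favorable  call                 caution_flag
S01        M001       SNP18    119    0.0                homozygous_negative  False
```

Against the simulator's truth table (`sim/truth.tsv`) every call in this
run is correct; `gbmas concordance` compares any two call tables the same
way (e.g. against uniplex KASP/STS results).

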