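# Methods

## Assay and data model

The package analyses multiplexed amplicon sequencing for marker-assisted
selection. Each marker is a locus-specific primer pair (17–21 nt each)
around an 80–200 nt amplicon with one or more annotated variant sites;
each sample is tagged by a 10–12 nt barcode through a two-step fusion PCR.
After the sequencer strips the A adapter, a read is

    barcode | M13 tail (21 nt) | forward primer | insert | revcomp(reverse primer) | P1/B adapter (23 nt)

The reference amplicon is the primer-to-primer sequence of a known
positive accession, so it includes both primer regions and carries the
favorable base at every annotated site; variant positions are 1-based on
that sequence, inclusive, and must not fall inside a primer region. The
`specificity → co-amplified copies` mapping is fixed: genome-specific → 1,
semi-specific → 2, non-specific → 3.

## Allele-fraction model

Under equal amplification of all templates within a marker, the expected
favorable-allele read percentage for c co-amplified diploid genome copies
is `100 · dose / (2c)`, where dose is the favorable-allele count across
the 2c allele slots. `exact_allele_fraction` returns the exact rational
(`Fraction(100, 6)` for one favorable allele in three genomes);
`floor_allele_fraction` floors it to an integer because printed reference
tables traditionally truncate the thirds (16, 33). All comparisons inside
the package use the exact value.

## Pipeline stages and numerical choices

**Demultiplexing and marker assignment** match fixed prefixes by Hamming
distance (substitutions only). Defaults: barcode ≤ 1 mismatch, M13+primer
prefix ≤ 2 mismatches — conservative, configurable. Mixed-length barcodes
are each tried at their own length; at equal mismatch count the longest
match wins and residual ties are binned as ambiguous. A tolerance at or
above the minimum pairwise prefix distance of the barcodes (or forward
primers) is rejected up front as a configuration error, since it would
make assignment systematically ambiguous. Both stages conserve reads:
assigned + unassigned + ambiguous = input.

**Alignment** replaces a k-mer database search tool: every read is already
attributed to one short reference, so a banded affine-gap dynamic program
(match +1, mismatch −1, gap open −2, gap extend −1; a length-k gap costs
open + k·extend; band ±10, widened to the length difference when needed)
gives identical information deterministically. The alignment is global in
the reference and semi-global in the read (read end overhangs are skipped
free — e.g. a residual trailing adapter). Tie-breaking is fixed:
diagonal > gap-in-read > gap-in-reference, smallest read end index on
equal end score. Identity is matches / reference length; reads under 0.9
identity are rejected (a data outcome, not an error). Because the sorter
has already trimmed the barcode/M13/forward-primer prefix, reads are
aligned to the reference minus its forward-primer region, with site
positions shifted accordingly. A same-length pair with ≤ 2 mismatches
short-circuits to the diagonal alignment, which is provably the unique
optimum under the default scoring; this keeps large runs fast without
changing any result. An uncovered or deleted site is observed as N,
consistent with N meaning "null allele or a deletion".

**Counting and calling.** Pileups count A/C/G/T/N per (sample, marker,
site); N observations stay in the denominator, per the literal definition
of percent favorable as favorable / total reads. Percents are computed and
compared at full precision and only rounded (1 decimal) for display, so no
boundary artifacts appear at the cutoff. The minimum-read threshold
(default 10) is interpreted as ≥ 10 total accepted reads at the site; the
alternative reading (10 per allele class) would roughly double the
requirement and is not used. Dominant markers without annotated sites are
tabulated under a pseudo-site `amplicon` so the zero-read null logic sees
the key. Markers with several sites are called per site independently; any
amplicon-level haplotype summary is a derived report, not a call.

**Cutoffs.** The homozygous-positive cutoff per (marker, site) is the
minimum percent favorable among the run's qualifying positive-control
replicates (depth ≥ the minimum-read threshold). One control degenerates
to its own value; no qualifying control yields no cutoff and downstream
no-calls — controls belong in every run. Raising a cutoff can never turn a
negative call positive (monotonicity, property-tested).

**Heterozygote calling** is disabled by default. In a polyploid the
het/hom separation is compressed (25 vs 50 %, 16⅔ vs 33⅓ %), so enabling
it requires an explicit percent band, intended to come from a synthetic
heterozygote control (an equal mix of positive and negative control DNA).

## Simulator

The simulator emulates the fusion-PCR library, not the chemistry: for each
(sample, marker) pair it draws reads uniformly from the 2c allele-resolved
templates, wraps them in the read structure above, and applies iid
per-base substitutions. Defaults reflect the emulated study conditions:
24 samples, mean 889 reads per sample-marker pair, negative-binomial depth
(size 10, capturing the large observed per-marker spread), 3 % unstructured
contaminant reads, substitution rate 0.005 (an assumption — the platform's
error profile is indel-heavy and no quantitative rate was available; indel
errors are a listed non-goal). Qualities are a constant Q30 placeholder.
A genome copy's genotype (AA/AT/TT, A = favorable) applies jointly to all
sites of the marker — one favorable and one wild haplotype per copy;
independent per-site phasing and homoeolog divergence outside the
annotated sites are not modeled. Dominant-marker wild samples emit zero
reads. All randomness flows from one integer seed; identical scenarios
produce byte-identical FASTQ.

What passing simulation tests shows, and what it does not: recovery of the
dilution model, sorter/aligner/caller correctness, and rule boundaries are
covered; PCR efficiency bias between genomes, homopolymer indel errors,
chimeras and quality-dependent artifacts of real data are not, so real
runs still require their in-run controls to behave.

## Validation-run control design

The default scenario mimics a marker-validation run on characterized,
fully homozygous germplasm: every sample known to be hom-favorable for a
marker is flagged as a positive-control replicate for it. This matters for
the control-anchored rule: with iid sampling noise, a *non-control*
hom-favorable sample falls below the minimum of k control replicates with
probability ≈ 1/(k+1), so a small control subset cannot certify 100 %
recovery — but in a validation run the positives *are* the control set,
the cutoff sits at the observed low edge of the positive class, and the
remaining classes (0 % for hom-wild, plus the dominant null/presence
split) are separated by tens of percentage points. Production runs with
unknown samples should carry several control replicates and treat calls
within sampling distance of the cutoff with corresponding care.

## Problem sizes

Tests and the acceptance script run entirely on simulated data at desk
scale: dilution-table recovery at depth 10,000 (20 seeds for the reported
averages), the end-to-end run at 24 samples × 10 markers × depth 60, the
replicate recovery check at 6 × 3 × depth 50 over 20 seeds, and the
aligner/oracle cross-check on 1,000 random pairs of ≤ 60 nt with ≤ 3-nt
indels. These sizes were chosen to make every stochastic check
statistically meaningful while keeping a full run of the suite around a
minute.

## Known limitations

* Substitution-only error model; no flowgram/homopolymer simulation.
* Equal template amplification within a marker (the dilution-table
  premise); real amplification bias between genome copies is not modeled.
* One forward primer per marker; homoeolog-shared primers are unsupported.
* Reads are assumed forward-oriented; a config flag can additionally try
  the reverse complement.
* The optional mean-quality read filter is off by default and minimal.
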