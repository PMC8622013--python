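# Methods

This note documents the models behind `ihrkit`, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
conventions. Coordinates are 1-based inclusive throughout; intervals are
closed `[start, end]` in memory and converted to 0-based half-open only when
written as BED.

## The genotype HMM

Each F2 chromosome is modelled as a 3-state chain over the ordered markers:
`HomP1`, `Het`, `HomP2` (P1 = Columbia, P2 = Landsberg). The published
screens of this kind used a custom hidden-Markov script whose internals are
not described; the design here is therefore a reconstruction from first
principles, and is flagged as such.

**Emissions.** At a marker with `n_P1`/`n_P2` reads supporting each parental
allele, reads are exchangeable and the likelihood is binomial with per-read
P1 probability `1 − ε` (HomP1), `0.5` (Het) or `ε` (HomP2), where `ε` is the
per-read allele miscall rate. `(0, 0)` scores 0 under every state: missing
data is uninformative, not evidence.

**Transitions.** Marker spacing is highly non-uniform, so transitions are
distance-aware: across a gap of `d` bp the chain stays with probability
`exp(−r·d)` and switches to each of the two other states with probability
`(1 − exp(−r·d))/2`. The default `r = 1e-6`/bp is deliberately weakly
informative — at genotyping coverage the emissions dominate by tens of nats,
and the rate only has to make spurious single-marker flips expensive. The
prior is the Mendelian F2 `1:2:1`.

**Decoding.** Viterbi in log space, ties broken toward staying in the
current state so equal-score paths prefer fewer transitions; the exactness
of the recursion is pinned by a test that enumerates all `3^m` paths on
random instances up to 8 markers. Forward–backward posteriors are computed
alongside and must normalize to 1 at every marker. One post-pass absorbs
*interior* single-marker islands whose two flanking blocks share a state
when the island's posterior is below 0.99 — a reproducible stand-in for the
manual review such one-marker calls receive in practice. Terminal blocks and
islands between unlike flanks are never merged: on sparse maps those are
real signal, not noise.

**Crossover calls.** Every block boundary yields a call whose interval is
`(last marker of the left block, first marker of the right block)` and whose
point estimate is the midpoint of those two positions, rounded half-up to an
integer bp. With a declared cut site, the reported distance is
`|midpoint − cut|`; a call whose interval overlaps `cut ± 20 kb` (closed) is
classified as a crossover at the target. Nothing else distinguishes induced
from meiotic crossovers — proximity is the whole criterion, matching how
such events are adjudicated in the underlying screens.

## Conversion-tract detection

**Screen.** NCO signatures are only interpretable on a homozygous
background, so a plant is eligible at a target only if every decoded marker
in `cut ± 100 kb` shares one homozygous state — except that discordant
markers are tolerated when they all lie within 10 kb of the cut and span at
most 10 kb, so the putative conversion island itself cannot disqualify the
plant. The 10 kb island allowance exceeds the largest tract the assay class
has reported (~7.5 kb) while staying far below the 100 kb flank. An
independent brute-force window scan re-implements this definition in the
test suite and must agree exactly.

**Genotype calls inside the window.** Per-marker calls use the *emission
evidence alone* (flat prior over the three states), thresholded at posterior
0.99; markers below threshold are uninformative and excluded from both the
converted and the flanking sets. The chain posteriors are deliberately not
used here: the HMM's transition prior encodes "genotype changes are rare per
bp", which is exactly wrong inside a conversion tract where mismatch repair
flips markers at the 100-bp scale — chain smoothing erases interrupted-tract
structure. At the coverage this stage expects (≈30×; hybrid NCO evaluation
needs high-coverage genotypes) a marker's own reads are decisive or the
marker is dropped.

**Statistics.** `min_length` = span of the outermost converted markers,
inclusive (a single converted marker reports 1 and is flagged
low-confidence). `max_length` = distance between the innermost informative
background-state markers flanking the tract, minus 1; chromosome ends bound
it when no flank exists. The minimal length is the assay's reportable
number; the maximal bound is an added, clearly labelled statistic. A tract
is `complex` iff at least one informative background-call marker lies
strictly between the outermost converted markers. Zygosity: converted
markers all Het → `heterozygous_tract`; all homozygous for the donor →
`homozygous_tract` (both gametes carried the conversion — evidence of a
pre-meiotic event); anything else → `complex_mixed`, reported rather than
rejected.

## NHEJ footprint classification

Anchor-based, no full alignment: two `k = 15` nt reference k-mers taken at
offsets `[cut−2k, cut−k)` and `[cut+k, cut+2k)` are located in the read with
at most one mismatch each, leaving a 2k-wide central segment that contains
any cut-site indel. The length difference between the central read and
reference segments gives the indel size; the inserted bases and the
placement-ambiguity interval come from the longest common prefix/suffix of
the two segments. An indel is attributed to the cut only if that ambiguity
interval overlaps `cut ± 3` nt; otherwise the read is `complex`. For
length-neutral reads, `complex` requires ≥ 2 mismatches within `cut ± 3` —
a single mismatch anywhere is treated as sequencing noise, which keeps the
classifier's agreement with a global edit-distance oracle above 99% at
realistic (0.5%) error rates instead of mislabelling ~14% of WT reads.
Reads where an anchor cannot be placed are excluded from the denominator
and reported separately; NHEJ% is `100 × indel reads / classified reads`.
Allele assignment reads the base at a diagnostic SNP (e.g. the PAM SNP that
makes a guide allele-specific) located via its upstream reference context;
a base matching neither parent is `unassigned`.

## Amplicon allele spectra

Molecules are reduced to a per-marker parental pattern plus a cut-site indel
signature. Clustering is greedy agglomeration: exact (pattern, indel) groups
are processed largest-first (ties by lexicographic pattern), and a group
joins the first cluster with an identical indel signature whose consensus is
within `max_mismatch = 1` marker; consensus is the per-marker weighted
majority. One mismatch absorbs the dominant error mode (a single miscalled
marker) without ever merging across indel signatures. Alleles at ≤ 5%
molecule frequency are discarded (with the discarded mass reported) —
the same floor the assay uses to exclude PCR artifacts. Classes describe
pattern topology only: 0 switches → parental or NHEJ-only; 1 switch →
exchange, *reciprocal* when a retained allele with an overlapping switch
interval and exchanged flanks co-occurs in the same plant, else
*non-reciprocal*; ≥ 2 switches → *interrupted* exchange. At 5 kb amplicon
scale a single switch cannot distinguish a crossover from a long conversion
tract, so no mechanism is claimed. The somatic IHR rate is the summed
frequency of exchange-class alleles.

## Reporting conventions

Rates are `100 × count / denominator`, rounded half-up (so 1/106 prints as
0.9 and 13/106 as 12). Because the homozygosity screen removes plants from
the NCO denominator, summaries always carry both denominators — plants
sequenced and plants eligible — side by side with the raw counts; no single
ambiguous percentage is ever emitted.

## The simulator

The generator emulates the evidence such a screen actually produces:

- **Marker maps**: uniform random unique positions at a configurable density
  (default 1/kb; dense Col/Ler SNP regions run ~4/kb), distinct parental
  bases per marker, written as VCF (P1 = REF, P2 = ALT).
- **Repair events**: per-plant class probabilities (defaults
  NHEJ 0.30, NCO 0.12, CO 0.009 — the germline-transmission regime of a
  responsive target); indel spectrum concentrated on ±1–2 nt; allele-specific
  (`P2_only`) guides always cut the P2 homolog, so P1 can only be donor.
- **Conversion tracts**: the heteroduplex extends from the cut by an
  independent geometric number of bp per side (default mean 500 bp/side —
  the underlying tract-length law is unknown; geometric is the maximum-
  entropy stand-in for a per-bp termination process and is configurable);
  each in-tract marker converts toward the donor independently with
  `p_conv` (default 0.7, giving the observed mix of simple and interrupted
  tracts; `p_conv = 1` produces only simple tracts).
- **Crossover offsets**: induced CO breakpoints are displaced from the cut
  by a Laplace-distributed branch-migration offset (scale 200 bp, the
  magnitude consistent with a ~190 bp observed displacement).
- **F2 meiosis**: each gamete recombines the two F1 haplotypes with
  Poisson-distributed crossovers (uniform positions; a fixed-count mode
  supports controlled recovery experiments); an F2 plant is two independent
  gametes. Cut-site indels travel with the physical segment covering the
  cut. Seed-fluorescence selection (GFP/RFP transgenes at their Columbia
  tester coordinates on chromosome 3) filters plants by parental origin at
  the two transgene positions.
- **Read counts**: depth ~ Poisson(coverage) per marker; each read reports a
  uniformly chosen chromatid's allele, miscalled with probability ε
  (implemented as the exactly equivalent binomial draw). Defaults: coverage
  15, ε = 0.005.
- **Amplicon molecules and reads**: molecules sample a specified allele
  mixture with per-marker miscalls; short reads around the cut carry
  spectrum-drawn indels and per-base substitution errors.

What it does **not** emulate: read-level FASTQ/alignment artifacts, PacBio
error models, somatic chimerism (one germline event per plant per target),
epigenetic landscapes (chromatin class is annotation only), and non-uniform
meiotic CO landscapes (a uniform landscape is the default; hotspot weighting
would slot into the gamete sampler). Passing tests therefore demonstrate the
*inference machinery* is correct under a faithful evidence model, not that
real tissue chimerism or alignment biases are handled.

## Problem sizes and numerical choices

End-to-end checks run at desk scale: 2 Mb chromosomes at 1 marker/kb and 100–
200 plants for crossover recovery (coverage 15, ε = 0.005, one meiotic CO
per gamete); 500 kb at 4 markers/kb, coverage 30, for tract recovery; 2,000
reads / 2,000–3,000 molecules for the NHEJ and amplicon estimators. Viterbi
optimality is checked exactly (tolerance 1e-9) against full enumeration on
≤ 8-marker instances. Statistical recoveries are asserted within 3 standard
errors at the n actually simulated. All randomness flows from explicit
`numpy` generators; identical config + seed reproduces outputs bit-for-bit.

## Known limitations

- The HMM is a reconstruction; its `r` and `ε` are not calibrated to any
  published decoder.
- The homozygosity screen's island rule uses fixed 100 kb / 10 kb windows;
  a tract longer than 10 kb would disqualify its own plant.
- Anchor-based NHEJ classification cannot size indels larger than the
  anchor offset (15 nt) and discards unanchorable reads rather than
  salvaging them by full alignment.
- Reciprocity of exchange alleles is assessed within one plant's retained
  alleles only; a partner allele just under the 5% floor makes a true
  reciprocal pair look non-reciprocal.
- Tract zygosity assumes correct genotype calls; at low coverage a
  homozygous tract can masquerade as `complex_mixed`.
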