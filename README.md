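# ihrkit

Detection and characterization of CRISPR-Cas9-induced **inter-homolog
recombination (IHR)** in hybrid plant populations — built around the
Col × Ler *Arabidopsis* F1/F2 design in which SNPs between the two parental
ecotypes serve as recombination markers.

When Cas9 cuts one chromosome of an F1 hybrid, the break can be repaired in
*cis* by non-homologous end joining (NHEJ, a small indel at the cut) or in
*trans* using the homologous chromosome as template, producing either a
**crossover** (CO: reciprocal arm exchange) or a **gene conversion** (NCO: a
non-reciprocal tract of donor markers copied around the cut, often
*interrupted* when mismatch repair resolves the heteroduplex both ways).
`ihrkit` provides tested, reusable implementations of every analysis step in
such a screen, plus a mechanistic simulator so the whole pipeline runs and
is validated without any external data.

## What it computes

| stage | module | core statistic |
| --- | --- | --- |
| genotype segmentation | `ihrkit.hmm` | 3-state HMM (HomP1/Het/HomP2), binomial emissions $P(n_{P1}\mid n, p_s)$ with $p_s \in \{1-\varepsilon,\ 0.5,\ \varepsilon\}$, distance-aware transitions $p_{\text{switch}}(d) = \tfrac{1}{2}(1-e^{-rd})$ |
| crossover calling | `ihrkit.hmm` | breakpoint interval = flanking informative markers; CO site = their midpoint; distance to the cut |
| NCO detection | `ihrkit.tracts` | 100-kb homozygosity screen, then minimal tract = span of outermost converted markers, maximal bound = innermost concordant flanks − 1, simple/interrupted class, tract zygosity |
| NHEJ quantification | `ihrkit.nhej` | NHEJ% = indel reads / classified reads; footprint spectrum; allele assignment via a diagnostic (PAM) SNP |
| somatic allele spectra | `ihrkit.amplicon` | long-amplicon molecule clustering into consensus alleles, >5% frequency filter, parental / NHEJ / reciprocal / non-reciprocal / interrupted classes, somatic IHR rate |
| reporting | `ihrkit.report` | per-target counts and half-up-rounded rates with *both* denominators (sequenced vs screen-eligible) |
| simulation | `ihrkit.simulate` | marker maps, repair-event truth (indel spectra, heteroduplex tracts with per-mismatch repair, dHJ-migration CO offsets), F2 meiosis, read-count and molecule emission |

## Worked example

`examples/detect_conversion_tract.py` simulates one eligible F2 plant whose
transmitted chromosome carries a partially repaired heteroduplex (70% of
mismatches converted toward the donor), genotypes it at coverage 30, and
runs the screen + detector:

```
homozygosity screen : eligible=True, background=HomP1
true heteroduplex   : [249,513, 250,190]  (678 bp, 2 converted markers)
detected tract      : minimal 396 bp, maximal bound 1502 bp
classification      : simple, heterozygous_tract
```

The *minimal* tract (396 bp) is the span of the outermost markers observed
as converted — a lower bound, since markers sample the true 678 bp
heteroduplex sparsely; the *maximal* bound (1,502 bp) is set by the nearest
flanking markers still showing the background genotype. `heterozygous_tract`
means one of the two gametes carried the conversion, the ordinary case for a
germline-transmitted event (a homozygous tract instead indicates a
pre-meiotic, somatic origin).

The other examples each exercise one capability end to end —
`simulate_f2_screen.py`, `call_crossovers.py` (breakpoint intervals that
bracket the true meiotic exchange points, with cut-site distances),
`quantify_nhej.py` (NHEJ% with an allele-specific guide: indels confined to
the cleavable P2 haplotype) and `amplicon_spectrum.py` (allele table with
frequencies, classes and the somatic IHR rate). A thin CLI mirrors the
stages (`ihr simulate | genotype | tracts | nhej | amplicon | report`).

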