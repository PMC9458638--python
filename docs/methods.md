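# Methods

## Constellation model and binomial screen

For a biallelic autosomal variant, the parental genotype pairings that
can produce variant-carrying offspring are enumerated with exact
rational arithmetic ("A" = variant allele).  Each pairing's Mendelian
probability of an AA (homozygous-variant) child is computed from the
gamete cross, and the model returns the **unweighted mean** over
pairings — no assumption about pairing frequencies in the population is
made, which is the appropriate agnostic prior when parental genotypes
are unobserved.  Under the viable-homozygote assumption the six
pairings AA×AA, Aa×Aa, AA×aa, aa×aa, Aa×AA, Aa×aa give
mean{1, 1/4, 0, 0, 1/2, 0} = 7/24; excluding homozygote parents leaves
Aa×Aa, aa×aa, Aa×aa with mean{1/4, 0, 0} = 1/12.  The non-viable
assumption (1/12) is the screen's default, since it is the conservative
choice for the hypothesis being tested (a recessive-lethal allele).

The exclusivity test treats the `het + hom` **carriers** as the
binomial trials — zygosity outcomes among variant-carrying individuals
— and returns the lower tail P(X ≤ hom) at p_hom.  The alternative
reading (allele count as n) is not offered because carrier count is the
quantity the genotype tables provide directly.  With zero carriers the
test returns 1 (no evidence).  The p-value is attached for reporting; the
operative candidate filter is the fixed threshold cascade:

| parameter | default | meaning |
|---|---|---|
| `min_het` | 41 | heterozygote floor in the primary cohort |
| `max_hom_primary` | 0 | homozygote cap, primary cohort |
| `max_hom_secondary` | 5 | homozygote cap, secondary cohort |
| `alpha` | 0.05 | significance level for the alpha-derived floor |

The 41-het floor is reproduced as a constant because no published
significance level uniquely implies it ((11/12)⁴¹ ≈ 0.028 sits between
0.05 and 0.01); `min_het_for_alpha(alpha, p_hom)` additionally derives
the floor from a chosen alpha (35 at alpha = 0.05).  All thresholds are
inclusive.  Gene blacklisting (repeat-prone genes, pseudogene shadows)
is by case-insensitive exact symbol match against a user-supplied list;
the pipeline does not detect pseudogenes itself.

## Cohort ingestion and harmonization

VCF ingestion consumes aggregate INFO fields (AC/AN/nhomalt by default,
keys configurable), decomposing multi-allelic sites per alternate
allele with `het = AC − 2·nhomalt`; per-sample genotype columns are
deliberately not required, since release-style cohort VCFs carry
aggregates.  A TSV dialect (`variant_id, gene, aa_pos, aa_ref, aa_alt,
het_count, hom_alt_count, n_individuals`) is the round-trip format the
generators emit.  Allele frequencies are folded onto [0, 0.5]
(f > 0.5 → 1 − f), and two cohorts are harmonized by intersecting on
variant id and keeping |MAF_A − MAF_B| ≤ 0.10 — interpreted as ten
percentage points on the folded scale, boundary inclusive.  Folded
frequencies are used on both sides because the filter's purpose is
concordance of the minor allele, whichever strand convention a release
uses; the threshold is configurable.

## Genotype shuffling

The null simulator re-draws each variant independently: per cycle and
per individual, two uniform deviates are drawn and an allele is mutated
iff its deviate is ≤ the observed allele frequency (the boundary draw
counts as mutated, as specified — a measure-zero convention kept for
fidelity).  Defaults are 2504 individuals and 100 cycles; means over
cycles are reported as real numbers.  Each variant receives its own
`numpy.random.Generator` substream spawned from the config seed
(PCG64 via `default_rng`; the generator identity is numpy's default and
is stable under a fixed seed), so summaries are reproducible and
independent of variant order.  Per-cycle counts can be retained for
plotting either per-cycle or cycle-averaged scatters.

## Feature channels

**Profiles.**  Conservation channels are position-specific log₂-odds
computed directly from alignment columns: per ungapped reference
position, amino-acid counts are smoothed with background-frequency
additive pseudocounts (default weight 1 effective observation, so
zero-count residues score finitely) and divided by the Robinson &
Robinson background.  This is a deliberate simplification of full
profile-HMM scoring — only per-position per-residue log-odds are
consumed downstream, so match-state emissions, insert/delete states and
sequence weighting are omitted.  The channel score is
`score(alt) − score(ref)`; negative means the mutant is disfavoured.

**BLOSUM62** comes from Biopython's canonical NCBI matrix.

**Structural zones.**  Each commodity partitions its domain into zones:
secondary structure H,G → helix, E,B → strand, else coil;
accessibility <16 / 16–59 / ≥60 Å²; burial <115 / 115–164 / ≥165 Å²;
phi/psi a 12×12 grid of half-open 30° bins over [−180, 180) with +180
wrapped to −180.  Accessibility and burial boundaries are absolute Å²
(DSSP-native units; configurable by editing the bounds, not by a
relative-accessibility switch).  Burial is the residue's maximal
Gly-X-Gly accessibility (Tien et al. 2013 theoretical values) minus
observed accessibility, floored at 0 — burial and accessibility weight
residue size differently, which is why both are channels.  Zone tables
are trained from any residue feature table as
`log₂[(obs(aa, zone) + pc) / (exp(aa, zone) + pc)]` with
`exp = total(zone) · freq(aa)` and pseudocount 0.5; on
amino-acid-independent data the entries shrink toward 0 with sample
size.  A variant's channel score is mutant-minus-wild-type log-odds
**within the wild-type residue's zone** (the structure is the wild
type's; the question is how well the mutant fits it).

**Annotations.**  FDA/OMIM are binary gene-list memberships; the
haplotype channel maps a five-level dosage-sensitivity category onto
{1, 0.75, 0.5, 0.25, 0} with autosomal-recessive evidence highest;
`uniprot_function` is 1 iff the variant position overlaps an annotated
functional feature interval (window configurable, default 0 — the
scale of this channel is otherwise undefined, so binary overlap is the
defensible choice).  Externally computed contact-potential channels
(`mech`, `mech_intra`) are accepted as pass-through columns and
calibrated like any other; they are never computed here.

## Calibration and integration

Each channel is calibrated by a threshold sweep over its distinct
benchmark values.  Channel direction is auto-detected (the orientation
with AUC ≥ 0.5) and recorded, so the sweep depends only on ranks and
calibration is invariant to monotone transforms.  A variant's raw value
is treated as the operating threshold: the call set is every benchmark
item at least as damaging, and the rates get a half-count continuity
correction (TPR = (TP + ½)/(P + 1), FPR = (FP + ½)/(N + 1)) so
log₂(TPR/FPR) is always finite — the integration formula is undefined
at exact 0 or 1 rates, and the half-count is the standard fix.  Absent
(NaN) channels contribute no term, matching the reality that structural
channels are undefined for unresolved regions.  Score thresholds are
selected as the smallest cut-off whose empirical FDR (false calls among
calls on the labelled set — not a multiple-testing q-value) and FPR stay
below the stated bounds, defaulting to FDR < 1% and FPR < 5%; a bound
of 1 excludes nothing, and an unattainable pair of bounds is reported
as such rather than raised.  Enrichment curves report the
fraction of variants at or above the threshold, binned by het count
among hom = 0 variants and by hom count; empty bins are NaN, not 0.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the screen relies
on: per-individual Hardy-Weinberg genotype draws (two uniform allele
draws, the same primitive as the shuffler), recessive lethality as
re-drawing homozygous-alternate individuals as heterozygotes (carriers
survive, allele counts stay realistic), cross-cohort MAF correlation
with truncated Gaussian noise (σ = 0.02 by default), rare-skewed beta
MAFs, position-specific alignment conservation, a hydrophobic-burial
accessibility bias (gamma-distributed accessibility with mean 20 Å² for
hydrophobic vs 70 Å² for polar residues at full bias), and Gaussian
benchmark channels shifted per class.  The canonical study scenarios
fix 2504 + 20000 individuals, 5000 variants, 5% lethals at MAF ≥ 0.02
(expected het ≥ ~95, comfortably above the 41 floor) — large enough for
stable rates, small enough to run in seconds.

Deliberately **not** modelled: linkage and haplotype structure,
population substructure, sex chromosomes, genotyping error, de novo
mutation, realistic gene lengths, and any correlation between a
variant's frequency and its functional-impact features beyond the
planted lethal flag.  Passing tests therefore demonstrate that the
screen and scorer recover the signals they assume, with correct error
behaviour under the null — not that real cohorts satisfy those
assumptions; in real data, MAF discordance, calling artefacts and
pseudogene shadows are handled only insofar as the harmonization filter
and blacklist remove them.

## Numerical conventions

Log base 2 throughout (profiles, zone tables, integration), so scores
are in bits.  All thresholds inclusive as stated.  Genotype-count
arithmetic validates `het + hom ≤ n` and non-negativity at
construction.  Zero-carrier tests return p = 1.  All stochastic
components flow from a single integer seed through
`numpy.random.SeedSequence` spawning, giving byte-identical outputs per
seed and order-independence per variant.
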