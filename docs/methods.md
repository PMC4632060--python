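# Methods

This note documents the models, rules and numeric conventions behind
`opakit`, the design choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real data.

## The repeat model and nomenclature

The locus is a run of 5′-CAX codons: CAR (CAA/CAG) encodes glutamine, CAY
(CAC/CAT) histidine. A valid repeat contains at most one histidine codon,
giving the layout Q<sub>n</sub>HQ<sub>m</sub>; an uninterrupted tract is
stored entirely in the left run (`PqConfig(left_q, has_his=False)`).
Because every codon begins with CA, a codon string is fully determined by
its third positions, and that compact string is the unit of identity
throughout the package: two alleles that encode the same pQ isoform but
differ at synonymous positions are distinct alleles (*opa35a1* vs
*opa35a2*) and are tallied separately during genotyping.

Naming policy (`resolve_name`): an unseen total length mints the bare
`opa{N}`; a taken length with a different histidine position receives the
next free letter in registration order (a, b, …); a matching pQ
configuration with a different codon string receives the next numeric
suffix within its letter group. `*n` tags for synonymous variants of a
named allele are stored as opaque registry metadata and never minted
automatically. Names of slippage derivatives use `opa{N}L`/`opa{N}R` for
events left/right of the histidine.

### Slippage relation

`is_slippage_derivative(child, parent)` is true when the child is
reachable by a length change confined to one glutamine tract, within
`max_del = 4` deleted and `max_ins = 2` inserted codons per event — the
extreme single-event sizes observed in the clone-library QC data
(an *opa27R*-type −4 contraction; an *opa33L*-type expansion). Slippage
never creates or destroys the histidine, so a histidine mismatch is never
a slippage relation: the His-less Q₂₃ allele is *not* a derivative of
Q₁₃HQ₁₇ even though it is within four residues of it on one side.
His-less parents take their L/R side label from the position the
histidine occupies in the ancestral wild-type pattern (13 glutamines to
its left); a run straddling that boundary takes the side holding more of
it, ties going left.

### Placeholder codon patterns

The exact nucleotide strings of the surveyed alleles are not bundled.
`default_codon_string` generates editable placeholder patterns that
reproduce the structure that matters to the pipeline: a (CAG)₇ run
immediately left of the histidine — the locus of essentially all observed
contractions, which is why observed slippage variants are predominantly
"L" types — with shorter CAA-broken CAG runs to the right. These defaults
must not be treated as ground-truth sequences; `read_registry`/
`write_registry` round-trip a user-supplied registry TSV
(`name, pq_string, third_position_string, his_index, notes`).

## Anchored extraction

`locate_and_extract` scans both strands for the two anchors (Hamming
matching, `max_mismatch = 1` per anchor, no indels — Sanger clone flanks
are high quality), then takes the in-frame codon run between them. Any
non-CAX codon between matched anchors is a malformed-repeat error rather
than a shortened call, and more than one candidate locus is an ambiguity
error rather than a guess: a genotyper must not silently pick a locus.
Reported coordinates are 0-based half-open on the forward strand.

The spanning criterion is strict: a read informs the repeat length only
if `read_len > 3·n_codons + 2·anchor_bp`. A 75-nt read is insufficient
for a locus needing exactly 75 bases (23 triplets + 3-bp anchors), which
is the borderline case that motivates the rule.

## Genotype calling

Calling is deliberately rule-based (no per-cycle stutter likelihood), as
the underlying laboratory procedure was. Per individual:

1. **Candidates.** An allele is a candidate true allele when it has
   ≥ `het_min_support` (2) clones *and* ≥ `het_min_fraction` (20%) of the
   tally, and does not match the known-foreign set. Foreign matching is
   at the codon level when codons are known on both sides (two cultures
   can legitimately carry the same pQ isoform with different codon
   histories), else at the pQ level.
2. **Dominance demotion.** A candidate that is a slippage derivative of a
   co-candidate with at least `contraction_dominance` (2×) its support
   (contractions) or `expansion_dominance` (3×, the ~10×-rarer artifact
   demands stronger evidence) is demoted to a slippage artifact. True
   heterozygotes segregate near 1:1, so an 8:2 tally of an allele and its
   one-step contraction is an artifact pattern, not a heterozygote; a 5:4
   tally survives. Without this rule, two identical slippage clones in a
   ten-clone library (probability ≈ 7% per individual at a 5% contraction
   rate) would routinely fake heterozygotes.
3. **Minor-clone classes.** Each non-candidate allele is classified, in
   order: slippage derivative of a candidate (ties between candidate
   parents break toward the higher count, then alphabetically; a clone
   that is both slippage-derivable and foreign-matching is classed as
   slippage — PCR error is the dominant observed process); known foreign
   allele → interculture contaminant at any count (the interculture QC
   data contain individuals with two contaminant clones that were still
   called homozygous); unexplained singleton in a library of ≥ 8 clones →
   intraculture contaminant; otherwise ambiguous.
4. **Zygosity.** One surviving candidate → single-allele (hemizygous or
   homozygous; X-linkage means males can never be heterozygous), two →
   heterozygous, otherwise an ambiguous call with diagnostics (never an
   exception).

Line genotypes are the union of called alleles across the line's
individuals (flagged, not fatal, past two alleles). Error rates are class
counts divided by total clones; `without_interculture()` recomputes them
after removing interculture contaminants, matching how the
contamination-control numbers were reported. Displayed percentages are
rounded to one decimal, ties away from zero; that convention (also used
for the Hardy-Weinberg female count and expected counts) is implemented
in `opakit._util.round_half_away` because Python's built-in banker's
rounding would print 10.5 as 10.

Known limitation: in a line segregating two alleles one slippage step
apart (e.g. Q₁₃HQ₁₇/Q₁₃HQ₁₈), a heterozygous individual whose minor
allele is the contraction-derivative side and drew ≤ a third of the
clones is conservatively demoted to a single-allele call. Line-level
pooling across individuals recovers the segregating pair.

## Population summaries and X-linked Hardy-Weinberg

Each homozygous line contributes weight 1 to its allele, each haplotype
of a segregating line 0.5; weights therefore sum to the line count. The
non-wild-type fraction is (total − wild-type weight)/lines; the mean
absolute deviation averages |length − 31| per haplotype within a line
(het haplotypes each weighted 0.5), then across lines.

`xlinked_hw_expected(n, percent_female, p)` rounds the female count to an
integer **before** computing expectations — flies are whole — giving
F females and M = n − F males; expected counts are M·p + F·p² (A-only),
M·q + F·q² (B-only) and F·2pq (heterozygous females, the only possible
heterozygotes). Raw counts sum to n exactly for any p and sex ratio;
rounded counts use the half-away convention. `goodness_of_fit` is the
plain Pearson χ² with df = categories − 1 (p-value from `scipy.stats`).

## Phenotype scoring

Scores per bristle position: normal 1.0; missing 0.0 (socket presence
recorded); ectopic-near or split 2.0; abnormally slender bristles a
fraction in (0, 1), default 0.5; an ectopic bristle exactly mid-distance
between a DC or SC pair scores 1.5 at each paired position (invalid
elsewhere); empty socket plus nearby ectopic −1.0; two empty sockets
−2.0. Negative compound scores enter the cohort means and are also
counted separately.

Masking: within a genotype × sex × position group, if both ectopic-type
(> 1) and missing-type (< 1) scores occur, every score of the less
frequent class becomes 1.0, so opposite defects cannot cancel in the
mean; ties keep the ectopic class (the source procedure states no tie
rule; this one is fixed and documented). Sex is part of the grouping
because cohorts are always reported per sex. The hemi-notum (two per
fly) is the unit for frequencies; the fly is the unit for the
ectopic-bristle rate, scored over the DC, SC and pPA positions.

Embryonic failure is unhatched/total; fecundity reports each line's egg
count as a percent of the panel maximum, with the mean's percent computed
from the unrounded mean.

## Synthetic data

The generator's defaults are the study conditions the pipeline assumes:
clones per individual uniform on [5, 13] (matching the reported range and
≈ 9.2 mean), contraction 0.05/clone, expansion 0.006/clone, intraculture
contamination 0.057/clone drawn from the line's own allele set (bottle
mates), interculture contamination 0.036/clone drawn from a named foreign
pool. Slippage is a single-codon event hitting the longest identical-
glutamine run (ties at random); multi-codon events are not simulated by
default (they arise in the data only as rare compound observations).
Females draw two alleles from the line frequencies, males one. One seed
drives everything through a fixed stream-splitting order (lines →
individuals → clones), so identical seeds give byte-identical FASTA,
sample-sheet and truth outputs.

The default validation panel (`default_study_config`) is eight fixed
lines × five individuals — mirroring an inbred reference panel, where
almost every line is homozygous — with the His-less Q₂₃ allele as the
foreign stock: maximally distinct from the panel, so interculture
contaminants are never confusable with slippage, the same geometry as the
real contamination control. Two consequences worth noting. First, in a
homozygous line intraculture contamination is invisible by construction
(bottle mates share the genotype), so parameter-recovery tests target the
contraction and interculture rates; the intraculture rate is structurally
unidentifiable there, and its published estimate likewise had no stated
derivation. Second, recovery tests at 40 individuals × 10 clones assert
≥ 99% exact-genotype accuracy and rate estimates within two binomial
standard errors of the generating rates; a two-SE band fails by design
about 5% of the time, so these checks run at a fixed seed. What passing
shows: the caller's rules recover truth under the modelled error
processes at realistic rates. What it does not show: robustness to
base-calling errors, chromatogram artifacts, indel-bearing flanks, or
non-uniform clone sampling — none of which are simulated.

Phenotype simulators draw per-hemi-notum defect categories from supplied
probabilities (remainder normal) and binomial hatch counts; they exist to
exercise the scoring and masking code, not to model bristle development.

## Reconstructed QC clone sets

`opakit.datasets` rebuilds the four QC experiments per individual from
their printed class totals, so the error-rate estimator can be run end to
end on them. Two printed tallies are internally inconsistent; the
reconstructions follow the printed totals and percentages: the
somatic-variation experiment lists 12 variant clones but reports 205/218
original (94.0%) with 6.0% variants, which requires 13; and the
interculture experiment's "340 total clones" after removing 13
contaminants from 358 must be 345 (= 333 + 12, matching 96.5%/3.5%).
Variant clones are placed as minor clones of distinct individuals, the
only placement consistent with every individual's reported genotype call.
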