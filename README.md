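# opakit

Genotyping and phenotype-scoring toolkit for the polyglutamine-encoding
*opa* (5′-CAX) triplet repeats in exon 8 of *Drosophila melanogaster*
*Notch*.

## The problem

The Notch intracellular domain carries a polyglutamine (pQ) tract of the
form Q<sub>n</sub>HQ<sub>m</sub>: two glutamine runs (CAR codons, CAA/CAG)
separated by a single histidine (CAY, CAC/CAT). The wild-type allele,
*opa31*, encodes Q₁₃HQ₁₇. Because the repeat is longer than a short
sequencing read plus the non-repetitive "anchor" flank needed to place an
alignment (3 bp × 40 triplets + 10 bp × 2 anchors = 140 bp), short-read
assemblies genotype this locus unreliably, and labs instead sequence
several independent plasmid clones per fly by Sanger. That raises a
calling problem: PCR replication slippage contracts the repeat in ~5% of
clones (rarely expands it, ~0.6%), and environmental contamination can
inject clones from bottle mates (intraculture) or other stocks
(interculture). `opakit` implements the full desk-side pipeline around
that design, for anyone genotyping unstable triplet repeats from clone
libraries:

- **`opakit.alleles`** — pQ configurations, CAX codon strings, and the
  allele nomenclature: `opa{N}` by total residue count, letter suffixes
  for same-length alleles with distinct His positions (*opa33a* = Q₁₄HQ₁₈
  vs *opa33b* = Q₁₅HQ₁₇), numeric suffixes for identical isoforms with
  independent codon histories (*opa35a1*/*opa35a2*), and `L`/`R` names
  for slippage derivatives (*opa30L* = Q₁₂HQ₁₇).
- **`opakit.extraction`** — anchored, strand-aware extraction of the
  in-frame CAX run from clone or assembly sequences, and the
  read-spanning length criterion.
- **`opakit.genotyping`** — rule-based per-individual genotype calls from
  clone tallies; every minor clone is classified as slippage
  contraction/expansion, intraculture or interculture contaminant, or
  ambiguous; class counts give empirical error rates.
- **`opakit.popqc`** — allele distributions across lines (heterozygous
  haplotypes weighted 0.5), non-wild-type fractions, mean absolute length
  deviation, and closed-form X-linked Hardy-Weinberg expected genotype
  counts (males hemizygous).
- **`opakit.phenotype`** — the 13-position macrochaete scoring system
  with the rarer-defect masking rule, ectopic-bristle rates, embryonic
  hatch failure and fecundity summaries.
- **`opakit.simulate`** — seeded synthetic clone libraries and phenotype
  tables with per-clone ground truth, so every stage is testable without
  any sequence download.

## Worked example

```python
>>> from opakit import (classify_codons, default_registry, call_individual,
...                     CloneRecord, xlinked_hw_expected)
>>> reg = default_registry()
>>> classify_codons(reg["opa31"].codons).pq_string
'Q13HQ17'

>>> # ten clones from one fly: eight wild type, two one-step contractions
>>> from opakit.alleles import PqConfig, AlleleRecord, default_codon_string
>>> opa30L = AlleleRecord("opa30L", PqConfig(12, True, 17),
...                       default_codon_string(PqConfig(12, True, 17)))
>>> clones = [CloneRecord(f"c{i}", "L1", reg["opa31"]) for i in range(8)]
>>> clones += [CloneRecord(f"c{8+i}", "L1", opa30L) for i in range(2)]
>>> call = call_individual(clones)
>>> call.zygosity
'single-allele'
>>> {k[:6]: cls.value for k, cls in call.allele_classes.items()}
{'GAGAGA': 'original', 'AGAGAG': 'slippage_contraction'}

>>> # X-linked Hardy-Weinberg for a stock segregating two alleles 50/50,
>>> # 39 flies, 53.7% female
>>> xlinked_hw_expected(39, 53.7, 0.5).expected_rounded
{'A_only': 14, 'B_only': 14, 'het_female': 11}
```

The genotype call keeps the well-supported allele, classifies the 8:2
minor tally as a slippage artifact rather than a heterozygote (true
heterozygotes segregate near 1:1), and the Hardy-Weinberg expectation
says a 39-fly sample of that stock should contain about 14 + 14
single-allele flies and 11 heterozygous females.

A command-line interface mirrors the library:
`opakit simulate | extract | genotype | popsum | hwe | bristles | embryos`
(see `opakit --help`).

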