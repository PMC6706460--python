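# Ordered rule table mapping variant facts to a 5-tier class.
# First matching rule wins.  Available facts: known (bool),
# consequence_class (truncating|missense|other), mode_class
# (dominant|recessive|none), de_novo (bool), phenotype_match (bool),
# biallelic (bool).  `any_of` requires at least one listed fact true.
# Regardless of this table, a recessive-gene variant without a biallelic
# state is capped at VOUS by the engine.
rules:
  - if: {known: true, phenotype_match: true}
    tier: pathogenic
    note: previously reported disease variant with matching phenotype
  - if: {known: true}
    tier: VOUS
    note: previously reported variant without phenotype correlation
  - if: {mode_class: dominant, consequence_class: truncating, any_of: [de_novo, phenotype_match]}
    tier: likely pathogenic
    note: novel truncating variant in a dominant disease gene
  - if: {mode_class: dominant, consequence_class: missense, de_novo: true, phenotype_match: true}
    tier: likely pathogenic
    note: de novo missense in a dominant disease gene, phenotype consistent
  - if: {mode_class: recessive, biallelic: true, phenotype_match: true}
    tier: likely pathogenic
    note: biallelic variants in a recessive disease gene
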