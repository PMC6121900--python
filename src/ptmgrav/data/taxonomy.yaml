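# Ordered PTM class-normalization and residue-chemistry grouping rules.
# Rules are applied top to bottom; the first matching pattern wins.
# Patterns are case-insensitive Python regular expressions matched against
# the modification text after typographic markup ("*N*-") and cross-link
# partner qualifiers ("(interchain with ...)") have been stripped.

# Known-typo and spelling-variant corrections applied before canonical lookup.
normalize:
  - pattern: '^n-acetylmelthionine$'
    canonical: N-acetylmethionine
  - pattern: '^glycyl[- ]lysine isopeptide(?:\s*\(lys-gly\))?$'
    canonical: Glycyl lysine isopeptide (Lys-Gly)

# Canonical spellings; matching is case-insensitive on the full string.
canonical_classes:
  - Phosphoserine
  - Phosphothreonine
  - Phosphotyrosine
  - Phosphohistidine
  - N6-acetyllysine
  - N6-methyllysine
  - N6,N6-dimethyllysine
  - N6-succinyllysine
  - N6-malonyllysine
  - N6-crotonyllysine
  - N-acetylmethionine
  - N-acetylthreonine
  - N-acetylserine
  - N-acetylalanine
  - N-acetylglycine
  - N-acetylvaline
  - N-acetylaspartate
  - N-acetylglutamate
  - N-linked (GlcNAc)
  - N-myristoyl glycine
  - Glycyl lysine isopeptide (Lys-Gly)
  - S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)
  - S-nitrosocysteine
  - S-palmitoyl cysteine
  - S-glutathionyl cysteine
  - C-linked (Man)
  - O-linked (Fuc)
  - O-linked (GalNAc)
  - O-linked (GlcNAc)
  - Hydroxyproline
  - Omega-N-methylarginine
  - Citrulline

# Residue-chemistry groups. PHOSPHORYLATION is deliberately restricted to
# the serine/threonine/tyrosine classes; extend the list to widen it.
groups:
  - pattern: '^phospho(serine|threonine|tyrosine)$'
    group: PHOSPHORYLATION
  - pattern: '^n6[-,].*lysine$'
    group: LYSINE_N6
  - pattern: '^glycyl lysine isopeptide'
    group: GLY_LYS_ISOPEPTIDE
  - pattern: '^s-'
    group: SULFUR
  - pattern: '^n-'
    group: OTHER_NITROGEN
  # anything else (O-linked, C-linked, hydroxylation, ...) falls to OTHER

# Unique chemically-targeted residue per class, where one exists.
# O-linked glycans (Ser or Thr) have no unique target and carry no rule.
target_residues:
  - pattern: '^phosphoserine$'
    residue: S
  - pattern: '^phosphothreonine$'
    residue: T
  - pattern: '^phosphotyrosine$'
    residue: Y
  - pattern: '^phosphohistidine$'
    residue: H
  - pattern: '^n6[-,].*lysine$'
    residue: K
  - pattern: '^glycyl lysine isopeptide'
    residue: K
  - pattern: '^s-(cysteinyl|nitroso|palmitoyl|glutathionyl)'
    residue: C
  - pattern: '^n-linked'
    residue: N
  - pattern: '^n-acetylmethionine$'
    residue: M
  - pattern: '^n-acetylthreonine$'
    residue: T
  - pattern: '^n-acetylserine$'
    residue: S
  - pattern: '^n-acetylalanine$'
    residue: A
  - pattern: '^n-acetylglycine$'
    residue: G
  - pattern: '^n-acetylvaline$'
    residue: V
  - pattern: '^n-acetylaspartate$'
    residue: D
  - pattern: '^n-acetylglutamate$'
    residue: E
  - pattern: '^n-myristoyl glycine$'
    residue: G
  - pattern: '^c-linked'
    residue: W
  - pattern: '^hydroxyproline$'
    residue: P
  - pattern: '^omega-n-methylarginine$'
    residue: R
  - pattern: '^citrulline$'
    residue: R
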