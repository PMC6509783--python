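# Default GH45 diagnostic scheme.
#
# The five positions are the classical GH45 active-site residues, numbered
# on the fungal (Humicola insulens) endoglucanase reference: the conserved
# tyrosine (Tyr8), the catalytic base (Asp10), the conserved alanine
# (Ala74), the substrate-stabilizing aspartate (Asp114) and the catalytic
# acid / proton donor (Asp121).
#
# SYNTHETIC REFERENCE: the reference sequence below is a constructed
# stand-in carrying the canonical residues at the documented positions,
# not the real fungal protein.  Substitute the genuine reference sequence
# here (same positions) to diagnose against the real structure's numbering.
reference:
  id: GH45_ref_synthetic
  taxon: synthetic
  residues: >-
    QIHSRSNYPDITFNMANTGEPFQKHISCKGCNFKIQEYTPFFPWDQAAVIDNDKAFIIGTWKMQWFFQATEMEA
    QEDQEIHIKKVNVNLTKCMEWYFIWHDRKLFKITAMPTIDLMSIVVDLYKLVYVLWMVDASVPQWQSHSGAVLK
    AMQAYGCRQNCSFGQGAMAEECYKKDTYWIAM

# 1-based positions on the ungapped reference, with the residue expected
# in the reference itself (checked at load time).
positions:
  tyr: {position: 8, expected: Y}
  cat_base: {position: 10, expected: D}
  ala: {position: 74, expected: A}
  stabilizer: {position: 114, expected: D}
  cat_acid: {position: 121, expected: D}

# Ordered classification rules; the first matching rule wins.  A gap at any
# diagnostic position short-circuits to 'indeterminate' before the rules
# run.  Condition keys: one diagnostic position name mapping to either
# {is: X}, {in: [..]} or {not_in: [..]}.
rules:
  - name: catalytic_acid_lost
    when: {cat_acid: {not_in: [D, E]}}
    label: inactive
    confidence: high
  - name: catalytic_base_lost
    when: {cat_base: {not_in: [D, E]}}
    label: inactive
    confidence: high
  - name: acid_D_to_E
    when: {cat_acid: {is: E}}
    label: xyloglucanase
    confidence: high
  - name: stabilizer_D_to_E
    when: {stabilizer: {is: E}}
    label: xyloglucanase
    confidence: high
  - name: stabilizer_lost
    when: {stabilizer: {not_in: [D, E]}}
    label: inactive
    confidence: low
  - name: ala_to_gly
    when: {ala: {is: G}}
    label: inactive
    confidence: low

default:
  label: glucanase
  confidence: high

# Fired when the default applies but a position is unusual without any rule
# matching; recorded as evidence, never changes the label.
warnings:
  - name: tyr_substituted
    when: {tyr: {not_in: [Y, F]}}
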