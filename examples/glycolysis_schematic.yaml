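# Schematic fermentation-style pathway, for illustration only.
# The stoichiometries use canonical cofactor ids (atp, adp, nadh, nad, pi)
# so the shipped cofactor constraints apply; the dg0_prime values are
# round-number placeholders, not curated thermochemistry.
name: glycolysis-schematic
metadata:
  ph: 7.0
  provenance: illustrative example, not a curated reconstruction
reactions:
  - {id: HEX, formula: "glc + atp <=> g6p + adp", dg0_prime: -17.0}
  - {id: PGI, formula: "g6p <=> f6p", dg0_prime: 2.5}
  - {id: PFK, formula: "f6p + atp <=> fbp + adp", dg0_prime: -15.0}
  - {id: ALD, formula: "fbp <=> dhap + g3p", dg0_prime: 20.0}
  - {id: TPI, formula: "dhap <=> g3p", dg0_prime: 5.5}
  - {id: GAPDH_PGK, formula: "g3p + nad + pi + adp <=> pg3 + nadh + atp", dg0_prime: -12.0}
  - {id: ENO_PYK, formula: "pg3 + adp <=> pyr + atp", dg0_prime: -25.0}
atp_accounting:
  substrate_level_atp: 2
  carriers:
    NADH: 2
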