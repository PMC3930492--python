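# mdfkit

Max-min Driving Force (MDF) analysis of metabolic pathways.

Given a pathway's reaction stoichiometries (actual molecularities, written
in the net-flux direction) and standard transformed Gibbs energies
(ΔrG′°, kJ/mol), `mdfkit` finds the metabolite concentration profile —
within physiological bounds — that maximizes the *smallest* reaction
driving force (−ΔrG′). The optimum (the MDF) measures how far from
equilibrium the worst pathway step can be pushed; a pathway is
thermodynamically feasible iff its MDF is positive. The LP dual provides
shadow prices identifying the reactions and metabolites that limit the
MDF, and the flux-force relationship converts driving forces into the
fraction of enzyme capacity realized as net flux.

## What's inside

| module | contents |
| --- | --- |
| `mdfkit.thermo` | flux-force relationships: forward/reverse flux ratio, reverse-flux fraction, flux-force efficacy |
| `mdfkit.model` | compounds, reactions, formula parsing, stoichiometric matrix, concentration constraints (bounds, fixed cofactors, cofactor ratios) |
| `mdfkit.lp` | the max-min LP (scipy/HiGHS), shadow-price extraction, explicit dual fallback, sensitivity checks, a brute-force grid oracle |
| `mdfkit.analysis` | pH sweeps over tabulated ΔrG′°(pH), ATP-yield accounting (P/O rules), MDF-vs-yield Pareto fronts, enzyme-demand report |
| `mdfkit.fileio` / `mdfkit.cli` | YAML pathway files, TSV reaction tables, JSON/TSV reports, the `mdf` command |
| `mdfkit.fixtures` | synthetic chains with closed-form optima and seeded random instances for testing |

Default constraints: every metabolite ranges over 1 µM – 10 mM; common
cofactors are fixed ([Pi] = 10 mM, [PPi] = 1 mM, [CoA] = 1 mM,
[CO2(aq)] = 10 µM) or ratio-constrained (ATP/ADP = 10, ADP/AMP = 1,
NADH/NAD⁺ = 0.1, NADPH/NADP⁺ = 10, Fd_red/Fd_ox = 1). All of this is
editable per pathway file or run config. Temperature defaults to 298.15 K
(RT ≈ 2.479 kJ/mol).

## CLI

```sh
# solve one pathway; writes NAME.mdf.json and NAME.mdf.tsv
mdf solve examples/glycolysis_schematic.yaml --out-dir out/

# override a concentration bound (molar)
mdf solve pathway.yaml --set-bound fbp:upper=15e-3

# MDF as a function of pH (needs per-reaction dg0_by_ph tables)
mdf sweep pathway.yaml --ph-from 5 --ph-to 9 --ph-steps 17 --out sweep.tsv

# compare pathways by MDF vs ATP yield, flag the Pareto front
mdf compare p1.yaml p2.yaml p3.yaml --out compare.tsv
```

Exit codes: `0` — optimal solve (including a negative-MDF *verdict*),
`2` — input/constraint error, `3` — infeasible constraint system,
`4` — numerical failure.

Pathway files are YAML with `reactions` (formula strings such as
`"f6p + atp <=> fbp + adp"` plus `dg0_prime`), optional `compounds`,
`constraints` overrides, and a declarative `atp_accounting` stanza; see
`examples/glycolysis_schematic.yaml` (illustrative energies, not curated
thermochemistry). A TSV reaction-table dialect
(`id  formula  dg0_prime_kj_mol`) is also read.

## Library

```python
from mdfkit import PathwayModel, Reaction, solve_mdf

pw = PathwayModel(name="demo")
pw.add_reaction(Reaction.from_formula("R1", "A <=> B", dg0_prime=-4.0))
pw.add_reaction(Reaction.from_formula("R2", "B <=> C", dg0_prime=-4.0))
res = solve_mdf(pw)          # default physiological constraints
res.mdf                      # kJ/mol
res.reaction_shadow_prices   # sum to 1 at the optimum
res.bottlenecks()            # reactions limiting the MDF
```

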