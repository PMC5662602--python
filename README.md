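# polygea

Constraint-based gene essentiality analysis for polyamine biosynthesis.

Polyamines (putrescine, spermidine, spermine) are polycations that cancer
cells over-produce and depend on, yet the biomass equations of in-silico
cancer metabolic models typically omit them — so a standard flux balance
analysis (FBA) screen never flags the genes that keep the pathway running.
`polygea` is a small, exact toolkit for asking what changes when biomass
*does* demand polyamines: it amends the biomass equation, runs single- and
double-gene-deletion screens driven by gene–protein–reaction (GPR) boolean
rules, and applies the annotation correction under which adenine
phosphoribosyltransferase (**APRT**) emerges as an essential gene — because
spermidine/spermine synthesis releases 5′-methylthioadenosine (MTA), MTAP
converts MTA to adenine, and once purine-nucleoside phosphorylase (PNP) is
no longer credited with degrading adenine (it does not, in human cells),
APRT is the only route that clears it.

It is aimed at systems-biology practitioners who want a transparent,
dependency-light implementation of the screen — with exact-rational
stoichiometry, an LP-free reachability oracle for verification, and a
planted-truth model generator — rather than at users of genome-scale
reconstructions (for those, use cobrapy; `polygea` reads only its own
documented JSON dialect).

## The model and the screen

FBA predicts steady-state fluxes v over the stoichiometric matrix S:

```
max  v_bio
s.t. S v = 0                  (steady state, every metabolite balanced)
     l_r ≤ v_r ≤ u_r          (bounds; irreversible ⇒ l_r = 0,
                               unbounded directions capped at ±M)
```

The growth medium enters through exchange-reaction lower bounds (intake of
absent nutrients fixed to zero). For a gene g, the GPR rules give the set
N(g) of reactions that lose their enzyme when g is deleted; clamping those
fluxes to zero and re-solving gives the knockout growth. A gene is
**essential** when that optimum falls below a lethality threshold
(default 10⁻⁴ gDW/h); a **synthetic-lethal pair** is two individually
non-essential genes whose joint deletion is lethal. LP solves are memoized
by disabled-reaction set, so gene pairs that collapse onto the same
reaction knockout cost one solve.

## Worked example

```python
from polygea import (build_polyamine_minimodel, correct_pnp_annotation,
                     double_deletion_screen)

model = build_polyamine_minimodel()          # polyamine-amended biomass
res = double_deletion_screen(model)
print(sorted(res.essential_genes))
print(sorted(res.synthetic_lethal_pairs))

corrected, removed = correct_pnp_annotation(model)
print(removed, sorted(double_deletion_screen(corrected).essential_genes))
```

prints

```
['AMD1', 'MTAP', 'ODC1', 'SMS', 'SRM']
[('APRT', 'PNP'), ('ARG1', 'OAT'), ('MAT1A', 'MAT2A'), ('MAT1A', 'MAT2B')]
['R_PNP_ade'] ['AMD1', 'APRT', 'MTAP', 'ODC1', 'SMS', 'SRM']
```

AMD1, MTAP, ODC1 and SRM are lethal to delete because each sits on the
only route to a demanded polyamine (MTAP because MTA would otherwise
accumulate, which steady state forbids). The MAT isozyme pairs and
ARG1/OAT are redundant routes to SAM and ornithine respectively — lethal
only jointly. APRT&PNP is synthetic-lethal *only* while the model
mis-credits PNP with adenine degradation; removing `R_PNP_ade` leaves APRT
as the sole adenine consumer and promotes it to essential. SMS (spermine
synthase) is flagged because the curated model demands spermine in
biomass; see `docs/methods.md`.

The `examples/` scripts walk through each capability (screens,
biomass differential, threshold sweep, planted-truth validation), and the
`gea` command line exposes the same pipeline
(`gea screen --fixture polyamine --biomass +polyamines --double`,
`gea simulate`, `gea curate`, `gea sweep`, `gea convert`).

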