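# Methods

## Model representation

A model is an ordered collection of metabolites and reactions, a gene set,
a designated biomass reaction, and a medium map. Stoichiometric
coefficients are exact rationals (`fractions.Fraction`), converted to
floats only when the LP matrix is assembled; serialization (a documented
subset of the community COBRA-JSON layout, schema in
`src/polygea/schema/model.schema.json`) therefore round-trips bit-exactly,
including decimal coefficients such as the 0.01 polyamine demand.
Insertion order is preserved end to end so the stoichiometric matrix — and
hence every solver run — is reproducible from the file alone.

GPR rules are ASTs over gene leaves with AND/OR connectives only. `not`
is rejected at parse time: gene–protein associations in metabolic
reconstructions are monotone (an enzyme never appears because a gene was
deleted), and monotonicity is what makes deletion screens well-defined —
enlarging the deleted set can only disable more reactions. This
monotonicity is enforced by construction and checked as a property test.

## The linear program

Maximize the biomass flux subject to `S v = 0` and per-reaction bounds.
Numerical choices:

- **big_M = 1000 mmol·gDW⁻¹·h⁻¹** caps unbounded directions, the common
  community convention for "a large positive scalar".
- **feas_tol = opt_tol = 1e-9**, five orders of magnitude below the 1e-4
  lethality threshold, so no classification can hinge on solver noise.
  The solver (HiGHS via `scipy.optimize.linprog`, with primal/dual
  tolerances tightened to 1e-10) returns a solution that is re-checked
  against mass-balance residuals and bounds within `feas_tol` scaled by
  the largest flux magnitude — a cheap certificate, raised as an error if
  violated rather than silently accepted.
- Objectives within ±opt_tol of zero are reported as exactly 0, so sign
  noise cannot flip an essentiality call.
- The backend is pluggable behind one solve-LP contract; the three HiGHS
  variants (`highs`, `highs-ds`, `highs-ipm`) are exposed and tested to
  agree within opt_tol. Knockouts clamp bounds to [0, 0], which is tested
  equivalent to deleting the matrix column.

Infeasible knockout models (possible when a reaction carries a forced
positive lower bound) are treated as zero growth for classification —
a cell that cannot satisfy its constraints cannot grow.

## Screens

Essentiality uses the **strict** inequality `growth < threshold`; a tie at
exactly the threshold is non-essential (the threshold is the *minimum*
biomass production compatible with proliferation). The default threshold
is 1e-4 gDW/h. Genes appearing in no GPR rule are recorded at wild-type
growth without an LP solve. The double-deletion screen covers all
unordered pairs of non-essential genes occurring in at least one GPR by
default, with an optional candidate restriction; growth values are
memoized by disabled-reaction set, so e.g. the pair {MAT1A, gene-with-no-
reactions} reuses the single-deletion solve. The threshold sweep
reclassifies the per-gene growth values at each threshold — one LP per
gene total — and its output is a chain under inclusion by construction.

## The curated mini-model

`build_polyamine_minimodel` encodes the polyamine pathway at desk scale:
methionine → SAM (MAT, GPR `MAT1A or (MAT2A and MAT2B)`) → dcSAM (AMD1);
arginine →(ARG1) ornithine ←(OAT, reversible) glutamate-5-semialdehyde;
ornithine →(ODC1) putrescine; SRM and SMS transfer aminopropyl groups
from dcSAM to make spermidine and spermine, each releasing MTA; MTAP is
the sole MTA consumer, yielding adenine; APRT (adenine + PRPP → AMP) and,
until corrected, a mis-annotated PNP reaction (adenine → adenosine) are
the only adenine consumers. Biomass consumes a generic precursor plus,
when amended, the three polyamines. Each load-bearing structural fact —
one MTA consumer, two adenine consumers before correction and one after,
two ornithine producers — is asserted directly in the tests. The GPR
strings are reverse-engineered from the reported essentiality pattern
(the source reconstruction's rules are not published alongside it), and
each reaction's gene assignment is the standard one for that enzyme.

**SMS.** The spermine-synthase step is chemically required when spermine
is demanded in biomass, so the screen flags SMS essential even though the
published gene lists do not mention it — most plausibly a GPR gap in the
source reconstruction. Tests and acceptance therefore assert containment
of the listed genes, not set equality over genes the lists are silent on.

**Polyamine demand coefficient.** The exact amendment values are deferred
to supplementary material of the source analysis that is not part of this
package's inputs; the shipped default is 0.01 mmol·gDW⁻¹ per polyamine, a
typical magnitude for minor biomass species in published reconstructions,
and is explicitly a configurable stand-in. The qualitative screen cannot
depend on it: classifications are tested invariant over [1e-4, 1].

**Medium.** Seven nutrients (methionine, arginine,
glutamate-5-semialdehyde, phosphate, PRPP, ATP, generic precursor) at a
10 mmol·gDW⁻¹·h⁻¹ intake cap each. Wild-type growth is then exactly
10 gDW/h (precursor-limited), every lethal knockout grows at exactly 0,
and every viable one at wild type — which is why the essential set is
flat across thresholds from 1e-8 to 5.

**XDH branch.** The optional adenine → 2,8-dihydroxyadenine (DHA) branch
models the hypothesis that excess adenine drains to a toxic end product.
DHA is toxic *because* cells cannot dispose of it, so the branch's sink
ships closed (bound 0): at steady state XDH then cannot clear adenine and
APRT remains essential. Opening the sink (`dha_sink_bound > 0`) models a
hypothetical benign drain instead, under which the APRT knockout is
rescued; both regimes are tested.

## The planted-truth generator

`generate_model` assembles networks from three motif types with exactly
known essentiality: linear exchange→…→biomass chains (every step gene
essential), two-branch OR-redundant modules (the branch genes form a
synthetic-lethal pair, neither essential), and AND-complex steps (both
subunit genes essential). Biomass consumes every module's terminal
metabolite, so each planted gene gates a biomass-feeding bridge. All
internal coefficients are ±1 and every byproduct is consumed or sinked,
keeping the models inside the oracle-safe class. Randomness (a single
seeded `numpy` generator) only permutes gene labels; same seed and
parameters give byte-identical serialized models. What the generator does
**not** emulate: genome-scale size, fractional stoichiometry, cofactor
coupling, compartments, or overlapping pathways — so passing the planted
suite certifies the screen's logic (GPR handling, LP construction,
memoization, pair enumeration), not its behaviour on real
reconstructions.

## The reachability oracle

For oracle-safe models the package carries an LP-free verdict:
forward hypergraph reachability from the medium metabolites (a reaction
direction fires iff its GPR holds and all substrates are reachable),
interleaved with a byproduct-clearance prune — a fired direction whose
product is neither a biomass substrate nor consumed by some *other* fired
direction cannot carry steady-state flux and is removed, after which
reachability is recomputed to a fixed point. The reverse direction of the
same reversible reaction never counts as clearing its own product (that
is futile cycling, not net consumption). Clearance is precisely the
steady-state requirement that makes MTAP essential: without MTAP, MTA has
no consumer, so the spermidine/spermine synthases cannot run even though
naive reachability would reach every biomass substrate. Outside the
oracle-safe class (non-±1 internal coefficients, unconsumable products)
the checker refuses rather than risk a wrong answer; the biomass reaction
is exempt from the ±1 rule because it only consumes, and producibility of
its substrates does not depend on demand magnitudes. Oracle/LP agreement
is asserted exhaustively — every single and double deletion — on the
mini-model and on 100 generated models per run; it is an empirically
certified equivalence on this class, not a general theorem.

## Verification strategy

Three mutually independent routes must agree: (1) the package's own
scipy-built LP screen, (2) the reachability oracle above, and
(3) cobrapy's FBA and gene-deletion machinery (GLPK backend) on a
converted copy of the mini-model. The test suite also carries the
structural invariants (GPR monotonicity, knockout monotonicity,
pair growth ≤ min single growth, row-scaling invariance, sweep
monotonicity, serializer exactness) as property or parametrized tests.
Problem sizes — a 23-reaction mini-model and 100 generated models of at
most 15 genes with exhaustive pair screens — were chosen so the whole
suite and the acceptance script each complete in well under a minute on a
single CPU.

## Known limitations

- Plain FBA only: no flux-variability analysis, no parsimonious FBA, no
  MOMA/ROOM knockout models, no triple deletions.
- The JSON dialect is the only on-disk format; SBML is not read or
  written.
- The oracle's correctness class is deliberately narrow; it refuses
  general models instead of extending to them.
- The mini-model reproduces the pathway's essentiality logic, not the
  genome-scale context (alternative routes, cofactor costs, tissue
  expression) of a full cancer reconstruction — conclusions about genes
  outside the polyamine pathway cannot be drawn from it.
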