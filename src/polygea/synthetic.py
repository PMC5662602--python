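"""Synthetic models: the curated polyamine mini-model, a seeded random
network generator with planted ground truth, and an LP-free reachability
oracle for small instances.

The mini-model encodes the polyamine biosynthesis pathway of a human
cancer reconstruction at desk scale: methionine adenosyltransferase (MAT)
makes SAM, AMD1 decarboxylates it to dcSAM, ornithine (from arginase ARG1
or ornithine transaminase OAT) is decarboxylated by ODC1 to putrescine,
and SRM/SMS attach aminopropyl groups from dcSAM to yield spermidine and
spermine, releasing 5'-methylthioadenosine (MTA). MTAP is the only MTA
consumer, producing adenine; adenine is consumed by APRT (and, before the
annotation correction, by a mis-annotated PNP reaction). The structural
facts mirrored here — one MTA consumer, two adenine consumers before
correction, two ornithine producers — carry the essentiality results.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

import numpy as np

from .curation import DEFAULT_POLYAMINE_COEFFICIENT
from .model import (
    EMPTY_RULE,
    GeneLeaf,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
)

__all__ = [
    "build_polyamine_minimodel",
    "GeneratorParams",
    "PlantedTruth",
    "generate_model",
    "reachability_oracle",
    "check_oracle_safe",
    "OracleUnsafeError",
    "GenerationError",
]

_F1 = Fraction(1)


def _rxn(rid, stoich, gpr="", lb=0.0, ub=1000.0, rev=False, ex=False, name=""):
    return Reaction(
        id=rid,
        name=name,
        stoichiometry={m: Fraction(c) for m, c in stoich.items()},
        lower_bound=lb,
        upper_bound=ub,
        reversible=rev,
        gpr=parse_gpr(gpr),
        is_exchange=ex,
    )


def build_polyamine_minimodel(
    corrected_pnp: bool = False,
    include_polyamines_in_biomass: bool = True,
    polyamine_coefficient: float = DEFAULT_POLYAMINE_COEFFICIENT,
    uptake: float = 10.0,
) -> MetabolicModel:
    """The curated polyamine-pathway mini-model.

    Parameters
    ----------
    corrected_pnp:
        If False (the state of the original reconstruction), a mis-annotated
        PNP reaction degrading adenine to adenosine is present. If True, the
        annotation is corrected and that reaction is absent.
    include_polyamines_in_biomass:
        If True, biomass consumes putrescine, spermidine and spermine in
        addition to a generic precursor, so polyamine synthesis is required
        for growth. If False, biomass consumes the precursor only (the
        unamended biomass, under which no pathway gene is essential).
    polyamine_coefficient:
        Biomass demand per polyamine, mmol·gDW⁻¹.
    uptake:
        Maximal intake flux for every medium nutrient, mmol·gDW⁻¹·h⁻¹.
    """
    mets = [
        Metabolite("met_L", "L-methionine"),
        Metabolite("arg_L", "L-arginine"),
        Metabolite("glu5sa", "L-glutamate 5-semialdehyde"),
        Metabolite("pi", "phosphate"),
        Metabolite("prpp", "5-phospho-alpha-D-ribose 1-diphosphate"),
        Metabolite("atp", "ATP"),
        Metabolite("precursor", "generic biomass precursor"),
        Metabolite("sam", "S-adenosyl-L-methionine"),
        Metabolite("dcsam", "decarboxylated SAM"),
        Metabolite("orn", "ornithine"),
        Metabolite("ptrc", "putrescine"),
        Metabolite("spmd", "spermidine"),
        Metabolite("sprm", "spermine"),
        Metabolite("mta", "5'-methylthioadenosine"),
        Metabolite("ade", "adenine"),
        Metabolite("mtr1p", "5-methylthio-D-ribose 1-phosphate"),
        Metabolite("adn", "adenosine"),
        Metabolite("amp", "AMP"),
        Metabolite("co2", "CO2"),
        Metabolite("ppi", "diphosphate"),
    ]
    medium_mets = ["met_L", "arg_L", "glu5sa", "pi", "prpp", "atp", "precursor"]
    reactions = [
        _rxn(f"EX_{m}", {m: -1}, lb=-uptake, rev=True, ex=True, name=f"{m} exchange")
        for m in medium_mets
    ]
    reactions += [
        _rxn(f"SK_{m}", {m: -1}, ex=True, name=f"{m} sink")
        for m in ("mtr1p", "adn", "amp", "co2", "ppi")
    ]
    reactions += [
        _rxn(
            "R_MAT",
            {"met_L": -1, "atp": -1, "sam": 1, "pi": 1, "ppi": 1},
            gpr="MAT1A or (MAT2A and MAT2B)",
            name="methionine adenosyltransferase",
        ),
        _rxn(
            "R_AMD1",
            {"sam": -1, "dcsam": 1, "co2": 1},
            gpr="AMD1",
            name="adenosylmethionine decarboxylase",
        ),
        _rxn("R_ARG1", {"arg_L": -1, "orn": 1}, gpr="ARG1", name="arginase"),
        _rxn(
            "R_OAT",
            {"glu5sa": -1, "orn": 1},
            gpr="OAT",
            lb=-1000.0,
            rev=True,
            name="ornithine transaminase (reversible)",
        ),
        _rxn(
            "R_ODC1",
            {"orn": -1, "ptrc": 1, "co2": 1},
            gpr="ODC1",
            name="ornithine decarboxylase",
        ),
        _rxn(
            "R_SRM",
            {"ptrc": -1, "dcsam": -1, "spmd": 1, "mta": 1},
            gpr="SRM",
            name="spermidine synthase",
        ),
        _rxn(
            "R_SMS",
            {"spmd": -1, "dcsam": -1, "sprm": 1, "mta": 1},
            gpr="SMS",
            name="spermine synthase",
        ),
        _rxn(
            "R_MTAP",
            {"mta": -1, "pi": -1, "ade": 1, "mtr1p": 1},
            gpr="MTAP",
            name="5'-methylthioadenosine phosphorylase",
        ),
        _rxn(
            "R_APRT",
            {"ade": -1, "prpp": -1, "amp": 1, "ppi": 1},
            gpr="APRT",
            name="adenine phosphoribosyltransferase",
        ),
    ]
    if not corrected_pnp:
        reactions.append(
            _rxn(
                "R_PNP_ade",
                {"ade": -1, "adn": 1},
                gpr="PNP",
                name="purine-nucleoside phosphorylase on adenine (mis-annotation)",
            )
        )
    bio_stoich: dict[str, Fraction] = {"precursor": -_F1}
    if include_polyamines_in_biomass:
        c = Fraction(repr(float(polyamine_coefficient)))
        bio_stoich.update({"ptrc": -c, "spmd": -c, "sprm": -c})
    reactions.append(
        _rxn("R_BIOMASS", bio_stoich, name="biomass equation")
    )
    genes = {
        "MAT1A", "MAT2A", "MAT2B", "AMD1", "ARG1", "OAT", "ODC1",
        "SRM", "SMS", "MTAP", "APRT", "PNP",
    }
    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        genes=genes,
        biomass_reaction_id="R_BIOMASS",
        medium={f"EX_{m}": uptake for m in medium_mets},
        id="polyamine_minimodel",
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Random model generator with planted truth
# ---------------------------------------------------------------------------


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the planted-truth network generator.

    The generator builds ``n_linear_chains`` independent substrate-to-
    precursor chains of ``chain_length`` reactions (each gated by its own
    gene: all essential), ``n_redundant_branches`` two-route OR-redundant
    modules (the two branch genes form a synthetic-lethal pair, neither
    essential), and ``n_complex_reactions`` chain steps gated by a
    two-gene AND complex (both subunits essential). Biomass consumes every
    module's terminal metabolite, so each planted gene sits on a bridge of
    a biomass-feeding path.
    """

    n_linear_chains: int = 1
    chain_length: int = 3
    n_redundant_branches: int = 1
    n_complex_reactions: int = 0
    seed: int = 0

    def __post_init__(self):
        if min(
            self.n_linear_chains,
            self.chain_length,
            self.n_redundant_branches,
            self.n_complex_reactions,
        ) < 0:
            raise GenerationError("generator counts must be non-negative")


@dataclass(frozen=True)
class PlantedTruth:
    essential_genes: frozenset[str]
    synthetic_lethal_pairs: frozenset[tuple[str, str]]


def generate_model(params: GeneratorParams) -> tuple[MetabolicModel, PlantedTruth]:
    """Generate a random stoichiometric network with known essentiality.

    Same seed, same params ⇒ byte-identical serialized model. Randomness
    only permutes gene labels and module order; the planted truth is exact
    by construction.
    """
    if (
        params.n_linear_chains == 0
        and params.n_redundant_branches == 0
        and params.n_complex_reactions == 0
    ):
        raise GenerationError("degenerate params: no path can feed biomass")
    rng = np.random.default_rng(params.seed)
    n_genes = (
        params.n_linear_chains * params.chain_length
        + 2 * params.n_redundant_branches
        + 2 * params.n_complex_reactions
    )
    gene_pool = [f"G{i:03d}" for i in rng.permutation(n_genes)]
    gene_iter = iter(gene_pool)

    mets: list[Metabolite] = []
    reactions: list[Reaction] = []
    genes: set[str] = set()
    bio_stoich: dict[str, Fraction] = {}
    essential: set[str] = set()
    lethal_pairs: set[tuple[str, str]] = set()

    def add_met(mid: str):
        mets.append(Metabolite(mid))
        return mid

    def add_exchange(mid: str, uptake: float = 10.0):
        reactions.append(
            _rxn(f"EX_{mid}", {mid: -1}, lb=-uptake, rev=True, ex=True)
        )

    def next_gene() -> str:
        g = next(gene_iter)
        genes.add(g)
        return g

    # linear chains: every step gene is essential
    for ci in range(params.n_linear_chains):
        prev = add_met(f"c{ci}_m0")
        add_exchange(prev)
        for si in range(params.chain_length):
            cur = add_met(f"c{ci}_m{si + 1}")
            g = next_gene()
            essential.add(g)
            reactions.append(
                _rxn(f"R_c{ci}_s{si}", {prev: -1, cur: 1}, gpr=g)
            )
            prev = cur
        bio_stoich[prev] = -_F1

    # OR-redundant modules: two parallel branch reactions, one gene each
    for bi in range(params.n_redundant_branches):
        src = add_met(f"b{bi}_src")
        dst = add_met(f"b{bi}_dst")
        add_exchange(src)
        ga, gb = next_gene(), next_gene()
        reactions.append(_rxn(f"R_b{bi}_a", {src: -1, dst: 1}, gpr=ga))
        reactions.append(_rxn(f"R_b{bi}_b", {src: -1, dst: 1}, gpr=gb))
        lethal_pairs.add((ga, gb) if ga <= gb else (gb, ga))
        bio_stoich[dst] = -_F1

    # AND-complex steps: both subunit genes essential
    for ki in range(params.n_complex_reactions):
        src = add_met(f"k{ki}_src")
        dst = add_met(f"k{ki}_dst")
        add_exchange(src)
        ga, gb = next_gene(), next_gene()
        reactions.append(
            _rxn(f"R_k{ki}", {src: -1, dst: 1}, gpr=f"{ga} and {gb}")
        )
        essential.update((ga, gb))
        bio_stoich[dst] = -_F1

    reactions.append(_rxn("R_BIOMASS", bio_stoich))
    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        genes=genes,
        biomass_reaction_id="R_BIOMASS",
        medium={r.id: 10.0 for r in reactions if r.is_exchange},
        id=f"planted_seed{params.seed}",
    )
    model.validate()
    return model, PlantedTruth(frozenset(essential), frozenset(lethal_pairs))


# ---------------------------------------------------------------------------
# Reachability oracle
# ---------------------------------------------------------------------------


class OracleUnsafeError(ValueError):
    """The model is outside the class the oracle is guaranteed correct on."""


def check_oracle_safe(model: MetabolicModel) -> None:
    """Verify the model is in the oracle-safe class, else refuse.

    Requirements: every non-biomass stoichiometric coefficient is ±1; the
    biomass reaction only consumes (any positive demand magnitudes —
    producibility of its substrates does not depend on them); every
    metabolite produced by an internal reaction has at least one potential
    consumer (another reaction, a sink/exchange, or biomass). Within this
    class, hypergraph reachability with byproduct clearance decides
    biomass producibility; outside it the oracle refuses rather than risk
    a wrong answer.
    """
    problems: list[str] = []
    for r in model.reactions:
        if r.id == model.biomass_reaction_id:
            continue
        for m, c in r.stoichiometry.items():
            if abs(c) != 1:
                problems.append(
                    f"reaction {r.id!r}: coefficient of {m!r} is {c}, not ±1"
                )
    bio = model.biomass_reaction
    if any(c > 0 for c in bio.stoichiometry.values()):
        problems.append("biomass reaction has products")
    consumers: set[str] = set()
    for r in model.reactions:
        for m in r.substrates():
            consumers.add(m)
        if r.reversible:
            for m in r.products():
                consumers.add(m)
    for r in model.reactions:
        if r.id == model.biomass_reaction_id:
            continue
        for m in r.products():
            if m not in consumers:
                problems.append(
                    f"product {m!r} of reaction {r.id!r} has no potential consumer"
                )
    if problems:
        raise OracleUnsafeError(
            "model outside the oracle-safe class:\n  - " + "\n  - ".join(problems)
        )


def reachability_oracle(
    model: MetabolicModel, deleted: Iterable[str] = ()
) -> bool:
    """LP-free verdict: can the model sustain positive biomass flux?

    Forward hypergraph reachability from the medium metabolites — a
    reaction direction fires iff its GPR holds under *deleted* and all its
    substrates are reachable — interleaved with a byproduct-clearance
    prune: a fired reaction whose product has no distinct fired consumer
    (and is neither a biomass substrate nor sinked) cannot carry steady-
    state flux and is removed, after which reachability is recomputed. The
    clearance rule is exactly what makes MTAP essential in the mini-model:
    without it, MTA accumulates and the spermidine/spermine synthases
    cannot run at steady state. The reverse direction of the same
    reversible reaction never counts as the consumer of its own product
    (that would be futile cycling, not net clearance).
    """
    check_oracle_safe(model)
    deleted = frozenset(deleted)

    bio = model.biomass_reaction
    bio_substrates = set(bio.substrates())

    # directed reaction instances: (reaction id, +1 forward / -1 backward)
    Directed = tuple[str, int]
    directed: dict[Directed, tuple[set[str], set[str]]] = {}
    for r in model.reactions:
        if r.id == model.biomass_reaction_id:
            continue
        if not r.gpr.evaluate(deleted):
            continue
        subs, prods = set(r.substrates()), set(r.products())
        if r.upper_bound > 0:
            directed[(r.id, +1)] = (subs, prods)
        if r.lower_bound < 0:
            directed[(r.id, -1)] = (prods, subs)

    active = set(directed)

    def reachable_set(act: set[Directed]) -> tuple[set[str], set[Directed]]:
        reach: set[str] = set()
        fired: set[Directed] = set()
        changed = True
        while changed:
            changed = False
            for d in act - fired:
                subs, prods = directed[d]
                if subs <= reach:
                    fired.add(d)
                    if not prods <= reach:
                        reach |= prods
                    changed = True
        return reach, fired

    while True:
        reach, fired = reachable_set(active)
        # clearance prune over fired directions
        removed = False
        for d in sorted(fired):
            rid, sign = d
            _subs, prods = directed[d]
            ok = True
            for m in prods:
                if m in bio_substrates:
                    continue
                has_consumer = any(
                    d2 != d
                    and not (d2[0] == rid and d2[1] == -sign)
                    and m in directed[d2][0]
                    for d2 in fired
                )
                if not has_consumer:
                    ok = False
                    break
            if not ok:
                active.discard(d)
                removed = True
        if not removed:
            break

    if not bio.gpr.evaluate(deleted):
        return False
    return bio_substrates <= reach
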