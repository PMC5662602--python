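"""Model curation edits for the polyamine essentiality analysis.

Two edits drive the analysis: (1) augmenting the biomass equation with the
polyamines putrescine, spermidine and spermine, so that growth demands
their synthesis; and (2) correcting the PNP annotation — purine-nucleoside
phosphorylase accepts adenine as a substrate in prokaryotes but not in
human cells, so adenine-degrading reactions carried by PNP are removed
(its guanine/hypoxanthine/uracil reactions are kept). The correction turns
APRT from one half of a spurious synthetic-lethal pair into the sole
adenine consumer, hence an essential gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Mapping

from .model import (
    EMPTY_RULE,
    GeneLeaf,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

__all__ = [
    "BiomassSpec",
    "DEFAULT_POLYAMINE_COEFFICIENT",
    "polyamine_biomass_spec",
    "augment_biomass",
    "correct_pnp_annotation",
    "add_xdh_branch",
    "CurationWarning",
]

#: Default demand per polyamine, mmol per gDW of biomass. The magnitude is
#: that of minor biomass species in published human reconstructions; it is a
#: configurable stand-in, and essentiality calls are insensitive to it over
#: several orders of magnitude (the qualitative result cannot depend on the
#: precise demand level).
DEFAULT_POLYAMINE_COEFFICIENT = 0.01

#: Metabolite ids of the three polyamines in the curated mini-model.
POLYAMINE_METABOLITES = ("ptrc", "spmd", "sprm")


class CurationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class BiomassSpec:
    """Metabolite → coefficient map used to amend the biomass reaction.

    Coefficients are positive consumption amounts (mmol·gDW⁻¹): each listed
    metabolite is added to the biomass reaction as a substrate with
    stoichiometric coefficient −coefficient.
    """

    additions: Mapping[str, float]

    def __post_init__(self):
        bad = [m for m, c in self.additions.items() if not float(c) > 0]
        if bad:
            raise ModelValidationError(
                [f"biomass coefficient for {m!r} must be positive" for m in sorted(bad)]
            )


def polyamine_biomass_spec(
    coefficient: float = DEFAULT_POLYAMINE_COEFFICIENT,
) -> BiomassSpec:
    """The polyamine amendment: putrescine, spermidine, spermine at equal demand."""
    return BiomassSpec({m: coefficient for m in POLYAMINE_METABOLITES})


def augment_biomass(model: MetabolicModel, spec: BiomassSpec) -> MetabolicModel:
    """Return a copy whose biomass reaction additionally consumes *spec* metabolites.

    Re-augmenting a metabolite that is already a biomass substrate replaces
    its coefficient rather than summing, so the edit is idempotent. No
    reaction other than biomass is touched.
    """
    missing = sorted(m for m in spec.additions if not model.has_metabolite(m))
    if missing:
        raise ModelValidationError(
            [f"biomass spec metabolite {m!r} is not in the model" for m in missing]
        )
    out = model.copy()
    bio = out.biomass_reaction
    stoich = dict(bio.stoichiometry)
    for met, coeff in spec.additions.items():
        stoich[met] = -Fraction(repr(float(coeff)))
    out.replace_reaction(replace(bio, stoichiometry=stoich))
    return out


def _consumes(rxn: Reaction, met_id: str) -> bool:
    # direction-agnostic: a reversible reaction producing the metabolite
    # forward can consume it in reverse
    coeff = rxn.stoichiometry.get(met_id)
    if coeff is None:
        return False
    return coeff < 0 or (rxn.reversible and coeff > 0)


def correct_pnp_annotation(
    model: MetabolicModel,
    gene: str = "PNP",
    adenine_id: str = "ade",
) -> tuple[MetabolicModel, list[str]]:
    """Remove adenine-degrading reactions mis-annotated to PNP.

    Every reaction whose GPR references *gene* and that can consume the
    adenine metabolite is removed; PNP reactions on its genuine substrates
    (guanine, hypoxanthine, uracil) are retained untouched. Returns the
    corrected model and the removed reaction ids. If no reaction matches,
    the model is returned unchanged with an explicit warning — never a
    silent no-op.
    """
    to_remove = [
        r.id
        for r in model.reactions
        if gene in r.gpr.genes() and _consumes(r, adenine_id)
    ]
    out = model.copy()
    if not to_remove:
        warnings.warn(
            f"no {gene}-associated reaction consumes {adenine_id!r}; "
            "model returned unchanged",
            CurationWarning,
            stacklevel=2,
        )
        return out, []
    out.remove_reactions(to_remove)
    return out, to_remove


def add_xdh_branch(
    model: MetabolicModel,
    enabled: bool = False,
    adenine_id: str = "ade",
    dha_sink_bound: float = 0.0,
) -> MetabolicModel:
    """Optionally add an adenine → 2,8-dihydroxyadenine (DHA) branch via XDH.

    Off by default. When enabled, adds a DHA metabolite, an irreversible
    xanthine-dehydrogenase reaction (GPR: XDH) converting adenine to DHA,
    and a DHA sink, so the hypothesis that excess adenine drains to the
    toxic by-product can be explored. DHA is a toxic end product that cells
    cannot dispose of, so the sink ships closed (``dha_sink_bound=0``): the
    branch then cannot clear adenine at steady state and APRT stays
    essential. Opening the sink (bound > 0) models a hypothetical benign
    drain instead. Idempotent when the branch already exists.
    """
    out = model.copy()
    if not enabled:
        return out
    if out.has_reaction("R_XDH"):
        return out  # already present
    if out.has_metabolite("dha"):
        raise ModelValidationError(
            ["metabolite id 'dha' already exists but is not the XDH branch"]
        )
    if out.has_reaction("SK_dha"):
        raise ModelValidationError(["reaction id 'SK_dha' already exists"])
    out.add_metabolite(Metabolite("dha", "2,8-dihydroxyadenine"))
    out.genes.add("XDH")
    out.add_reaction(
        Reaction(
            id="R_XDH",
            name="xanthine dehydrogenase (adenine to DHA)",
            stoichiometry={adenine_id: Fraction(-1), "dha": Fraction(1)},
            lower_bound=0.0,
            upper_bound=1000.0,
            gpr=GeneLeaf("XDH"),
        )
    )
    out.add_reaction(
        Reaction(
            id="SK_dha",
            name="DHA sink (closed by default: toxic accumulation)",
            stoichiometry={"dha": Fraction(-1)},
            lower_bound=0.0,
            upper_bound=float(dha_sink_bound),
            is_exchange=True,
        )
    )
    return out
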