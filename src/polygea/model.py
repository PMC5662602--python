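"""Core data structures for constraint-based metabolic models.

A model is a stoichiometric network: metabolites, reactions with signed
stoichiometric coefficients (substrates negative, products positive), flux
bounds, and gene-protein-reaction (GPR) boolean rules that state which gene
combinations make a reaction available. One designated reaction is the
biomass equation; its flux is the growth rate.

Stoichiometric coefficients are stored as exact :class:`fractions.Fraction`
values and only converted to floats when a linear program is built, so
serialization round-trips are bit-exact.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GPRParseError",
    "ModelValidationError",
    "GeneRule",
    "GeneLeaf",
    "BoolAnd",
    "BoolOr",
    "EMPTY_RULE",
    "parse_gpr",
    "evaluate_gpr",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "reactions_disabled_by",
    "read_model",
    "write_model",
    "model_to_dict",
    "model_from_dict",
]


class GPRParseError(ValueError):
    """Raised for malformed GPR rule text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ModelValidationError(ValueError):
    """Aggregated model validation failure: all problems reported at once."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "model validation failed with %d error(s):\n  - %s"
            % (len(self.errors), "\n  - ".join(self.errors))
        )


# ---------------------------------------------------------------------------
# GPR boolean rules
# ---------------------------------------------------------------------------


class GeneRule:
    """Base class for GPR rule AST nodes (AND/OR over gene leaves)."""

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        raise NotImplementedError

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_string()!r})"


@dataclass(frozen=True)
class _EmptyRule(GeneRule):
    """No gene association: the reaction is always available."""

    def evaluate(self, deleted):
        return True

    def genes(self):
        return frozenset()

    def to_string(self):
        return ""


EMPTY_RULE = _EmptyRule()


@dataclass(frozen=True)
class GeneLeaf(GeneRule):
    gene: str

    def evaluate(self, deleted):
        return self.gene not in deleted

    def genes(self):
        return frozenset({self.gene})

    def to_string(self):
        return self.gene


@dataclass(frozen=True)
class BoolAnd(GeneRule):
    children: tuple[GeneRule, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND node needs at least two children")

    def evaluate(self, deleted):
        return all(c.evaluate(deleted) for c in self.children)

    def genes(self):
        return frozenset().union(*(c.genes() for c in self.children))

    def to_string(self):
        parts = [
            f"({c.to_string()})" if isinstance(c, BoolOr) else c.to_string()
            for c in self.children
        ]
        return " and ".join(parts)


@dataclass(frozen=True)
class BoolOr(GeneRule):
    children: tuple[GeneRule, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR node needs at least two children")

    def evaluate(self, deleted):
        return any(c.evaluate(deleted) for c in self.children)

    def genes(self):
        return frozenset().union(*(c.genes() for c in self.children))

    def to_string(self):
        parts = [
            f"({c.to_string()})" if isinstance(c, BoolAnd) else c.to_string()
            for c in self.children
        ]
        return " or ".join(parts)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule_text: str, known_genes: Iterable[str] | None = None) -> GeneRule:
    """Parse a GPR rule string into a boolean AST.

    Grammar: gene identifiers, parentheses, and the connectives ``and`` /
    ``or`` (case-insensitive). ``not`` is deliberately rejected: GPR rules
    in genome-scale reconstructions are monotone (isozymes = OR, complex
    subunits = AND). An empty or whitespace-only string yields the EMPTY
    rule (no gene association, always true).

    If *known_genes* is given, every leaf must name a gene in that set;
    unknown leaves raise :class:`ModelValidationError`.
    """
    if rule_text is None or not rule_text.strip():
        return EMPTY_RULE
    tokens = _tokenize(rule_text)
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else (None, len(rule_text))

    def parse_or() -> GeneRule:
        nonlocal idx
        children = [parse_and()]
        while True:
            tok, _pos = peek()
            if tok is not None and tok.lower() == "or":
                idx += 1
                children.append(parse_and())
            else:
                break
        if len(children) == 1:
            return children[0]
        flat: list[GeneRule] = []
        for c in children:
            flat.extend(c.children if isinstance(c, BoolOr) else [c])
        return BoolOr(tuple(flat))

    def parse_and() -> GeneRule:
        nonlocal idx
        children = [parse_atom()]
        while True:
            tok, _pos = peek()
            if tok is not None and tok.lower() == "and":
                idx += 1
                children.append(parse_atom())
            else:
                break
        if len(children) == 1:
            return children[0]
        flat: list[GeneRule] = []
        for c in children:
            flat.extend(c.children if isinstance(c, BoolAnd) else [c])
        return BoolAnd(tuple(flat))

    def parse_atom() -> GeneRule:
        nonlocal idx
        tok, pos = peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", pos)
        low = tok.lower()
        if tok == "(":
            idx += 1
            inner = parse_or()
            tok2, pos2 = peek()
            if tok2 != ")":
                raise GPRParseError("unbalanced parentheses: missing ')'", pos2)
            idx += 1
            return inner
        if tok == ")":
            raise GPRParseError("unbalanced parentheses: unexpected ')'", pos)
        if low in ("and", "or"):
            raise GPRParseError(f"unexpected connective {tok!r}", pos)
        if low == "not":
            raise GPRParseError("'not' is not allowed in GPR rules", pos)
        idx += 1
        return GeneLeaf(tok)

    rule = parse_or()
    tok, pos = peek()
    if tok is not None:
        raise GPRParseError(f"unexpected token {tok!r}", pos)
    if known_genes is not None:
        known = set(known_genes)
        unknown = sorted(rule.genes() - known)
        if unknown:
            raise ModelValidationError(
                [f"GPR leaf gene {g!r} is not in the model gene set" for g in unknown]
            )
    return rule


def evaluate_gpr(rule: GeneRule, deleted: Iterable[str]) -> bool:
    """Evaluate a GPR rule under a set of deleted genes.

    A leaf is true iff its gene is not deleted; AND/OR have standard boolean
    semantics; the EMPTY rule is always true (spontaneous reaction).
    """
    return rule.evaluate(frozenset(deleted))


# ---------------------------------------------------------------------------
# Metabolites, reactions, models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    """A reaction with exact-rational stoichiometry and flux bounds.

    Bounds are in mmol·gDW⁻¹·h⁻¹. Negative coefficients are substrates,
    positive are products. Exchange/sink reactions touch exactly one
    metabolite and cross the system boundary (negative flux = uptake for
    the ``met -> ∅`` convention used here).
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    reversible: bool = False
    gpr: GeneRule = EMPTY_RULE
    is_exchange: bool = False
    name: str = ""

    def __post_init__(self):
        object.__setattr__(
            self,
            "stoichiometry",
            {m: Fraction(c) for m, c in self.stoichiometry.items()},
        )

    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    Metabolite and reaction order is insertion order and is preserved by
    serialization, so the stoichiometric matrix is reproducible.
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    biomass_reaction_id: str = ""
    medium: dict[str, float] = field(default_factory=dict)
    id: str = "model"

    def __post_init__(self):
        self._reindex()

    def _reindex(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- access ------------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reaction(self.biomass_reaction_id)

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            genes=set(self.genes),
            biomass_reaction_id=self.biomass_reaction_id,
            medium=dict(self.medium),
            id=self.id,
        )

    def replace_reaction(self, rxn: Reaction) -> None:
        self.reactions[self._rxn_index[rxn.id]] = rxn

    def remove_reactions(self, rxn_ids: Iterable[str]) -> None:
        drop = set(rxn_ids)
        self.reactions = [r for r in self.reactions if r.id not in drop]
        self._reindex()

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelValidationError([f"duplicate metabolite id {met.id!r}"])
        self.metabolites.append(met)
        self._met_index[met.id] = len(self.metabolites) - 1

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelValidationError([f"duplicate reaction id {rxn.id!r}"])
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = len(self.reactions) - 1

    # -- matrix ------------------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S matrix (metabolites x reactions), floats, insertion order."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[self._met_index[met_id], j] = float(coeff)
        return S

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise one aggregated error."""
        errors: list[str] = []
        seen_m: set[str] = set()
        for m in self.metabolites:
            if not m.id:
                errors.append("metabolite with empty id")
            if m.id in seen_m:
                errors.append(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                errors.append(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            if r.lower_bound > r.upper_bound:
                errors.append(
                    f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
            if not r.reversible and r.lower_bound < 0:
                errors.append(
                    f"reaction {r.id!r}: irreversible but lower_bound < 0"
                )
            if not r.stoichiometry and not r.is_exchange:
                errors.append(f"reaction {r.id!r}: empty stoichiometry")
            if r.is_exchange and len(r.stoichiometry) != 1:
                errors.append(
                    f"exchange reaction {r.id!r} must touch exactly one metabolite"
                )
            for met_id in r.stoichiometry:
                if met_id not in seen_m:
                    errors.append(
                        f"reaction {r.id!r} references undeclared metabolite {met_id!r}"
                    )
            for g in sorted(r.gpr.genes() - self.genes):
                errors.append(
                    f"reaction {r.id!r} GPR references unknown gene {g!r}"
                )
        if not self.biomass_reaction_id:
            errors.append("missing biomass_reaction_id")
        elif self.biomass_reaction_id not in seen_r:
            errors.append(
                f"biomass_reaction_id {self.biomass_reaction_id!r} "
                "does not name a reaction"
            )
        for ex_id in self.medium:
            if ex_id not in seen_r:
                errors.append(f"medium references unknown reaction {ex_id!r}")
        if errors:
            raise ModelValidationError(errors)


def reactions_disabled_by(
    model: MetabolicModel, deleted: Iterable[str]
) -> frozenset[str]:
    """Reaction ids whose GPR evaluates false when *deleted* genes are off.

    This is the N(g) set of the gene-essentiality algorithm: the reactions
    that can no longer be catalysed once the deleted genes' products are
    absent. Reactions with no gene association are never disabled.
    """
    deleted = frozenset(deleted)
    unknown = deleted - model.genes
    if unknown:
        raise ModelValidationError(
            [f"deleted gene {g!r} is not in the model" for g in sorted(unknown)]
        )
    return frozenset(
        r.id for r in model.reactions if not r.gpr.evaluate(deleted)
    )


# ---------------------------------------------------------------------------
# JSON serialization (documented dialect; see schema/model.schema.json)
# ---------------------------------------------------------------------------


def _coeff_to_json(c: Fraction):
    if c.denominator == 1:
        return int(c)
    return f"{c.numerator}/{c.denominator}"


def _coeff_from_json(v) -> Fraction:
    if isinstance(v, bool):
        raise ModelValidationError([f"invalid stoichiometric coefficient {v!r}"])
    if isinstance(v, int):
        return Fraction(v)
    if isinstance(v, float):
        # decimal-exact: 0.01 -> 1/100, not the binary float expansion
        return Fraction(repr(v))
    if isinstance(v, str):
        return Fraction(v)
    raise ModelValidationError([f"invalid stoichiometric coefficient {v!r}"])


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {
                    m: _coeff_to_json(c) for m, c in r.stoichiometry.items()
                },
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "reversible": r.reversible,
                "gpr": r.gpr.to_string(),
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
        "biomass_reaction_id": model.biomass_reaction_id,
        "medium": {k: model.medium[k] for k in sorted(model.medium)},
    }


def model_from_dict(data: dict) -> MetabolicModel:
    errors: list[str] = []
    for key in ("metabolites", "reactions", "genes", "biomass_reaction_id"):
        if key not in data:
            errors.append(f"missing top-level key {key!r}")
    if errors:
        raise ModelValidationError(errors)
    genes = set(data["genes"])
    metabolites = [
        Metabolite(
            id=m["id"], name=m.get("name", ""), compartment=m.get("compartment", "c")
        )
        for m in data["metabolites"]
    ]
    reactions = []
    for rd in data["reactions"]:
        try:
            gpr = parse_gpr(rd.get("gpr", ""))
        except GPRParseError as exc:
            errors.append(f"reaction {rd.get('id')!r}: bad GPR: {exc}")
            continue
        try:
            stoich = {
                m: _coeff_from_json(c) for m, c in rd.get("stoichiometry", {}).items()
            }
        except (ModelValidationError, ValueError) as exc:
            errors.append(f"reaction {rd.get('id')!r}: bad stoichiometry: {exc}")
            continue
        reactions.append(
            Reaction(
                id=rd["id"],
                name=rd.get("name", ""),
                stoichiometry=stoich,
                lower_bound=float(rd.get("lower_bound", 0.0)),
                upper_bound=float(rd.get("upper_bound", 1000.0)),
                reversible=bool(rd.get("reversible", False)),
                gpr=gpr,
                is_exchange=bool(rd.get("is_exchange", False)),
            )
        )
    if errors:
        raise ModelValidationError(errors)
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_reaction_id=data["biomass_reaction_id"],
        medium={k: float(v) for k, v in data.get("medium", {}).items()},
        id=data.get("id", "model"),
    )
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=1, sort_keys=False) + "\n"
    )


def read_model(path: str | Path) -> MetabolicModel:
    data = json.loads(Path(path).read_text())
    return model_from_dict(data)
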