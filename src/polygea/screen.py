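"""Gene essentiality analysis: single/double deletion screens.

For a gene g, the screen disables the reaction set N(g) whose GPR rules
evaluate false without g, re-maximizes biomass, and calls g essential when
the optimum falls strictly below a lethality threshold (default 1e-4 gDW/h
— the minimum biomass production compatible with proliferation). Synthetic
lethal pairs are pairs of individually non-essential genes whose joint
deletion is lethal.

LP solves are memoized by the *disabled-reaction set*, not by the gene
combination: distinct gene pairs that collapse onto the same reaction
knockout are solved once, and the results are identical by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .fba import DEFAULT_CONFIG, SolverConfig, maximize_biomass
from .model import MetabolicModel, ModelValidationError, reactions_disabled_by

__all__ = [
    "DEFAULT_THRESHOLD",
    "ScreenError",
    "ScreenResult",
    "DifferentialReport",
    "single_deletion_screen",
    "double_deletion_screen",
    "differential_essentials",
    "threshold_sweep",
]

#: Lethality threshold on biomass flux, gDW/h.
DEFAULT_THRESHOLD = 1e-4


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of a deletion screen.

    ``single_growth`` maps each screened gene to the optimal biomass flux
    after its deletion; ``pair_growth`` maps canonically sorted gene pairs
    to the joint-deletion optimum. Essential genes grow strictly below the
    threshold; synthetic-lethal pairs are pairs of non-essential genes
    whose joint growth is below it.
    """

    threshold: float
    growth_wildtype: float
    single_growth: dict[str, float]
    essential_genes: frozenset[str]
    pair_growth: dict[tuple[str, str], float] = field(default_factory=dict)
    synthetic_lethal_pairs: frozenset[tuple[str, str]] = frozenset()

    def genes(self) -> frozenset[str]:
        return frozenset(self.single_growth)


class _GrowthCache:
    """Memoizes optimal biomass by disabled-reaction set."""

    def __init__(self, model: MetabolicModel, config: SolverConfig):
        self.model = model
        self.config = config
        self._cache: dict[frozenset[str], float] = {}
        self.lp_solves = 0

    def growth(self, disabled: frozenset[str]) -> float:
        if disabled not in self._cache:
            sol = maximize_biomass(self.model, disabled, self.config)
            self.lp_solves += 1
            # an infeasible knockout model cannot grow at all
            self._cache[disabled] = sol.objective if sol.optimal else 0.0
        return self._cache[disabled]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def single_deletion_screen(
    model: MetabolicModel,
    threshold: float = DEFAULT_THRESHOLD,
    config: SolverConfig = DEFAULT_CONFIG,
    _cache: _GrowthCache | None = None,
) -> ScreenResult:
    """Delete every gene in turn and classify it as essential or not.

    Genes that appear in no GPR rule can never disable a reaction; they are
    recorded with wild-type growth (trivially non-essential) without an LP
    solve.
    """
    if threshold <= 0:
        raise ScreenError("threshold must be positive")
    cache = _cache or _GrowthCache(model, config)
    wt = cache.growth(frozenset())
    if wt < threshold:
        raise ScreenError(
            f"wild-type growth {wt:.6g} is below the threshold {threshold:.6g}: "
            "the model cannot grow, so an essentiality screen is meaningless"
        )
    single_growth: dict[str, float] = {}
    for gene in sorted(model.genes):
        disabled = reactions_disabled_by(model, {gene})
        single_growth[gene] = wt if not disabled else cache.growth(disabled)
    essential = frozenset(g for g, v in single_growth.items() if v < threshold)
    return ScreenResult(
        threshold=threshold,
        growth_wildtype=wt,
        single_growth=single_growth,
        essential_genes=essential,
    )


def double_deletion_screen(
    model: MetabolicModel,
    threshold: float = DEFAULT_THRESHOLD,
    config: SolverConfig = DEFAULT_CONFIG,
    candidates: Iterable[str] | None = None,
    single: ScreenResult | None = None,
) -> ScreenResult:
    """Screen all unordered pairs of non-essential genes for synthetic lethality.

    Candidate genes default to every non-essential gene appearing in at
    least one GPR rule; an explicit *candidates* set restricts the screen
    (essential candidates are excluded automatically). Pairs whose disabled
    reaction set was already solved — e.g. it coincides with one partner's
    own N(g) — reuse the memoized optimum.
    """
    cache = _GrowthCache(model, config)
    if single is None or single.threshold != threshold:
        single = single_deletion_screen(model, threshold, config, _cache=cache)
    else:
        cache._cache[frozenset()] = single.growth_wildtype
        for g in single.single_growth:
            cache._cache.setdefault(
                reactions_disabled_by(model, {g}), single.single_growth[g]
            )

    gpr_genes: set[str] = set()
    for r in model.reactions:
        gpr_genes |= r.gpr.genes()

    if candidates is None:
        pool = sorted(gpr_genes - single.essential_genes)
    else:
        pool = sorted(set(candidates))
        unknown = [g for g in pool if g not in model.genes]
        if unknown:
            raise ModelValidationError(
                [f"candidate gene {g!r} is not in the model" for g in unknown]
            )
        pool = [g for g in pool if g not in single.essential_genes]

    pair_growth: dict[tuple[str, str], float] = {}
    lethal: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(pool, 2):
        disabled = reactions_disabled_by(model, {a, b})
        growth = (
            single.growth_wildtype if not disabled else cache.growth(disabled)
        )
        key = _pair_key(a, b)
        pair_growth[key] = growth
        if growth < threshold:
            lethal.add(key)
    return ScreenResult(
        threshold=threshold,
        growth_wildtype=single.growth_wildtype,
        single_growth=dict(single.single_growth),
        essential_genes=single.essential_genes,
        pair_growth=pair_growth,
        synthetic_lethal_pairs=frozenset(lethal),
    )


@dataclass(frozen=True)
class DifferentialReport:
    """Essentiality gained by a biomass variant: augmented minus base."""

    gained_essential: frozenset[str]
    gained_synthetic_lethal: frozenset[tuple[str, str]]

    def empty(self) -> bool:
        return not self.gained_essential and not self.gained_synthetic_lethal


def differential_essentials(
    base: ScreenResult, augmented: ScreenResult
) -> DifferentialReport:
    """Hits specific to the augmented biomass: set differences of the screens.

    Both screens must cover the same gene universe at the same threshold,
    otherwise the comparison is meaningless and an error is raised.
    """
    if base.threshold != augmented.threshold:
        raise ScreenError(
            f"threshold mismatch: base {base.threshold} vs augmented {augmented.threshold}"
        )
    if base.genes() != augmented.genes():
        raise ScreenError("screens cover different gene universes")
    return DifferentialReport(
        gained_essential=augmented.essential_genes - base.essential_genes,
        gained_synthetic_lethal=(
            augmented.synthetic_lethal_pairs - base.synthetic_lethal_pairs
        ),
    )


def threshold_sweep(
    model: MetabolicModel,
    thresholds: Sequence[float],
    config: SolverConfig = DEFAULT_CONFIG,
    single: ScreenResult | None = None,
) -> dict[float, frozenset[str]]:
    """Essential-gene sets at several thresholds, from one pass of LPs.

    The single-deletion growth values are computed once (one LP per gene)
    and reclassified at each threshold, so the sweep costs no extra solves.
    The returned sets grow monotonically with the threshold.
    """
    if single is None:
        base_t = min(min(thresholds), DEFAULT_THRESHOLD)
        single = single_deletion_screen(model, base_t, config)
    for t in thresholds:
        if t <= 0:
            raise ScreenError(f"threshold {t} must be positive")
        if t > single.growth_wildtype:
            raise ScreenError(
                f"threshold {t:.6g} exceeds wild-type growth "
                f"{single.growth_wildtype:.6g}"
            )
    return {
        t: frozenset(g for g, v in single.single_growth.items() if v < t)
        for t in thresholds
    }


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_gene_report(result: ScreenResult, path) -> None:
    lines = ["gene\tgrowth\tessential"]
    for g in sorted(result.single_growth):
        v = result.single_growth[g]
        lines.append(f"{g}\t{v:.12g}\t{str(g in result.essential_genes).lower()}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pair_report(result: ScreenResult, path) -> None:
    lines = ["gene_a\tgene_b\tgrowth\tsynthetic_lethal"]
    for a, b in sorted(result.pair_growth):
        v = result.pair_growth[(a, b)]
        sl = (a, b) in result.synthetic_lethal_pairs
        lines.append(f"{a}\t{b}\t{v:.12g}\t{str(sl).lower()}")
    Path(path).write_text("\n".join(lines) + "\n")


def screen_summary(result: ScreenResult) -> dict:
    """JSON-ready summary with pinned ordering and 12-significant-digit floats."""

    def f(x: float) -> float:
        return float(f"{x:.12g}")

    return {
        "threshold": f(result.threshold),
        "growth_wildtype": f(result.growth_wildtype),
        "single_growth": {g: f(v) for g, v in sorted(result.single_growth.items())},
        "essential_genes": sorted(result.essential_genes),
        "pair_growth": {
            f"{a}&{b}": f(v) for (a, b), v in sorted(result.pair_growth.items())
        },
        "synthetic_lethal_pairs": [
            [a, b] for a, b in sorted(result.synthetic_lethal_pairs)
        ],
    }
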