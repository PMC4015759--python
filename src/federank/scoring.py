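"""Partial-score normalization and weighted global scoring.

Each ranked service contributes one *partial score* per record, obtained by
normalizing the raw value of its ranked attribute (a BLAST expectation
value, an expression p-value, ...) into [0, 1] with 1 best.  A joined tuple's
*global score* is the weighted sum of its partial scores; the per-service
weight is the product of a service-specific component (realized here as the
pluggable normalization strategy) and a user-settable relative weight, with
relative weights constrained to sum to one so the global score stays in
[0, 1].

Three normalization strategies are provided:

``complement``
    ``s = 1 - clamp(v, 0, 1)`` for ascending-better attributes.  The default
    for [0, 1]-valued ranked attributes such as e-values and p-values, which
    are dimensionless values on the same scale.  E-values above 1 clamp to 0.
``neglog``
    ``s = min(1, -log10(max(v, eps)) / C)``; spreads tiny probabilities
    (an e-value range covering 180 orders of magnitude) over the unit
    interval.  ``C`` caps the magnitude (default 100), ``eps`` floors the
    input (default 1e-300).
``rank_based``
    position-only: ``s_i = 1 - (r_i - 1) / (n - 1)`` with midranks ``r_i``
    over the visible cohort, so tied raw values get tied scores.

Unranked services carry no partial score; their relative weight mass is
redistributed proportionally among the ranked services present.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from scipy.stats import rankdata

from .errors import ScoringError
from .service_model import Direction

__all__ = [
    "NormalizationStrategy",
    "COMPLEMENT",
    "NEGLOG",
    "RANK_BASED",
    "PartialScore",
    "WeightConfig",
    "normalize",
    "rank_normalize",
    "global_score",
    "reweight",
    "ranking_sort_key",
    "sort_ranked",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class NormalizationStrategy:
    """Service-specific mapping of raw ranked values into [0, 1]."""

    kind: str  # complement | neglog | rank_based
    cap: float = 100.0
    floor: float = 1e-300

    def __post_init__(self):
        if self.kind not in ("complement", "neglog", "rank_based"):
            raise ScoringError(f"unknown normalization strategy {self.kind!r}")
        if self.kind == "neglog" and (self.cap <= 0 or self.floor <= 0):
            raise ScoringError("neglog requires cap > 0 and floor > 0")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "cap": self.cap, "floor": self.floor}

    @classmethod
    def from_dict(cls, d: Union[Mapping, str, "NormalizationStrategy"]) -> "NormalizationStrategy":
        if isinstance(d, NormalizationStrategy):
            return d
        if isinstance(d, str):
            return cls(d)
        return cls(d["kind"], d.get("cap", 100.0), d.get("floor", 1e-300))


COMPLEMENT = NormalizationStrategy("complement")
NEGLOG = NormalizationStrategy("neglog")
RANK_BASED = NormalizationStrategy("rank_based")


@dataclass(frozen=True)
class PartialScore:
    """One service's contribution to a joined tuple, raw and normalized."""

    interface: str
    raw_value: float
    normalized: float

    def __post_init__(self):
        if not (0.0 <= self.normalized <= 1.0):
            raise ScoringError(
                f"partial score for {self.interface!r} outside [0,1]: {self.normalized}"
            )


def _clamp01(v: float) -> float:
    return 0.0 if v < 0.0 else 1.0 if v > 1.0 else v


def normalize(
    raw_value: float,
    direction: Union[Direction, str] = Direction.ASCENDING_BETTER,
    strategy: NormalizationStrategy = COMPLEMENT,
) -> float:
    """Normalize one raw ranked value into [0, 1], monotone per direction."""
    v = float(raw_value)
    if math.isnan(v):
        raise ScoringError("cannot normalize NaN")
    direction = Direction(direction)
    if strategy.kind == "rank_based":
        raise ScoringError("rank_based normalization needs a cohort; use rank_normalize")
    if strategy.kind == "complement":
        s = 1.0 - _clamp01(v)
    else:  # neglog
        s = min(1.0, max(0.0, -math.log10(max(v, strategy.floor)) / strategy.cap))
    if direction is Direction.DESCENDING_BETTER:
        s = 1.0 - s
    return s


def rank_normalize(
    values: Sequence[float], direction: Union[Direction, str] = Direction.ASCENDING_BETTER
) -> list[float]:
    """Position-only normalization of a cohort of raw ranked values.

    ``s_i = 1 - (r_i - 1)/(n - 1)`` with ``r_i`` the midrank under the
    direction's ordering.  Degenerate cohorts (a single value, or all values
    tied) carry no ranking information and score 1.0 throughout.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ScoringError("rank_normalize: empty cohort")
    if any(math.isnan(v) for v in vals):
        raise ScoringError("rank_normalize: NaN in cohort")
    n = len(vals)
    if n == 1 or all(v == vals[0] for v in vals):
        return [1.0] * n
    if Direction(direction) is Direction.DESCENDING_BETTER:
        ranks = rankdata([-v for v in vals], method="average")
    else:
        ranks = rankdata(vals, method="average")
    return [1.0 - (float(r) - 1.0) / (n - 1) for r in ranks]


@dataclass(frozen=True)
class WeightConfig:
    """Per-interface normalization strategy and relative mixing weight.

    Relative weights are non-negative and sum to one (tolerance 1e-9); a
    config whose weights merely sum to something positive can be repaired
    with :meth:`normalized`, which warns and rescales.
    """

    strategies: Mapping[str, NormalizationStrategy]
    weights: Mapping[str, float]

    def __post_init__(self):
        if set(self.strategies) != set(self.weights):
            raise ScoringError("weight config: strategies and weights cover different interfaces")

    @classmethod
    def equal(
        cls,
        interfaces: Iterable[str],
        strategy: NormalizationStrategy = COMPLEMENT,
        strategies: Optional[Mapping[str, NormalizationStrategy]] = None,
    ) -> "WeightConfig":
        names = list(interfaces)
        w = 1.0 / len(names) if names else 0.0
        return cls(
            {n: (strategies or {}).get(n, strategy) for n in names},
            {n: w for n in names},
        )

    def validate(self) -> None:
        for name, w in self.weights.items():
            if not math.isfinite(w) or w < 0:
                raise ScoringError(f"weight for {name!r} must be finite and >= 0, got {w}")
        if self.weights and abs(sum(self.weights.values()) - 1.0) > _WEIGHT_TOL:
            raise ScoringError(
                f"relative weights must sum to 1 (got {sum(self.weights.values())!r})"
            )

    def normalized(self) -> "WeightConfig":
        """Rescale weights to sum to one (warns if rescaling was needed)."""
        total = sum(self.weights.values())
        if not self.weights:
            return self
        if total <= 0:
            raise ScoringError("relative weights must have positive mass")
        if abs(total - 1.0) <= _WEIGHT_TOL:
            return self
        warnings.warn(f"relative weights sum to {total}; auto-normalizing", stacklevel=2)
        return WeightConfig(dict(self.strategies), {n: w / total for n, w in self.weights.items()})

    def interfaces(self) -> list[str]:
        return sorted(self.weights)

    def strategy(self, interface: str) -> NormalizationStrategy:
        try:
            return self.strategies[interface]
        except KeyError:
            raise ScoringError(f"no strategy configured for interface {interface!r}") from None

    def effective_weights(self, present: Iterable[str]) -> dict[str, float]:
        """Weights over the ranked interfaces actually present in a result.

        The weight mass of configured-but-absent (or unranked) interfaces is
        redistributed proportionally among those present; if the present
        interfaces carry zero configured mass they share it equally.
        """
        names = [n for n in present]
        for n in names:
            if n not in self.weights:
                raise ScoringError(f"interface {n!r} has no configured weight")
        if not names:
            return {}
        total = sum(self.weights[n] for n in names)
        if total <= 0:
            return {n: 1.0 / len(names) for n in names}
        return {n: self.weights[n] / total for n in names}

    def to_dict(self) -> dict:
        return {
            n: {"strategy": self.strategies[n].to_dict(), "relative_weight": self.weights[n]}
            for n in sorted(self.weights)
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WeightConfig":
        strategies = {}
        weights = {}
        for name, entry in d.items():
            strategies[name] = NormalizationStrategy.from_dict(entry.get("strategy", "complement"))
            weights[name] = float(entry.get("relative_weight", 0.0))
        return cls(strategies, weights)


def _norm_of(p) -> float:
    return p.normalized if isinstance(p, PartialScore) else float(p)


def global_score(partials: Mapping[str, Union[PartialScore, float]], weights: WeightConfig) -> float:
    """Weighted sum of partial scores; in [0, 1], 1 iff every partial is 1.

    Every interface configured in ``weights`` must have a partial; partials
    of interfaces without a configured weight contribute nothing.
    """
    weights.validate()
    missing = [n for n in weights.weights if n not in partials]
    if missing:
        raise ScoringError(f"missing partial score for weighted interface(s) {missing}")
    g = sum(w * _norm_of(partials[n]) for n, w in weights.weights.items())
    return _clamp01(g)


def ranking_sort_key(t):
    """Total, deterministic ordering key for combined tuples.

    Nonincreasing global score, ties broken by (1) higher partial score of
    the earlier interface in plan order, (2) lexicographic join key,
    (3) provenance record indices.
    """
    order = [i for i, _ in t.provenance if i in t.partials]
    return (
        -t.global_score,
        tuple(-t.partials[i].normalized for i in order),
        tuple(t.key),
        tuple(idx for _, idx in t.provenance),
    )


def sort_ranked(tuples):
    return sorted(tuples, key=ranking_sort_key)


def reweight(results, weights: WeightConfig):
    """Re-rank already-joined tuples under new relative weights.

    The tuple set is unchanged and no service is re-invoked: global scores
    are recomputed from the stored partial scores (absent interfaces'
    weight mass is redistributed) and the list re-sorted with the standard
    tie-break.
    """
    weights.validate()
    results = list(results)
    if results:
        known = set().union(*(set(t.partials) for t in results))
        unknown = [n for n in weights.weights if n not in known]
        if unknown:
            raise ScoringError(f"weights reference unknown interface(s) {unknown}")
    out = []
    for t in results:
        eff = weights.effective_weights([n for n in t.partials if n in weights.weights])
        g = _clamp01(sum(eff[n] * t.partials[n].normalized for n in eff))
        out.append(t.with_global_score(g))
    return sort_ranked(out)
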