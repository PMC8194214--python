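"""Deterministic evaluation of the decision model.

Expected-value rollback over the tree with discounting of both costs and
QALYs, followed by incremental analysis: strategies sorted by cost,
absolutely and extendedly dominated strategies removed from the efficiency
frontier, ICERs between adjacent frontier members, and net monetary benefit
at a willingness-to-pay threshold lambda.

QALY accrual convention
-----------------------
A utility stream held over ``[start, start + duration)`` is split into
calendar-year slices; the slice covering year ``k`` (the interval
``[k, k+1)``) contributes ``utility x fraction / (1 + r)^t`` with ``t`` equal
to ``k + 1`` (end-of-year annuity, the default), ``k + 0.5`` (mid-year), or
``k`` (start-of-year).  With rate 0 the stream is exactly
``utility x duration``.  Costs are discounted at the year the event occurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .parameters import ParameterSet
from .tree import DecisionTree, Path, iter_paths, validate_tree

__all__ = [
    "EngineError",
    "discount",
    "qaly_stream",
    "qaly_to_days",
    "icer",
    "nmb",
    "StrategyOutcome",
    "EvaluationResult",
    "rollback",
    "IncrementalRow",
    "IncrementalAnalysis",
    "incremental_analysis",
    "CompiledStrategy",
    "compile_tree",
]


class EngineError(ValueError):
    """Evaluation refused (invalid tree or arguments); carries the report."""


def discount(amount: float, rate: float, year: float) -> float:
    """Present value of ``amount`` occurring at ``year``: amount / (1+rate)^year."""
    if year < 0:
        raise EngineError(f"year must be >= 0, got {year}")
    if rate < 0:
        raise EngineError(f"rate must be >= 0, got {rate}")
    return amount / (1.0 + rate) ** year


def _year_offset(convention: str) -> float:
    try:
        return {"end": 1.0, "mid": 0.5, "start": 0.0}[convention]
    except KeyError:
        raise EngineError(f"unknown qaly convention {convention!r}") from None


def qaly_stream(
    utility: float,
    start_year: float,
    duration_years: float,
    rate: float,
    convention: str = "end",
) -> float:
    """Discounted QALYs from holding ``utility`` over ``[start, start+duration)``."""
    if duration_years < 0:
        raise EngineError(f"duration must be >= 0, got {duration_years}")
    if start_year < 0:
        raise EngineError(f"start year must be >= 0, got {start_year}")
    offset = _year_offset(convention)
    if rate == 0:
        return utility * duration_years
    end = start_year + duration_years
    total = 0.0
    k = math.floor(start_year)
    while k < end:
        overlap = min(end, k + 1.0) - max(start_year, float(k))
        if overlap > 0:
            total += utility * overlap / (1.0 + rate) ** (k + offset)
        k += 1
    return total


def qaly_to_days(delta_qalys: float) -> float:
    """A QALY difference expressed as days of perfect health (x 365)."""
    return delta_qalys * 365.0


def icer(delta_cost: float, delta_qalys: float) -> float:
    """Incremental cost-effectiveness ratio; undefined (raises) at zero ΔE."""
    if delta_qalys == 0:
        raise EngineError("ICER undefined: incremental QALYs are zero")
    return delta_cost / delta_qalys


def nmb(delta_e: float, delta_c: float, wtp: float) -> float:
    """Incremental net monetary benefit ΔE·λ − ΔC."""
    if wtp < 0:
        raise EngineError(f"wtp must be >= 0, got {wtp}")
    return delta_e * wtp - delta_c


# --------------------------------------------------------------------------
# rollback
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyOutcome:
    strategy: str
    cost: float                # discounted USD
    qalys: float               # discounted
    cost_undiscounted: float
    qalys_undiscounted: float


class EvaluationResult(Mapping[str, StrategyOutcome]):
    """Per-strategy expected cost (USD) and QALYs, discounted and undiscounted."""

    def __init__(self, outcomes: Sequence[StrategyOutcome]):
        self._outcomes = {o.strategy: o for o in outcomes}

    def __getitem__(self, key: str) -> StrategyOutcome:
        return self._outcomes[key]

    def __iter__(self):
        return iter(self._outcomes)

    def __len__(self) -> int:
        return len(self._outcomes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": o.strategy,
                    "cost": o.cost,
                    "qalys": o.qalys,
                    "cost_undiscounted": o.cost_undiscounted,
                    "qalys_undiscounted": o.qalys_undiscounted,
                }
                for o in self._outcomes.values()
            ]
        ).set_index("strategy")


class CompiledStrategy:
    """Pre-enumerated paths of one strategy, for repeated re-evaluation.

    The path list is fixed (the tree is symbolic); only probabilities, event
    costs and utility values change across parameter draws.  Per-path utility
    exposure is reduced to discounted year-weights per state, so a path's
    QALYs are a dot product with the utility vector.
    """

    def __init__(self, strategy: str, paths: Sequence[Path], params: ParameterSet):
        self.strategy = strategy
        self.paths = list(paths)
        rate = params.discount_rate
        conv = params.qaly_convention
        # per-path: {state: discounted exposure}, {state: raw exposure}
        self.state_weights: list[dict[str, float]] = []
        self.state_weights_undiscounted: list[dict[str, float]] = []
        for path in self.paths:
            w: dict[str, float] = {}
            wu: dict[str, float] = {}
            for entry in path.utility_entries:
                w[entry.state] = w.get(entry.state, 0.0) + qaly_stream(
                    1.0, entry.start, entry.duration, rate, conv
                )
                wu[entry.state] = wu.get(entry.state, 0.0) + entry.duration
            self.state_weights.append(w)
            self.state_weights_undiscounted.append(wu)

    def probabilities(self, params: ParameterSet) -> list[float]:
        return [p.probability(params) for p in self.paths]

    def path_costs(self, params: ParameterSet, discounted: bool = True) -> list[float]:
        rate = params.discount_rate if discounted else 0.0
        cache: dict[str, float] = {}
        out = []
        for path in self.paths:
            total = 0.0
            for entry in path.cost_entries:
                if entry.event not in cache:
                    cache[entry.event] = params.event_cost_usd(entry.event)
                total += discount(cache[entry.event], rate, entry.year)
            out.append(total)
        return out

    def path_qalys(
        self,
        params: ParameterSet,
        discounted: bool = True,
        utilities: Mapping[str, float] | None = None,
    ) -> list[float]:
        weights = self.state_weights if discounted else self.state_weights_undiscounted
        u = {k: v.utility for k, v in params.utilities.items()}
        if utilities:
            u.update(utilities)
        return [sum(u[state] * wt for state, wt in w.items()) for w in weights]


def compile_tree(tree: DecisionTree, params: ParameterSet) -> dict[str, CompiledStrategy]:
    """Group the tree's paths by strategy and pre-compute utility exposures."""
    by_strategy: dict[str, list[Path]] = {s: [] for s in tree.strategies}
    for path in iter_paths(tree):
        by_strategy[path.strategy].append(path)
    return {s: CompiledStrategy(s, paths, params) for s, paths in by_strategy.items()}


def rollback(
    tree: DecisionTree,
    params: ParameterSet,
    compiled: Mapping[str, CompiledStrategy] | None = None,
    validate: bool = True,
) -> EvaluationResult:
    """Expected cost and QALYs per strategy by expectation over terminal paths.

    Refuses an invalid tree, surfacing the full validation report.  Passing a
    pre-compiled path table (from :func:`compile_tree`) skips re-enumeration;
    note the compiled discounted utility weights are anchored to the
    ``discount_rate``/``qaly_convention`` of the compiling parameter set.
    """
    if validate:
        report = validate_tree(tree, params)
        if report:
            raise EngineError("invalid tree: " + "; ".join(report))
    compiled = compiled or compile_tree(tree, params)
    outcomes = []
    for strategy, cs in compiled.items():
        probs = cs.probabilities(params)
        cost_d = cs.path_costs(params, discounted=True)
        cost_u = cs.path_costs(params, discounted=False)
        q_d = cs.path_qalys(params, discounted=True)
        q_u = cs.path_qalys(params, discounted=False)
        outcomes.append(
            StrategyOutcome(
                strategy,
                cost=sum(p * c for p, c in zip(probs, cost_d)),
                qalys=sum(p * q for p, q in zip(probs, q_d)),
                cost_undiscounted=sum(p * c for p, c in zip(probs, cost_u)),
                qalys_undiscounted=sum(p * q for p, q in zip(probs, q_u)),
            )
        )
    return EvaluationResult(outcomes)


# --------------------------------------------------------------------------
# incremental analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IncrementalRow:
    strategy: str
    comparator: str | None       # previous frontier member, or the dominator
    cost: float
    qalys: float
    delta_cost: float | None
    delta_qalys: float | None
    verdict: str                 # reference | icer | absolutely_dominated |
    #                              extendedly_dominated | undefined_zero_delta_e
    icer: float | None
    nmb: float | None            # ΔE·λ − ΔC against the comparator


@dataclass
class IncrementalAnalysis:
    rows: list[IncrementalRow]
    frontier: list[str]
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": r.strategy,
                    "comparator": r.comparator,
                    "cost": r.cost,
                    "qalys": r.qalys,
                    "delta_cost": r.delta_cost,
                    "delta_qalys": r.delta_qalys,
                    "verdict": r.verdict,
                    "icer": r.icer,
                    "nmb": r.nmb,
                }
                for r in self.rows
            ]
        ).set_index("strategy")


def _as_points(results) -> list[tuple[str, float, float]]:
    if isinstance(results, EvaluationResult):
        return [(o.strategy, o.cost, o.qalys) for o in results.values()]
    out = []
    for item in results:
        name, cost, qalys = item
        out.append((str(name), float(cost), float(qalys)))
    return out


def incremental_analysis(results, wtp: float = 6667.0, undiscounted: bool = False) -> IncrementalAnalysis:
    """Cost-ordered incremental analysis with dominance pruning and NMB.

    ``results`` is an :class:`EvaluationResult` or an iterable of
    ``(name, cost, qalys)`` triples.  Strategies are sorted by ascending cost
    (ties broken by descending QALYs, then input order).  A strategy is
    *absolutely dominated* if some other strategy is no more costly and no
    less effective (strictly better on one axis); remaining strategies are
    pruned by *extended dominance* (an ICER exceeding that of the next, more
    effective frontier step).  ICERs chain adjacent frontier members only;
    dominated rows are reported against their lowest-cost dominator.
    """
    if isinstance(results, EvaluationResult) and undiscounted:
        points = [(o.strategy, o.cost_undiscounted, o.qalys_undiscounted) for o in results.values()]
    else:
        points = _as_points(results)
    if len(points) < 2:
        raise EngineError("incremental analysis requires at least two strategies")

    order = sorted(range(len(points)), key=lambda i: (points[i][1], -points[i][2], i))
    ordered = [points[i] for i in order]

    def dominated_by(i: int) -> str | None:
        name_i, c_i, e_i = ordered[i]
        best = None
        for j, (name_j, c_j, e_j) in enumerate(ordered):
            if j == i:
                continue
            if c_j <= c_i and e_j >= e_i and (c_j < c_i or e_j > e_i):
                if best is None or c_j < ordered[best][1]:
                    best = j
        return None if best is None else ordered[best][0]

    dominators = {ordered[i][0]: dominated_by(i) for i in range(len(ordered))}
    frontier = [name for name, *_ in ordered if dominators[name] is None]
    lookup = {name: (c, e) for name, c, e in ordered}

    # extended dominance: successive ICERs along the frontier must increase
    extended: set[str] = set()
    changed = True
    while changed:
        changed = False
        live = [s for s in frontier if s not in extended]
        for k in range(1, len(live) - 1):
            lo, mid, hi = live[k - 1], live[k], live[k + 1]
            de1 = lookup[mid][1] - lookup[lo][1]
            de2 = lookup[hi][1] - lookup[mid][1]
            if de1 <= 0 or de2 <= 0:
                continue
            icer1 = (lookup[mid][0] - lookup[lo][0]) / de1
            icer2 = (lookup[hi][0] - lookup[mid][0]) / de2
            if icer1 > icer2:
                extended.add(mid)
                changed = True
                break
    frontier = [s for s in frontier if s not in extended]

    rows: list[IncrementalRow] = []
    prev_frontier: str | None = None
    for name, cost, qalys in ordered:
        if dominators[name] is not None:
            comp = dominators[name]
            dc, de = cost - lookup[comp][0], qalys - lookup[comp][1]
            rows.append(IncrementalRow(
                name, comp, cost, qalys, dc, de, "absolutely_dominated", None, nmb(de, dc, wtp)
            ))
            continue
        if name in extended:
            comp = prev_frontier
            dc = None if comp is None else cost - lookup[comp][0]
            de = None if comp is None else qalys - lookup[comp][1]
            row_nmb = None if comp is None else nmb(de, dc, wtp)
            rows.append(IncrementalRow(
                name, comp, cost, qalys, dc, de, "extendedly_dominated", None, row_nmb
            ))
            continue
        if prev_frontier is None:
            rows.append(IncrementalRow(name, None, cost, qalys, None, None, "reference", None, None))
        else:
            dc = cost - lookup[prev_frontier][0]
            de = qalys - lookup[prev_frontier][1]
            if de == 0:
                rows.append(IncrementalRow(
                    name, prev_frontier, cost, qalys, dc, de,
                    "undefined_zero_delta_e", None, nmb(de, dc, wtp),
                ))
            else:
                rows.append(IncrementalRow(
                    name, prev_frontier, cost, qalys, dc, de, "icer", dc / de, nmb(de, dc, wtp)
                ))
        prev_frontier = name
    return IncrementalAnalysis(rows, frontier, wtp)


def incremental_table(result: EvaluationResult, wtp: float = 6667.0) -> pd.DataFrame:
    """Discounted + undiscounted incremental blocks as one tidy table (CSV-ready)."""
    blocks = []
    for undiscounted, label in ((True, "undiscounted"), (False, "discounted")):
        frame = incremental_analysis(result, wtp=wtp, undiscounted=undiscounted).to_frame()
        frame.insert(0, "block", label)
        blocks.append(frame.reset_index())
    return pd.concat(blocks, ignore_index=True)
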