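"""Deterministic and probabilistic sensitivity analysis.

Deterministic: one-way sweeps over a single input (tornado summaries) and
threshold analysis solving for the input value at which two strategies reach
net-monetary-benefit parity.

Probabilistic: first-order Monte Carlo microsimulation (patient-level
variability at fixed parameters, with per-trial utility draws), second-order
Monte Carlo over the parameter distributions (beta for probabilities and
utilities, Dirichlet for the polytomous complication split, Poisson for
resource quantities, uniform for unit tariffs and relative risks), the
cost-effectiveness acceptability curve, the incremental-NMB distribution,
and a population-scale budget simulation.

All randomness flows through ``numpy.random.Generator`` instances derived
from a single integer seed via named, non-overlapping streams
(:func:`named_rng`), so identical seeds give bitwise-identical samples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .engine import (
    CompiledStrategy,
    EngineError,
    compile_tree,
    rollback,
)
from .parameters import (
    DistributionSpec,
    ParameterError,
    ParameterSet,
    rescale_recurrence_schedule,
)
from .tree import DecisionTree

__all__ = [
    "named_rng",
    "set_parameter",
    "get_parameter",
    "draw_parameters",
    "TornadoEntry",
    "one_way",
    "tornado",
    "ThresholdResult",
    "threshold_analysis",
    "microsimulate",
    "PSASamples",
    "psa_run",
    "CEACPoint",
    "ceac",
    "incremental_nmb_distribution",
    "PopulationResult",
    "population_simulation",
]

#: fixed stream identifiers keeping first-order, second-order and population
#: simulations on distinct, reproducible substreams of one seed
STREAM_IDS = {"psa": 101, "microsim": 211, "population": 307, "synthetic": 401, "generic": 503}


def named_rng(seed: int, name: str = "generic") -> np.random.Generator:
    """A Generator on the named substream of ``seed``."""
    if name not in STREAM_IDS:
        raise EngineError(f"unknown stream name {name!r}; use one of {sorted(STREAM_IDS)}")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), STREAM_IDS[name]]))


# --------------------------------------------------------------------------
# dotted-path access into a ParameterSet
# --------------------------------------------------------------------------

def _split(target: str) -> list[str]:
    return str(target).split(".")


def get_parameter(params: ParameterSet, target: str) -> float:
    parts = _split(target)
    if parts[0] == "scale":
        # virtual multiplier targets (baseline value 1); see set_parameter
        _resolve_scale(params, parts)
        return 1.0
    if len(parts) == 1:
        if not hasattr(params, parts[0]):
            raise ParameterError([f"unknown parameter {target!r}"])
        return float(getattr(params, parts[0]))
    if parts[0] == "utilities" and len(parts) in (2, 3):
        name = parts[1]
        if name not in params.utilities:
            raise ParameterError([f"unknown utility state {name!r}"])
        field = parts[2] if len(parts) == 3 else "utility"
        return float(getattr(params.utilities[name], field))
    if parts[0] == "cost_items" and len(parts) == 4:
        event, resource, field = parts[1:]
        if event not in params.cost_items:
            raise ParameterError([f"unknown cost event {event!r}"])
        for item in params.cost_items[event]:
            if item.resource == resource:
                if field not in ("quantity", "unit_cost_cop"):
                    raise ParameterError([f"unknown cost-item field {field!r}"])
                return float(getattr(item, field))
        raise ParameterError([f"unknown resource {resource!r} in event {event!r}"])
    raise ParameterError([f"cannot resolve parameter path {target!r}"])


def _resolve_scale(params: ParameterSet, parts: list[str]) -> list[str]:
    """Events addressed by a ``scale.cost_items.<event>`` virtual target."""
    if len(parts) != 3 or parts[1] != "cost_items":
        raise ParameterError([f"cannot resolve parameter path {'.'.join(parts)!r}"])
    event = parts[2]
    if event not in params.cost_items:
        raise ParameterError([f"unknown cost event {event!r}"])
    return [event]


def set_parameter(params: ParameterSet, target: str, value: float) -> None:
    """Set a dotted-path parameter in place.

    Setting ``p_nom_success`` rescales the recurrence schedule so the
    schedule-implied success tracks the new value (the curve keeps its shape).
    The virtual target ``scale.cost_items.<event>`` multiplies every unit
    tariff of that event by ``value`` (relative to the current tariffs; its
    baseline reading via :func:`get_parameter` is 1), which supports
    deterministic sweeps and threshold analyses of a whole costed event.
    """
    parts = _split(target)
    if parts[0] == "scale":
        for event in _resolve_scale(params, parts):
            params.cost_items[event] = [
                replace(item, unit_cost_cop=item.unit_cost_cop * float(value))
                for item in params.cost_items[event]
            ]
        return
    if len(parts) == 1:
        name = parts[0]
        if not hasattr(params, name):
            raise ParameterError([f"unknown parameter {target!r}"])
        if name == "p_nom_success" and float(value) != params.p_nom_success:
            params.recurrence_schedule = rescale_recurrence_schedule(
                params.recurrence_schedule, float(value), params.p_nom_initial_failure
            )
        setattr(params, name, float(value))
        return
    if parts[0] == "utilities" and len(parts) in (2, 3):
        name = parts[1]
        if name not in params.utilities:
            raise ParameterError([f"unknown utility state {name!r}"])
        field = parts[2] if len(parts) == 3 else "utility"
        params.utilities[name] = replace(params.utilities[name], **{field: float(value)})
        return
    if parts[0] == "cost_items" and len(parts) == 4:
        event, resource, field = parts[1:]
        if event not in params.cost_items:
            raise ParameterError([f"unknown cost event {event!r}"])
        for i, item in enumerate(params.cost_items[event]):
            if item.resource == resource:
                if field not in ("quantity", "unit_cost_cop"):
                    raise ParameterError([f"unknown cost-item field {field!r}"])
                params.cost_items[event][i] = replace(item, **{field: float(value)})
                return
        raise ParameterError([f"unknown resource {resource!r} in event {event!r}"])
    raise ParameterError([f"cannot resolve parameter path {target!r}"])


# --------------------------------------------------------------------------
# second-order draws
# --------------------------------------------------------------------------

def _sample(spec: DistributionSpec, rng: np.random.Generator):
    p = spec.parameters
    if spec.kind == "beta":
        return float(rng.beta(p["alpha"], p["beta"]))
    if spec.kind == "dirichlet":
        return rng.dirichlet(np.asarray(p["concentration"], dtype=float))
    if spec.kind == "poisson":
        return float(rng.poisson(p["mean"]))
    if spec.kind == "uniform":
        return float(rng.uniform(p["lower"], p["upper"]))
    if spec.kind == "point":
        return float(p["value"])
    raise ParameterError([f"unknown distribution kind {spec.kind!r}"])


def draw_parameters(
    specs: Sequence[DistributionSpec],
    base: ParameterSet,
    rng: np.random.Generator,
) -> ParameterSet:
    """One second-order draw: targeted fields replaced, everything else kept.

    A Dirichlet spec replaces a whole polytomous simplex jointly; a ``None``
    slot in its target list marks the residual branch whose probability is
    implied.  The returned set is *not* validated; callers that need validity
    (``psa_run``, ``population_simulation``) redraw on violation.
    """
    out = base.copy()
    for spec in specs:
        bad = spec.validate()
        if bad:
            raise ParameterError(bad)
        value = _sample(spec, rng)
        if spec.kind == "dirichlet":
            for slot, v in zip(spec.target, value):
                if slot is not None:
                    set_parameter(out, slot, float(v))
        else:
            set_parameter(out, spec.target, value)
    return out


def _draw_valid(
    specs: Sequence[DistributionSpec],
    base: ParameterSet,
    rng: np.random.Generator,
    max_redraws: int = 1000,
) -> tuple[ParameterSet, int]:
    redraws = 0
    while True:
        candidate = draw_parameters(specs, base, rng)
        if not candidate.validate():
            return candidate, redraws
        redraws += 1
        if redraws > max_redraws:
            raise ParameterError(
                [f"exceeded {max_redraws} redraws without a valid parameter draw"]
            )


def _digest(params: ParameterSet) -> str:
    payload = json.dumps(params.to_dict(), sort_keys=True, default=float)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# deterministic sensitivity analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    outcome_low: float    # outcome at the low parameter value
    outcome_high: float   # outcome at the high parameter value
    span: float           # max - min of the outcome over the grid
    grid: tuple[float, ...]
    outcomes: tuple[float, ...]


def _outcome(
    tree: DecisionTree,
    params: ParameterSet,
    compiled: Mapping[str, CompiledStrategy],
    wtp: float,
    strategy: str | None,
    pair: tuple[str, str] | None,
) -> float:
    result = rollback(tree, params, compiled=compiled, validate=False)
    if pair is not None:
        a, b = pair
        dc = result[a].cost - result[b].cost
        de = result[a].qalys - result[b].qalys
        if de == 0:
            raise EngineError(f"ICER undefined between {a} and {b}: zero incremental QALYs")
        return dc / de
    o = result[strategy]
    return wtp * o.qalys - o.cost  # absolute NMB


def one_way(
    parameter: str,
    low: float,
    high: float,
    tree: DecisionTree,
    base: ParameterSet,
    wtp: float | None = None,
    n_points: int = 11,
    strategy: str | None = None,
    icer_pair: tuple[str, str] | None = None,
) -> TornadoEntry:
    """Sweep one input over an even grid; outcome is a strategy's absolute NMB
    (``wtp * QALYs - cost``, default strategy = first tree strategy) or, with
    ``icer_pair``, the pairwise ICER."""
    if low > high:
        raise EngineError(f"low must be <= high, got ({low}, {high})")
    if n_points < 2:
        raise EngineError(f"n_points must be >= 2, got {n_points}")
    get_parameter(base, parameter)  # raises on unknown targets
    wtp = base.wtp if wtp is None else wtp
    if strategy is None and icer_pair is None:
        strategy = tree.strategies[0]
    compiled = compile_tree(tree, base)
    grid = np.linspace(low, high, n_points)
    outcomes = []
    for x in grid:
        trial = base.copy()
        set_parameter(trial, parameter, float(x))
        outcomes.append(_outcome(tree, trial, compiled, wtp, strategy, icer_pair))
    outcomes_arr = np.asarray(outcomes)
    return TornadoEntry(
        parameter=parameter,
        low=float(low),
        high=float(high),
        outcome_low=float(outcomes_arr[0]),
        outcome_high=float(outcomes_arr[-1]),
        span=float(outcomes_arr.max() - outcomes_arr.min()),
        grid=tuple(float(x) for x in grid),
        outcomes=tuple(float(v) for v in outcomes_arr),
    )


def tornado(
    ranges: Mapping[str, tuple[float, float]],
    tree: DecisionTree,
    base: ParameterSet,
    wtp: float | None = None,
    n_points: int = 5,
    strategy: str | None = None,
) -> list[TornadoEntry]:
    """One-way entries for every input in ``ranges``, sorted by descending span."""
    entries = [
        one_way(name, lo, hi, tree, base, wtp=wtp, n_points=n_points, strategy=strategy)
        for name, (lo, hi) in ranges.items()
    ]
    return sorted(entries, key=lambda e: -e.span)


def tornado_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high,
                "span": e.span,
            }
            for e in entries
        ]
    )


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    crossed: bool
    value: float | None            # parameter value at NMB parity
    percent_change: float | None   # vs the baseline parameter value
    baseline: float
    diff_low: float                # NMB(a) - NMB(b) at the interval ends
    diff_high: float


def threshold_analysis(
    parameter: str,
    tree: DecisionTree,
    base: ParameterSet,
    strategy_a: str,
    strategy_b: str,
    low: float,
    high: float,
    wtp: float | None = None,
    n_grid: int = 21,
    rtol: float = 1e-6,
) -> ThresholdResult:
    """Solve for the input value at which two strategies reach NMB parity.

    The NMB difference is first evaluated on an even grid to check empirical
    monotonicity; with a sign change, the crossing is bisected (Brent) to
    relative tolerance ``rtol``.  No sign change is a declared
    *no-threshold-in-range* result, not an exception.
    """
    wtp = base.wtp if wtp is None else wtp
    baseline_value = get_parameter(base, parameter)
    compiled = compile_tree(tree, base)

    def diff(x: float) -> float:
        trial = base.copy()
        set_parameter(trial, parameter, float(x))
        result = rollback(tree, trial, compiled=compiled, validate=False)
        a, b = result[strategy_a], result[strategy_b]
        return (wtp * a.qalys - a.cost) - (wtp * b.qalys - b.cost)

    grid = np.linspace(low, high, n_grid)
    values = np.array([diff(x) for x in grid])
    steps = np.diff(values)
    if steps.size and not (np.all(steps >= -1e-9) or np.all(steps <= 1e-9)):
        raise EngineError(
            f"NMB difference is not monotone in {parameter!r} on [{low}, {high}]"
        )
    if values[0] == 0.0:
        return ThresholdResult(parameter, True, float(grid[0]), _pct(grid[0], baseline_value),
                               baseline_value, float(values[0]), float(values[-1]))
    sign_change = np.nonzero(np.sign(values[:-1]) * np.sign(values[1:]) <= 0)[0]
    if sign_change.size == 0:
        return ThresholdResult(parameter, False, None, None,
                               baseline_value, float(values[0]), float(values[-1]))
    i = int(sign_change[0])
    if values[i + 1] == 0.0 and values[i] != 0.0 and i + 1 == len(values) - 1:
        root = float(grid[i + 1])
    else:
        root = float(brentq(diff, grid[i], grid[i + 1], rtol=max(rtol, 1e-12)))
    return ThresholdResult(parameter, True, root, _pct(root, baseline_value),
                           baseline_value, float(values[0]), float(values[-1]))


def _pct(value: float, baseline: float) -> float | None:
    if baseline == 0:
        return None
    return 100.0 * (value - baseline) / baseline


# --------------------------------------------------------------------------
# first-order microsimulation
# --------------------------------------------------------------------------

def _utility_specs(specs: Sequence[DistributionSpec] | None) -> dict[str, DistributionSpec]:
    out: dict[str, DistributionSpec] = {}
    for spec in specs or ():
        if isinstance(spec.target, str):
            parts = _split(spec.target)
            if parts[0] == "utilities" and (len(parts) == 2 or parts[2] == "utility"):
                out[parts[1]] = spec
    return out


def microsimulate(
    tree: DecisionTree,
    params: ParameterSet,
    n_trials: int,
    rng: np.random.Generator,
    specs: Sequence[DistributionSpec] | None = None,
    utilities_only: bool = False,
) -> pd.DataFrame:
    """First-order Monte Carlo: per-trial (cost, QALY) samples per strategy.

    Each trial samples its terminal path from the compiled path distribution
    (equivalent to walking the tree branch by branch) and receives utility
    values drawn from the beta specs targeting ``utilities.*`` (fixed at the
    point values when no specs are given).  With ``utilities_only=True``
    branch outcomes are expectation-weighted instead of sampled, so only the
    utility draws vary between trials.  Discounted outcomes.
    """
    if n_trials < 1:
        raise EngineError(f"n_trials must be >= 1, got {n_trials}")
    params.ensure_valid()
    compiled = compile_tree(tree, params)
    u_specs = _utility_specs(specs)
    states = sorted({s for cs in compiled.values() for w in cs.state_weights for s in w})
    # per-trial utility matrix (n_trials x n_states)
    u_base = np.array([params.utilities[s].utility for s in states])
    U = np.tile(u_base, (n_trials, 1))
    for j, s in enumerate(states):
        if s in u_specs:
            spec = u_specs[s]
            U[:, j] = rng.beta(spec.parameters["alpha"], spec.parameters["beta"], size=n_trials)
    records = []
    for strategy, cs in compiled.items():
        probs = np.asarray(cs.probabilities(params))
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        costs = np.asarray(cs.path_costs(params, discounted=True))
        W = np.zeros((len(cs.paths), len(states)))
        for i, w in enumerate(cs.state_weights):
            for s, wt in w.items():
                W[i, states.index(s)] = wt
        qaly_by_path = U @ W.T  # n_trials x n_paths
        if utilities_only:
            trial_cost = np.full(n_trials, float(probs @ costs))
            trial_qaly = qaly_by_path @ probs
        else:
            idx = rng.choice(len(probs), size=n_trials, p=probs)
            trial_cost = costs[idx]
            trial_qaly = qaly_by_path[np.arange(n_trials), idx]
        records.append(pd.DataFrame({
            "trial": np.arange(n_trials),
            "strategy": strategy,
            "cost": trial_cost,
            "qalys": trial_qaly,
        }))
    return pd.concat(records, ignore_index=True)


# --------------------------------------------------------------------------
# second-order PSA
# --------------------------------------------------------------------------

@dataclass
class PSASamples:
    """Iteration x strategy samples of (cost, QALYs) under parameter uncertainty."""

    data: pd.DataFrame            # columns: iteration, strategy, cost, qalys, digest
    redraws: int                  # invalid draws rejected and redrawn
    seed_digest: str | None = None

    @property
    def strategies(self) -> list[str]:
        return list(dict.fromkeys(self.data["strategy"]))

    def matrix(self, column: str) -> pd.DataFrame:
        """Iterations x strategies pivot of ``cost`` or ``qalys``."""
        return self.data.pivot(index="iteration", columns="strategy", values=column)[self.strategies]

    def summary(self) -> pd.DataFrame:
        """Mean/SD/min/median/max of cost and QALYs per strategy."""
        rows = []
        for column in ("cost", "qalys"):
            m = self.matrix(column)
            for strategy in self.strategies:
                s = m[strategy]
                rows.append({
                    "outcome": column,
                    "strategy": strategy,
                    "mean": s.mean(),
                    "sd": s.std(ddof=1) if len(s) > 1 else 0.0,
                    "min": s.min(),
                    "median": s.median(),
                    "max": s.max(),
                })
        return pd.DataFrame(rows)


def psa_run(
    tree: DecisionTree,
    base: ParameterSet,
    specs: Sequence[DistributionSpec],
    n_iterations: int,
    rng: np.random.Generator | int,
) -> PSASamples:
    """Second-order Monte Carlo: per iteration one joint parameter draw, then
    expected-value rollback of every strategy under that draw.

    Draws violating ParameterSet invariants are redrawn (count reported),
    never clamped.
    """
    if n_iterations < 1:
        raise EngineError(f"n_iterations must be >= 1, got {n_iterations}")
    if isinstance(rng, (int, np.integer)):
        rng = named_rng(int(rng), "psa")
    base.ensure_valid()
    compiled = compile_tree(tree, base)
    records: list[dict[str, Any]] = []
    total_redraws = 0
    for it in range(n_iterations):
        drawn, redraws = _draw_valid(specs, base, rng)
        total_redraws += redraws
        digest = _digest(drawn)
        result = rollback(tree, drawn, compiled=compiled, validate=False)
        for strategy, outcome in result.items():
            records.append({
                "iteration": it,
                "strategy": strategy,
                "cost": outcome.cost,
                "qalys": outcome.qalys,
                "digest": digest,
            })
    return PSASamples(pd.DataFrame(records), total_redraws)


# --------------------------------------------------------------------------
# CEAC and incremental NMB
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probabilities: dict[str, float]  # per-strategy P(maximal NMB); sums to 1


def ceac(samples: PSASamples, wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """Probability each strategy attains the maximal absolute NMB per lambda.

    Ties (measure-zero under continuous draws) go to the lowest-cost tying
    strategy, keeping the curve deterministic.
    """
    wtp_grid = list(wtp_grid)
    if not wtp_grid:
        raise EngineError("wtp grid must be non-empty")
    costs = samples.matrix("cost").to_numpy()
    qalys = samples.matrix("qalys").to_numpy()
    if costs.size == 0:
        raise EngineError("samples are empty")
    strategies = samples.strategies
    points = []
    for lam in wtp_grid:
        nmb = lam * qalys - costs
        rowmax = nmb.max(axis=1, keepdims=True)
        tie = nmb >= rowmax - 1e-12
        masked_cost = np.where(tie, costs, np.inf)
        winner = masked_cost.argmin(axis=1)
        counts = np.bincount(winner, minlength=len(strategies)).astype(float)
        probs = counts / counts.sum()
        points.append(CEACPoint(float(lam), dict(zip(strategies, probs))))
    return points


def ceac_table(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"wtp": p.wtp, **p.probabilities} for p in points]
    ).set_index("wtp")


def incremental_nmb_distribution(
    samples: PSASamples,
    strategy_a: str,
    strategy_b: str,
    wtp: float,
    quantiles: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> dict[str, float]:
    """Per-iteration NMB(a) - NMB(b): mean, SD, quantiles and P(> 0)."""
    for s in (strategy_a, strategy_b):
        if s not in samples.strategies:
            raise EngineError(f"strategy {s!r} not present in samples")
    costs = samples.matrix("cost")
    qalys = samples.matrix("qalys")
    delta = (wtp * qalys[strategy_a] - costs[strategy_a]) - (
        wtp * qalys[strategy_b] - costs[strategy_b]
    )
    out = {
        "mean": float(delta.mean()),
        "sd": float(delta.std(ddof=1)) if len(delta) > 1 else 0.0,
        "p_positive": float((delta > 0).mean()),
    }
    for q in quantiles:
        out[f"q{q:g}"] = float(delta.quantile(q))
    return out


# --------------------------------------------------------------------------
# population budget simulation
# --------------------------------------------------------------------------

@dataclass
class PopulationResult:
    """Total-cost distribution per strategy for a patient population.

    ``totals``: iterations x strategies (USD).  Each iteration is one
    second-order parameter draw under which ``n_patients`` patients are
    simulated first-order (a multinomial over the terminal paths), so the
    spread reflects both parameter and sampling uncertainty.
    """

    totals: pd.DataFrame
    n_patients: int
    redraws: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.totals.mean(),
            "sd": self.totals.std(ddof=1) if len(self.totals) > 1 else 0.0,
        })

    def over_expenditure(self, strategy_a: str, strategy_b: str) -> float:
        """Mean extra spend of running the population on ``a`` instead of ``b``."""
        return float(self.totals[strategy_a].mean() - self.totals[strategy_b].mean())


def population_simulation(
    tree: DecisionTree,
    base: ParameterSet,
    specs: Sequence[DistributionSpec],
    n_patients: int,
    rng: np.random.Generator | int,
    n_iterations: int = 1000,
) -> PopulationResult:
    """Aggregate per-patient sampled costs into population totals per strategy."""
    if n_patients < 1:
        raise EngineError(f"n_patients must be >= 1, got {n_patients}")
    if n_iterations < 1:
        raise EngineError(f"n_iterations must be >= 1, got {n_iterations}")
    if isinstance(rng, (int, np.integer)):
        rng = named_rng(int(rng), "population")
    base.ensure_valid()
    compiled = compile_tree(tree, base)
    strategies = list(compiled)
    totals = np.zeros((n_iterations, len(strategies)))
    total_redraws = 0
    for it in range(n_iterations):
        drawn, redraws = _draw_valid(specs, base, rng)
        total_redraws += redraws
        for j, strategy in enumerate(strategies):
            cs = compiled[strategy]
            probs = np.clip(np.asarray(cs.probabilities(drawn)), 0.0, None)
            probs = probs / probs.sum()
            costs = np.asarray(cs.path_costs(drawn, discounted=True))
            counts = rng.multinomial(n_patients, probs)
            totals[it, j] = float(counts @ costs)
    return PopulationResult(
        pd.DataFrame(totals, columns=strategies), n_patients, total_redraws
    )
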