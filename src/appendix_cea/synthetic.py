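"""Synthetic parameter sets and toy trees with known closed-form answers.

The generator emulates the *structure* of the model's input tables —
probabilities in (0, 1), utilities in a plausible band, positive tariff-scale
costs, relative risks in (0.2, 2), and the matching second-order distribution
families (beta / Dirichlet / Poisson / uniform) — without claiming any
particular published point value beyond the anchors the baseline already
documents (five-year NOM success of 72.7%, currency constants).

Scenario levels are mapped through *shared uniforms*: the same seed produces
the same underlying uniform draws whatever the scenario scales are, so
raising e.g. the complication-probability scale can only raise every
generated complication probability (monotone coupling), which makes
scenario-comparison property tests exact rather than statistical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .parameters import (
    CostItem,
    DistributionSpec,
    HealthState,
    ParameterSet,
    baseline_distributions,
)
from .sensitivity import named_rng
from .tree import DecisionTree, TreeNode, CostEntry, UtilityEntry, pconst

__all__ = ["ScenarioSpec", "generate_parameter_set", "ToyModel", "generate_toy_tree"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Knobs of the synthetic-data generator.

    ``complication_scale`` and ``cost_scale`` multiply the baseline
    complication probabilities and tariffs; ``nom_success`` fixes the
    five-year NOM success probability; ``utility_band`` bounds the episodic
    (non-healthy) utilities; ``ess`` is the effective sample size behind the
    generated beta/Dirichlet concentrations.
    """

    seed: int = 0
    complication_scale: float = 1.0
    nom_success: float = 0.727
    cost_scale: float = 1.0
    utility_band: tuple[float, float] = (0.70, 0.95)
    ess: float = 100.0


def _uniforms(seed: int, n: int) -> np.ndarray:
    """Scenario-independent uniforms: the shared coupling across scenarios."""
    return named_rng(seed, "synthetic").uniform(size=n)


def generate_parameter_set(
    scenario: ScenarioSpec = ScenarioSpec(),
) -> tuple[ParameterSet, list[DistributionSpec]]:
    """A validated ParameterSet plus its matching distribution specs.

    Same seed, same scenario -> identical output.  Raising
    ``complication_scale`` never decreases any generated complication
    probability; raising ``cost_scale`` never decreases any generated tariff.
    """
    base = ParameterSet()  # structural template: resource lists, durations
    u = iter(_uniforms(scenario.seed, 64))

    def jitter(value: float, lo: float = 0.8, hi: float = 1.2) -> float:
        return value * (lo + (hi - lo) * next(u))

    comp_cap = 0.45  # keeps the polytomous complication split on the simplex
    params = base.copy()
    params.p_oa_ssi = min(jitter(base.p_oa_ssi) * scenario.complication_scale, comp_cap)
    params.p_oa_abscess = min(jitter(base.p_oa_abscess) * scenario.complication_scale, comp_cap)
    params.p_oa_ileus = min(jitter(base.p_oa_ileus) * scenario.complication_scale, comp_cap)
    # relative risks constrained to (0.2, 2)
    params.rr_la_ssi = 0.25 + (0.49 - 0.25) * next(u)
    params.rr_la_abscess = 1.05 + (1.95 - 1.05) * next(u)
    params.rr_la_ileus = 0.25 + (0.64 - 0.25) * next(u)
    params.p_nom_success = scenario.nom_success
    params.p_nom_initial_failure = 0.0
    params.recurrence_schedule = None  # re-derived for the new success level
    params.p_recur_complicated = 0.08 + 0.06 * next(u)
    params.p_choose_oa = 0.85 + 0.10 * next(u)
    params.p_complicated_medical = 0.50 + 0.20 * next(u)

    lo, hi = scenario.utility_band
    new_utilities: dict[str, HealthState] = {}
    for name, state in base.utilities.items():
        if name == "healthy":
            value = 0.99 + 0.01 * next(u)
        else:
            value = lo + (hi - lo) * next(u)
        new_utilities[name] = HealthState(value, state.duration_years)
    # convalescence after laparoscopy is never worse than after open surgery
    if new_utilities["post_surgery_la"].utility < new_utilities["post_surgery_oa"].utility:
        la, oa = new_utilities["post_surgery_la"], new_utilities["post_surgery_oa"]
        new_utilities["post_surgery_la"] = HealthState(oa.utility, la.duration_years)
        new_utilities["post_surgery_oa"] = HealthState(la.utility, oa.duration_years)
    params.utilities = new_utilities

    params.package_cost_oa = jitter(base.package_cost_oa) * scenario.cost_scale
    params.package_cost_la = params.package_cost_oa + jitter(15_000.0) * scenario.cost_scale
    new_items: dict[str, list[CostItem]] = {}
    for event, items in base.cost_items.items():
        new_items[event] = [
            CostItem(i.resource, i.quantity, jitter(i.unit_cost_cop) * scenario.cost_scale)
            for i in items
        ]
    params.cost_items = new_items
    params.__post_init__()  # derive the recurrence schedule
    params.ensure_valid()
    return params, baseline_distributions(params, ess=scenario.ess)


# --------------------------------------------------------------------------
# toy trees with analytic expectations
# --------------------------------------------------------------------------

@dataclass
class ToyModel:
    tree: DecisionTree
    params: ParameterSet
    #: strategy -> (expected discounted cost USD, expected discounted QALYs)
    expected: dict[str, tuple[float, float]]


def generate_toy_tree(
    n_leaves: int,
    seed: int = 0,
    n_strategies: int = 2,
    discount_rate: float = 0.05,
) -> ToyModel:
    """A random chance tree per strategy plus its analytic expectations.

    Leaf payoffs use unit currency conversion (fx = 1, inflation = 1), integer
    event years and integer utility durations, so the expected discounted cost
    and QALYs have clean closed forms (geometric annuity sums) computed here
    independently of the rollback engine.
    """
    if n_leaves < 1:
        raise ValueError(f"n_leaves must be >= 1, got {n_leaves}")
    rng = named_rng(seed, "synthetic")
    params = ParameterSet(
        discount_rate=discount_rate,
        exchange_rate=1.0,
        inflation_factor=1.0,
    )
    horizon = params.horizon_years
    root = TreeNode("root", "decision")
    expected: dict[str, tuple[float, float]] = {}

    def annuity(u: float, years: int) -> float:
        # end-of-year discounted stream of `u` over `years` whole years
        if discount_rate == 0:
            return u * years
        return u * (1 - (1 + discount_rate) ** -years) / discount_rate

    for s in range(n_strategies):
        name = f"S{s + 1}"
        leaf_cost_usd = rng.uniform(50, 500, size=n_leaves)
        leaf_cost_year = rng.integers(0, min(3, horizon) + 1, size=n_leaves)
        leaf_utility = rng.uniform(0.5, 1.0, size=n_leaves)
        leaf_years = rng.integers(1, horizon + 1, size=n_leaves)

        leaves = []
        for i in range(n_leaves):
            event = f"toy_{name}_{i}"
            state = f"toy_{name}_{i}"
            params.cost_items[event] = [CostItem("lump_sum", 1.0, float(leaf_cost_usd[i]))]
            params.utilities[state] = HealthState(float(leaf_utility[i]), float(leaf_years[i]))
            node = TreeNode(
                f"{name}/leaf{i}",
                "terminal",
                cost_entries=[CostEntry(event, float(leaf_cost_year[i]))],
                utility_entries=[UtilityEntry(state, 0.0, float(leaf_years[i]))],
            )
            pv_cost = float(leaf_cost_usd[i]) / (1 + discount_rate) ** float(leaf_cost_year[i])
            pv_qaly = annuity(float(leaf_utility[i]), int(leaf_years[i]))
            leaves.append((node, pv_cost, pv_qaly))

        def build(group: list, prefix: str):
            """Random binary chance tree over `group`; returns (node, E[cost], E[qaly])."""
            if len(group) == 1:
                return group[0]
            k = int(rng.integers(1, len(group)))
            q = float(rng.uniform(0.2, 0.8))
            left, lc, lq = build(group[:k], prefix + "0")
            right, rc, rq = build(group[k:], prefix + "1")
            node = TreeNode(f"{prefix}", "chance")
            node.add(left, pconst(q))
            node.add(right, pconst(1.0 - q))
            return node, q * lc + (1 - q) * rc, q * lq + (1 - q) * rq

        strategy_node, e_cost, e_qaly = build(leaves, name)
        strategy_node.id = name
        root.add(strategy_node)
        expected[name] = (e_cost, e_qaly)

    params.ensure_valid()
    return ToyModel(DecisionTree(root, horizon), params, expected)
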