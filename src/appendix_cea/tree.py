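"""Decision-tree representation and the appendicitis model structure.

Nodes come in three kinds: a single decision root (the three management
strategies), chance nodes whose child probabilities are *symbolic*
expressions over a :class:`~appendix_cea.parameters.ParameterSet` (so
deterministic and probabilistic sensitivity analyses re-evaluate the same
tree without rebuilding it), and terminal nodes carrying timed cost events
and utility streams.

The clinical structure built by :func:`build_appendicitis_tree`:

* **OA / LA** — index appendectomy followed by a mutually exclusive
  polytomous short-term outcome: no complication, surgical-site infection,
  intra-abdominal abscess, or ileus (ileus is cost-only; it resolves within
  the same admission without a quality-of-life decrement).
* **NOM** — antibiotics and in-hospital observation; then either durable
  success, failure within the initial admission (immediate appendectomy), or
  a recurrence in one of the horizon years.  An uncomplicated recurrence goes
  to appendectomy (open with probability ``p_choose_oa``, otherwise
  laparoscopic, inheriting that operation's complication branches); a
  complicated recurrence is managed either medically (antibiotics plus
  percutaneous drainage, then interval appendectomy) or by immediate surgery.

Death, incisional hernia, enteric fistula and abdominal sepsis are excluded
by design: their incidence in uncomplicated appendicitis is negligible, and
the structural validator asserts no node references them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

from .parameters import PROB_TOL, ParameterSet, la_probability

__all__ = [
    "Expr",
    "pref",
    "pconst",
    "pcomp",
    "pla",
    "precur",
    "CostEntry",
    "UtilityEntry",
    "TreeNode",
    "DecisionTree",
    "TreeError",
    "build_appendicitis_tree",
    "validate_tree",
    "iter_paths",
    "to_outline",
    "to_dot",
    "FORBIDDEN_STATES",
]

#: health states the model must never reference (structural exclusions)
FORBIDDEN_STATES = ("death", "hernia", "fistula", "sepsis")


class TreeError(ValueError):
    """Structural violation in a decision tree; message names the node."""


class Expr:
    """A probability expression: a ParameterSet -> float callable with a label."""

    __slots__ = ("fn", "label")

    def __init__(self, fn: Callable[[ParameterSet], float], label: str):
        self.fn = fn
        self.label = label

    def __call__(self, params: ParameterSet) -> float:
        return self.fn(params)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Expr({self.label})"


def pref(name: str) -> Expr:
    """Reference a scalar ParameterSet field."""
    return Expr(lambda p: getattr(p, name), name)


def pconst(value: float) -> Expr:
    return Expr(lambda p, v=value: v, f"{value:g}")


def pcomp(*exprs: Expr) -> Expr:
    """1 minus the sum of ``exprs`` (the residual branch of a chance node)."""
    label = "1 - (" + " + ".join(e.label for e in exprs) + ")"
    return Expr(lambda p: 1.0 - sum(e(p) for e in exprs), label)


def pla(which: str) -> Expr:
    """Clamped laparoscopic complication probability min(p_oa * rr, 1)."""
    return Expr(
        lambda p: la_probability(getattr(p, f"p_oa_{which}"), getattr(p, f"rr_la_{which}")),
        f"min(p_oa_{which} * rr_la_{which}, 1)",
    )


def precur(year: int) -> Expr:
    """Unconditional probability of a NOM recurrence in ``year``."""
    return Expr(lambda p: p.recurrence_probability(year), f"recurrence[{year}]")


@dataclass(frozen=True)
class CostEntry:
    """A costed event occurring at ``year`` (0 = model entry)."""

    event: str
    year: float


@dataclass(frozen=True)
class UtilityEntry:
    """A utility stream: ``state`` held from ``start`` for ``duration`` years."""

    state: str
    start: float
    duration: float


@dataclass
class TreeNode:
    id: str
    kind: str  # decision | chance | terminal
    children: list[tuple["TreeNode", Expr | None]] = field(default_factory=list)
    cost_entries: list[CostEntry] = field(default_factory=list)
    utility_entries: list[UtilityEntry] = field(default_factory=list)

    def add(self, child: "TreeNode", prob: Expr | None = None) -> "TreeNode":
        self.children.append((child, prob))
        return child


@dataclass
class DecisionTree:
    root: TreeNode
    horizon_years: int

    @property
    def strategies(self) -> list[str]:
        return [child.id for child, _ in self.root.children]


# --------------------------------------------------------------------------
# builder
# --------------------------------------------------------------------------

def _episodes_to_entries(
    params: ParameterSet, episodes: Sequence[tuple[str, float]], horizon: float
) -> list[UtilityEntry]:
    """Chain episodes chronologically and fill the gaps with the healthy state.

    Episodes that would overlap are pushed back-to-back (a convalescence
    starting at an event year begins after any episode still running); all
    windows are clipped at the horizon.
    """
    entries: list[UtilityEntry] = []
    cursor = 0.0
    intervals: list[tuple[str, float, float]] = []
    for state, event_year in sorted(episodes, key=lambda e: e[1]):
        duration = params.utilities[state].duration_years
        start = max(event_year, cursor)
        end = min(start + duration, horizon)
        if end > start:
            intervals.append((state, start, end - start))
            cursor = end
    t = 0.0
    for state, start, duration in intervals:
        if start > t:
            entries.append(UtilityEntry("healthy", t, start - t))
        entries.append(UtilityEntry(state, start, duration))
        t = start + duration
    if t < horizon:
        entries.append(UtilityEntry("healthy", t, horizon - t))
    return entries


def build_appendicitis_tree(params: ParameterSet) -> DecisionTree:
    """Construct the three-strategy appendicitis model from a validated ParameterSet."""
    params.ensure_valid()
    horizon = float(params.horizon_years)

    def terminal(
        node_id: str,
        cost_events: Sequence[tuple[str, float]],
        episodes: Sequence[tuple[str, float]],
    ) -> TreeNode:
        return TreeNode(
            node_id,
            "terminal",
            cost_entries=[CostEntry(e, y) for e, y in cost_events],
            utility_entries=_episodes_to_entries(params, episodes, horizon),
        )

    def surgery_subtree(
        node_id: str,
        approach: str,  # "oa" | "la"
        year: float,
        base_costs: Sequence[tuple[str, float]],
        base_episodes: Sequence[tuple[str, float]],
    ) -> TreeNode:
        """Appendectomy with its polytomous short-term complication outcome."""
        if approach == "oa":
            probs = {w: pref(f"p_oa_{w}") for w in ("ssi", "abscess", "ileus")}
            package, post = "package_oa", "post_surgery_oa"
        else:
            probs = {w: pla(w) for w in ("ssi", "abscess", "ileus")}
            package, post = "package_la", "post_surgery_la"
        costs = [*base_costs, (package, year)]
        episodes = [*base_episodes, (post, year)]
        node = TreeNode(node_id, "chance")
        node.add(
            terminal(f"{node_id}/no_complication", costs, episodes),
            pcomp(probs["ssi"], probs["abscess"], probs["ileus"]),
        )
        node.add(
            terminal(f"{node_id}/ssi", [*costs, ("ssi", year)], [*episodes, ("ssi", year)]),
            probs["ssi"],
        )
        node.add(
            terminal(f"{node_id}/abscess", [*costs, ("abscess", year)], [*episodes, ("abscess", year)]),
            probs["abscess"],
        )
        # cost-only branch: ileus resolves within the index admission
        node.add(
            terminal(f"{node_id}/ileus", [*costs, ("ileus", year)], episodes),
            probs["ileus"],
        )
        return node

    def appendectomy_choice(
        node_id: str,
        year: float,
        base_costs: Sequence[tuple[str, float]],
        base_episodes: Sequence[tuple[str, float]],
    ) -> TreeNode:
        """Open vs laparoscopic operation, each with its complication branches."""
        node = TreeNode(node_id, "chance")
        node.add(surgery_subtree(f"{node_id}/oa", "oa", year, base_costs, base_episodes), pref("p_choose_oa"))
        node.add(
            surgery_subtree(f"{node_id}/la", "la", year, base_costs, base_episodes),
            pcomp(pref("p_choose_oa")),
        )
        return node

    root = TreeNode("root", "decision")
    root.add(surgery_subtree("OA", "oa", 0.0, [], []))
    root.add(surgery_subtree("LA", "la", 0.0, [], []))

    nom = TreeNode("NOM", "chance")
    nom_costs = [("nom_initial", 0.0)]
    nom_episodes = [("nom_initial", 0.0)]
    nom.add(terminal("NOM/success", nom_costs, nom_episodes), pref("p_nom_success"))
    nom.add(
        appendectomy_choice("NOM/initial_failure", 0.0, nom_costs, nom_episodes),
        pref("p_nom_initial_failure"),
    )
    for year in range(1, params.horizon_years + 1):
        recur = TreeNode(f"NOM/recurrence_y{year}", "chance")
        recur.add(
            appendectomy_choice(f"{recur.id}/uncomplicated", float(year), nom_costs, nom_episodes),
            pcomp(pref("p_recur_complicated")),
        )
        complicated = TreeNode(f"{recur.id}/complicated", "chance")
        comp_costs = [*nom_costs, ("complicated_aa", float(year))]
        comp_episodes = [*nom_episodes, ("complicated_aa", float(year))]
        complicated.add(
            appendectomy_choice(f"{complicated.id}/medical_interval", float(year), comp_costs, comp_episodes),
            pref("p_complicated_medical"),
        )
        complicated.add(
            appendectomy_choice(
                f"{complicated.id}/immediate_surgery", float(year), nom_costs, comp_episodes
            ),
            pcomp(pref("p_complicated_medical")),
        )
        recur.add(complicated, pref("p_recur_complicated"))
        nom.add(recur, precur(year))
    root.add(nom)

    tree = DecisionTree(root, params.horizon_years)
    report = validate_tree(tree, params)
    if report:
        raise TreeError("invalid model structure: " + "; ".join(report))
    return tree


# --------------------------------------------------------------------------
# traversal, validation, export
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Path:
    """One root-to-terminal path within a strategy subtree."""

    strategy: str
    terminal_id: str
    prob_exprs: tuple[Expr, ...]
    cost_entries: tuple[CostEntry, ...]
    utility_entries: tuple[UtilityEntry, ...]

    def probability(self, params: ParameterSet) -> float:
        p = 1.0
        for e in self.prob_exprs:
            p *= e(params)
        return p


def iter_paths(tree: DecisionTree) -> Iterator[Path]:
    """Enumerate every root-to-terminal path, grouped under its strategy."""

    def walk(node: TreeNode, strategy: str, exprs, costs, utils):
        costs = costs + tuple(node.cost_entries)
        utils = utils + tuple(node.utility_entries)
        if not node.children:
            yield Path(strategy, node.id, exprs, costs, utils)
            return
        for child, prob in node.children:
            child_exprs = exprs if prob is None else exprs + (prob,)
            yield from walk(child, strategy, child_exprs, costs, utils)

    for child, _ in tree.root.children:
        yield from walk(child, child.id, (), (), ())


def validate_tree(tree: DecisionTree, params: ParameterSet) -> list[str]:
    """Report every structural invariant violation (empty report == valid)."""
    report: list[str] = []
    horizon = float(tree.horizon_years)
    seen_ids: set[str] = set()

    def walk(node: TreeNode, is_root: bool) -> None:
        if node.id in seen_ids:
            report.append(f"{node.id}: duplicate node id")
        seen_ids.add(node.id)
        if node.kind == "decision" and not is_root:
            report.append(f"{node.id}: decision node allowed only at the root")
        if node.kind == "terminal" and node.children:
            report.append(f"{node.id}: terminal node must have no children")
        if node.kind in ("decision", "chance") and not node.children:
            report.append(f"{node.id}: {node.kind} node must have children")
        for entry in node.cost_entries:
            if not 0.0 <= entry.year <= horizon:
                report.append(f"{node.id}: cost event {entry.event!r} at year {entry.year} outside [0, {horizon}]")
            for bad in FORBIDDEN_STATES:
                if bad in entry.event:
                    report.append(f"{node.id}: cost event {entry.event!r} references excluded state {bad!r}")
        for entry in node.utility_entries:
            if entry.start < -PROB_TOL or entry.start + entry.duration > horizon + PROB_TOL:
                report.append(
                    f"{node.id}: utility window [{entry.start}, {entry.start + entry.duration}] outside [0, {horizon}]"
                )
            if entry.duration < 0:
                report.append(f"{node.id}: utility entry {entry.state!r} has negative duration")
            for bad in FORBIDDEN_STATES:
                if bad in entry.state:
                    report.append(f"{node.id}: utility state {entry.state!r} references excluded state {bad!r}")
        if node.kind == "chance":
            probs = []
            for child, prob in node.children:
                if prob is None:
                    report.append(f"{node.id}: chance-node child {child.id} lacks a probability")
                    continue
                try:
                    v = prob(params)
                except Exception as exc:  # expression referencing a missing field
                    report.append(f"{node.id}: probability {prob.label!r} failed: {exc}")
                    continue
                if not -PROB_TOL <= v <= 1.0 + PROB_TOL:
                    report.append(f"{node.id}: child {child.id} probability {v:.12g} outside [0, 1]")
                probs.append(v)
            if probs and abs(sum(probs) - 1.0) > 1e-9:
                report.append(f"{node.id}: child probabilities sum to {sum(probs):.12g}, not 1")
        if node.kind == "decision":
            for child, prob in node.children:
                if prob is not None:
                    report.append(f"{node.id}: decision-node child {child.id} must not carry a probability")
        for child, _ in node.children:
            walk(child, False)

    walk(tree.root, True)
    return report


def to_outline(tree: DecisionTree, params: ParameterSet | None = None) -> str:
    """Plain-text indented outline; numeric probabilities shown when params given."""
    lines: list[str] = []

    def walk(node: TreeNode, prob: Expr | None, depth: int) -> None:
        label = node.id.rsplit("/", 1)[-1] if depth else node.id
        if prob is not None:
            p = f"{prob(params):.6g}" if params is not None else prob.label
            label += f"  [p = {p}]"
        if node.kind == "terminal":
            costs = ", ".join(f"{c.event}@y{c.year:g}" for c in node.cost_entries) or "-"
            label += f"  (costs: {costs})"
        lines.append("  " * depth + label)
        for child, cprob in node.children:
            walk(child, cprob, depth + 1)

    walk(tree.root, None, 0)
    return "\n".join(lines)


def to_dot(tree: DecisionTree, params: ParameterSet | None = None) -> str:
    """GraphViz DOT export for visual inspection of the model structure."""
    lines = ["digraph model {", "  rankdir=LR;", '  node [fontsize=9];']
    shapes = {"decision": "box", "chance": "circle", "terminal": "triangle"}

    def q(node_id: str) -> str:
        return '"' + node_id.replace('"', "'") + '"'

    def walk(node: TreeNode) -> None:
        label = node.id.rsplit("/", 1)[-1]
        lines.append(f"  {q(node.id)} [label=\"{label}\", shape={shapes[node.kind]}];")
        for child, prob in node.children:
            edge = ""
            if prob is not None:
                edge = f"{prob(params):.4g}" if params is not None else prob.label
            lines.append(f"  {q(node.id)} -> {q(child.id)} [label=\"{edge}\", fontsize=8];")
            walk(child)

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)
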