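"""Most-parsimonious ancestral-state reconstruction on a rooted tree.

Implements the Sankoff dynamic programme (arbitrary cost matrices, soft
polytomies, "?" tips unconstrained), exact counting and enumeration of all
most-parsimonious reconstructions (MPRs), ACCTRAN/DELTRAN resolutions, and
the assignment of state-change events to branches.

Polarization: gene rearrangements are scored against the canonical
vertebrate arrangement, which acts as an implicit outgroup.  When the
character's declared ancestral state is among the cost-minimal root states
it is preferred at the root (``polarize_root=True``); the minimum change
count itself is never affected, only which of several tied rootings the
reconstructions use.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .rearrangement import CHARACTERS, MISSING, CharacterMatrix

__all__ = [
    "read_tree",
    "write_tree",
    "branch_name",
    "sankoff_min_changes",
    "fitch_count",
    "count_mprs",
    "enumerate_mprs",
    "map_events",
    "count_state_origins",
    "constrained_cost",
    "Event",
    "EventMap",
    "annotated_newick",
]

_INF = float("inf")

#: default cap on explicit MPR enumeration before sampling/error kicks in
DEFAULT_MPR_BOUND = 100_000


# ---------------------------------------------------------------------------
# tree plumbing (dendropy behind the surface)

def read_tree(source) -> dendropy.Tree:
    """Read a rooted Newick tree from a path, file object or string.

    Internal node labels are preserved and never reinterpreted as taxa.
    """
    if isinstance(source, dendropy.Tree):
        return source
    kwargs = dict(schema="newick", suppress_internal_node_taxa=True,
                  preserve_underscores=True)
    text = None
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    if text is not None:
        tree = dendropy.Tree.get(data=text, **kwargs)
    else:
        tree = dendropy.Tree.get(path=str(source), **kwargs)
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True))


def branch_name(node) -> str:
    """Stable display name for the branch subtending `node`."""
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    tips = sorted(lf.taxon.label for lf in node.leaf_iter())
    return f"clade({tips[0]}+{len(tips) - 1})"


def _tip_label(node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "")


def _check_tips(tree, tip_states, prune_missing=False):
    labels = {_tip_label(lf) for lf in tree.leaf_node_iter()}
    extra = set(tip_states) - labels
    if extra:
        raise ValueError(f"taxa absent from tree: {sorted(extra)}")
    missing = labels - set(tip_states)
    if missing:
        if not prune_missing:
            raise ValueError(
                f"tree tips without states: {sorted(missing)} "
                "(pass prune_missing=True to drop them)")
        tree = tree.clone(depth=1)
        keep = [t for t in tree.taxon_namespace if t.label in tip_states]
        tree.retain_taxa(keep)
    return tree


# ---------------------------------------------------------------------------
# Sankoff tables

def _uniform_cost(k: int) -> np.ndarray:
    return np.ones((k, k)) - np.eye(k)


def _resolve_states(tip_states, states) -> List[str]:
    if states is None:
        states = sorted({s for s in tip_states.values() if s != MISSING})
    states = list(states)
    if not states:
        raise ValueError("no states observed and none supplied")
    return states


def _tables(tree, tip_states, states, cost, constraints=None):
    """Bottom-up Sankoff cost tables; returns {node: cost vector}."""
    idx = {s: i for i, s in enumerate(states)}
    k = len(states)
    table = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = _tip_label(node)
            state = tip_states.get(label, MISSING)
            if state == MISSING:
                vec = np.zeros(k)
            else:
                if state not in idx:
                    raise ValueError(f"tip {label}: state {state!r} not in {states}")
                vec = np.full(k, _INF)
                vec[idx[state]] = 0.0
        else:
            vec = np.zeros(k)
            for child in node.child_nodes():
                # cost[s] += min_t child_cost[t] + C[s, t]
                vec = vec + (cost + table[child][None, :]).min(axis=1)
        if constraints:
            pin = constraints.get(node.label)
            if pin is not None:
                if pin not in idx:
                    raise ValueError(f"constraint state {pin!r} not in {states}")
                mask = np.full(k, _INF)
                mask[idx[pin]] = 0.0
                vec = vec + mask
        table[node] = vec
    return table, idx


def sankoff_min_changes(tree, tip_states: Dict[str, str],
                        cost_matrix: Optional[np.ndarray] = None,
                        states: Optional[Sequence[str]] = None,
                        prune_missing: bool = False) -> float:
    """Minimum total substitution cost over all ancestral labelings.

    Default cost is uniform (1 off-diagonal), in which case the result is
    the parsimony change count.  Tips scored "?" contribute zero cost for
    every state.
    """
    tree = _check_tips(read_tree(tree), tip_states, prune_missing)
    states = _resolve_states(tip_states, states)
    cost = _uniform_cost(len(states)) if cost_matrix is None else np.asarray(cost_matrix, float)
    table, _ = _tables(tree, tip_states, states, cost)
    value = float(table[tree.seed_node].min())
    return int(value) if value == int(value) else value


def fitch_count(tree, tip_states: Dict[str, str],
                prune_missing: bool = False) -> int:
    """Fitch parsimony count (independent of the Sankoff DP path).

    Classical set-based bottom-up pass, generalized to polytomies by the
    standard most-frequent-element rule: at an internal node the state set
    is the set of states attaining the maximum number of child-set votes,
    and the change count increases by (number of children) minus (maximum
    vote count).  For binary trees this is Fitch's union/intersection rule.
    """
    tree = _check_tips(read_tree(tree), tip_states, prune_missing)
    states = _resolve_states(tip_states, None)
    changes = 0
    sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states.get(_tip_label(node), MISSING)
            sets[node] = set(states) if s == MISSING else {s}
        else:
            votes = {}
            for child in node.child_nodes():
                for s in sets[child]:
                    votes[s] = votes.get(s, 0) + 1
            top = max(votes.values())
            sets[node] = {s for s, v in votes.items() if v == top}
            changes += len(node.child_nodes()) - top
    return changes


def _root_states(table, idx, states, root, ancestral_state, polarize_root):
    root_costs = table[root]
    best = root_costs.min()
    minima = [states[i] for i in range(len(states))
              if root_costs[i] == best]
    if polarize_root and ancestral_state in minima:
        return [ancestral_state]
    return minima


def count_mprs(tree, tip_states, states=None, cost_matrix=None,
               ancestral_state=None, polarize_root=True,
               prune_missing=False) -> int:
    """Exact number of most-parsimonious full labelings (no enumeration)."""
    tree = _check_tips(read_tree(tree), tip_states, prune_missing)
    states = _resolve_states(tip_states, states)
    cost = _uniform_cost(len(states)) if cost_matrix is None else np.asarray(cost_matrix, float)
    table, idx = _tables(tree, tip_states, states, cost)

    counts = {}

    def n_below(node, si) -> int:
        key = (id(node), si)
        if key in counts:
            return counts[key]
        if node.is_leaf():
            counts[key] = 1
            return 1
        total = 1
        for child in node.child_nodes():
            opts = cost[si] + table[child]
            best = opts.min()
            total *= sum(n_below(child, ti)
                         for ti in range(len(states)) if opts[ti] == best)
        counts[key] = total
        return total

    roots = _root_states(table, idx, states, tree.seed_node,
                         ancestral_state, polarize_root)
    return sum(n_below(tree.seed_node, idx[s]) for s in roots)


def enumerate_mprs(tree, tip_states, states=None, cost_matrix=None,
                   ancestral_state=None, polarize_root=True,
                   prune_missing=False, bound=DEFAULT_MPR_BOUND):
    """Yield every MPR as a dict {branch_name: state} (root under "<root>").

    Raises if the exact MPR count exceeds `bound`.
    """
    tree = _check_tips(read_tree(tree), tip_states, prune_missing)
    states = _resolve_states(tip_states, states)
    cost = _uniform_cost(len(states)) if cost_matrix is None else np.asarray(cost_matrix, float)
    table, idx = _tables(tree, tip_states, states, cost)
    total = count_mprs(tree, tip_states, states, cost,
                       ancestral_state, polarize_root)
    if total > bound:
        raise RuntimeError(f"{total} MPRs exceed enumeration bound {bound}")

    root = tree.seed_node
    internal = [n for n in tree.preorder_node_iter()]

    def assignments(node, si):
        """Generate {node: state_index} maps for the subtree below node."""
        base = {node: si}
        child_opt = []
        for child in node.child_nodes():
            opts = cost[si] + table[child]
            best = opts.min()
            child_opt.append((child, [ti for ti in range(len(states))
                                      if opts[ti] == best]))

        def rec(i):
            if i == len(child_opt):
                yield {}
                return
            child, choices = child_opt[i]
            for ti in choices:
                for sub in assignments(child, ti):
                    for rest in rec(i + 1):
                        merged = dict(sub)
                        merged.update(rest)
                        yield merged
        for combo in rec(0):
            combo.update(base)
            yield combo

    for root_state in _root_states(table, idx, states, root,
                                   ancestral_state, polarize_root):
        for assign in assignments(root, idx[root_state]):
            out = {}
            for node, si in assign.items():
                key = "<root>" if node is root else branch_name(node)
                out[key] = states[si]
            yield out


# ---------------------------------------------------------------------------
# event mapping


@dataclass(frozen=True)
class Event:
    branch: str
    from_state: str
    to_state: str
    ambiguous: bool = False


@dataclass
class EventMap:
    """Per-character parsimony summary: minimum change counts and one
    resolved set of branch events, with ambiguity flags and (when
    enumerable) the exact number of equally parsimonious reconstructions."""

    min_changes: dict = field(default_factory=dict)     # char -> int
    events: dict = field(default_factory=dict)          # char -> [Event]
    n_mprs: dict = field(default_factory=dict)          # char -> int
    resolution: str = "DELTRAN"
    approximate: bool = False

    def to_dict(self) -> dict:
        return {
            "resolution": self.resolution,
            "approximate": self.approximate,
            "characters": {
                cid: {
                    "min_changes": self.min_changes[cid],
                    "n_mprs": self.n_mprs.get(cid),
                    "events": [
                        {"branch": e.branch, "from": e.from_state,
                         "to": e.to_state, "ambiguous": e.ambiguous}
                        for e in self.events[cid]
                    ],
                }
                for cid in self.min_changes
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_branch_tsv(self) -> str:
        lines = ["character\tbranch\tfrom_state\tto_state\tambiguous"]
        for cid, events in self.events.items():
            for e in events:
                lines.append(f"{cid}\t{e.branch}\t{e.from_state}\t{e.to_state}"
                             f"\t{int(e.ambiguous)}")
        return "\n".join(lines) + "\n"


def _resolve_one(tree, table, idx, states, cost, root_state, mode, rng=None):
    """One full labeling under ACCTRAN/DELTRAN-style tie-breaking.

    DELTRAN keeps the parent state whenever it is among the optimal child
    choices (changes delayed tipward); ACCTRAN prefers a different state
    when one is optimal (changes accelerated rootward).  With `rng` set the
    choice among optima is random (used for MPR sampling).
    """
    assign = {}
    root = tree.seed_node
    assign[root] = idx[root_state]
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        si = assign[node]
        for child in node.child_nodes():
            opts = cost[si] + table[child]
            best = opts.min()
            choices = [ti for ti in range(len(states)) if opts[ti] == best]
            if rng is not None:
                pick = rng.choice(choices)
            elif mode == "DELTRAN" and si in choices:
                pick = si
            elif mode == "ACCTRAN":
                non_parent = [t for t in choices if t != si]
                pick = non_parent[0] if non_parent else choices[0]
            else:
                pick = choices[0]
            assign[child] = pick
    return assign


def _events_of(tree, assign, states) -> List[Event]:
    events = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        a, b = assign[parent], assign[node]
        if a != b:
            events.append(Event(branch_name(node), states[a], states[b]))
    return events


def map_events(tree, matrix, resolution: str = "DELTRAN",
               cost_matrix=None, prune_missing=False,
               polarize_root=True, bound=DEFAULT_MPR_BOUND,
               sample: int = 0, seed: int = 0) -> EventMap:
    """Assign most-parsimonious state changes to branches, per character.

    `matrix` is a :class:`CharacterMatrix` (or {char: {taxon: state}}).
    ``resolution`` is ACCTRAN, DELTRAN (default; changes pushed tipward,
    matching subfamily-stem placements) or "all".  Events whose branch
    placement differs between MPRs are flagged ambiguous whenever full
    enumeration is feasible; with ``resolution="all"`` the events of every
    MPR are unioned.  If the MPR count exceeds `bound`, enumeration falls
    back to weighted sampling of `sample` reconstructions (seeded) when
    sample > 0, else raises.
    """
    if isinstance(matrix, CharacterMatrix):
        columns = {cid: matrix.column(cid) for cid in matrix.characters}
        chars = matrix.characters
    else:
        columns = matrix
        chars = {cid: CHARACTERS.get(cid) for cid in columns}
    if resolution not in ("ACCTRAN", "DELTRAN", "all"):
        raise ValueError(f"unknown resolution {resolution!r}")

    emap = EventMap(resolution=resolution)
    for cid, tip_states in columns.items():
        char = chars.get(cid)
        states = list(char.states) if char is not None else None
        ancestral = char.ancestral_state if char is not None else None
        states = _resolve_states(tip_states, states)
        if ancestral is not None and ancestral not in states:
            states.append(ancestral)
        t = _check_tips(read_tree(tree), tip_states, prune_missing)
        cost = (_uniform_cost(len(states)) if cost_matrix is None
                else np.asarray(cost_matrix, float))
        table, idx = _tables(t, tip_states, states, cost)
        min_cost = float(table[t.seed_node].min())
        emap.min_changes[cid] = int(min_cost) if min_cost == int(min_cost) else min_cost
        n = count_mprs(t, tip_states, states, cost, ancestral, polarize_root)
        emap.n_mprs[cid] = n

        # event sets across MPRs, for ambiguity flags / "all" mode
        event_sets = None
        if n <= bound:
            event_sets = []
            for mpr in enumerate_mprs(t, tip_states, states, cost,
                                      ancestral, polarize_root, bound=bound):
                evs = _mpr_events(t, mpr, states)
                event_sets.append(frozenset(evs))
        elif sample > 0:
            rng = random.Random(seed)
            roots = _root_states(table, idx, states, t.seed_node,
                                 ancestral, polarize_root)
            event_sets = []
            for _ in range(sample):
                rs = rng.choice(roots)
                assign = _resolve_one(t, table, idx, states, cost, rs,
                                      "DELTRAN", rng=rng)
                event_sets.append(frozenset(
                    (e.branch, e.from_state, e.to_state)
                    for e in _events_of(t, assign, states)))
            emap.approximate = True
        else:
            raise RuntimeError(
                f"{cid}: {n} MPRs exceed bound {bound}; pass sample>0 to "
                "approximate")

        common = frozenset.intersection(*event_sets) if event_sets else frozenset()
        if resolution == "all":
            union = frozenset.union(*event_sets) if event_sets else frozenset()
            chosen = sorted(union)
        else:
            roots = _root_states(table, idx, states, t.seed_node,
                                 ancestral, polarize_root)
            assign = _resolve_one(t, table, idx, states, cost, roots[0],
                                  resolution)
            chosen = sorted((e.branch, e.from_state, e.to_state)
                            for e in _events_of(t, assign, states))
        emap.events[cid] = [
            Event(b, f, s, ambiguous=(b, f, s) not in common)
            for b, f, s in chosen
        ]
    return emap


def _mpr_events(tree, mpr: dict, states) -> List[Tuple[str, str, str]]:
    events = []
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        pkey = "<root>" if parent is root else branch_name(parent)
        a = mpr[pkey]
        b = mpr[branch_name(node)]
        if a != b:
            events.append((branch_name(node), a, b))
    return events


def count_state_origins(tree, tip_states, derived_state,
                        states=None, cost_matrix=None,
                        ancestral_state=None, polarize_root=True,
                        prune_missing=False,
                        bound=DEFAULT_MPR_BOUND) -> Tuple[int, int]:
    """(min, max) number of branches gaining `derived_state` over all MPRs.

    A gain is an edge whose parent state differs from `derived_state` and
    whose child state equals it; a derived root does not count as a gain.
    """
    states = _resolve_states(tip_states, states)
    if derived_state not in states:
        raise ValueError(f"derived state {derived_state!r} not in {states}")
    t = _check_tips(read_tree(tree), tip_states, prune_missing)
    lo, hi = None, None
    for mpr in enumerate_mprs(t, tip_states, states, cost_matrix,
                              ancestral_state, polarize_root, bound=bound):
        gains = sum(1 for br, frm, to in _mpr_events(t, mpr, states)
                    if to == derived_state)
        lo = gains if lo is None else min(lo, gains)
        hi = gains if hi is None else max(hi, gains)
    return lo, hi


def constrained_cost(tree, tip_states, node_constraints: Dict[str, str],
                     states=None, cost_matrix=None,
                     prune_missing=False) -> float:
    """Minimum change count subject to pinned internal-node states.

    `node_constraints` maps internal-node labels to required states; an
    unknown label raises.  With no constraints this equals
    :func:`sankoff_min_changes`.
    """
    t = _check_tips(read_tree(tree), tip_states, prune_missing)
    labels = {n.label for n in t.preorder_internal_node_iter() if n.label}
    unknown = set(node_constraints) - labels
    if unknown:
        raise ValueError(f"constraint labels not found in tree: {sorted(unknown)}")
    states = _resolve_states(tip_states, states)
    for s in node_constraints.values():
        if s not in states:
            states = states + [s]
    cost = (_uniform_cost(len(states)) if cost_matrix is None
            else np.asarray(cost_matrix, float))
    table, _ = _tables(t, tip_states, states, cost, constraints=node_constraints)
    value = float(table[t.seed_node].min())
    if value == _INF:
        raise ValueError("constraints are jointly unsatisfiable")
    return int(value) if value == int(value) else value


def annotated_newick(tree, emap: EventMap) -> str:
    """Newick string with per-branch event comments in bracketed labels."""
    t = read_tree(tree).clone(depth=1)
    by_branch: Dict[str, List[str]] = {}
    for cid, events in emap.events.items():
        for e in events:
            tag = f"{cid}:{e.from_state}->{e.to_state}" + ("(?)" if e.ambiguous else "")
            by_branch.setdefault(e.branch, []).append(tag)
    for node in t.preorder_node_iter():
        name = branch_name(node)
        if name in by_branch:
            comment = "&events=" + "|".join(by_branch[name])
            node.annotations.add_new("events", "|".join(by_branch[name]))
    return t.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True,
                       suppress_annotations=False)
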