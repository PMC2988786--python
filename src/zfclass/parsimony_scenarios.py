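"""Gene-family origin scenarios under Dollo and Fitch parsimony.

Given a rooted species tree and a presence/absence map for one gene family,
each candidate origin node is scored under Dollo parsimony: the gene is
gained exactly once (at the origin) and may be lost any number of times.
Losses are counted per edge — a single loss event silences an entire absent
clade — so the minimal loss set is the set of *maximal absent subtrees*
within the origin's subtree. A scenario is feasible only when the origin is
ancestral to every taxon that retains the gene.

Fitch (unordered two-state) parsimony provides an independent lower bound:
any feasible Dollo scenario spends at least as many events.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .seqio import PresenceMap, SeqIOError, SpeciesTree, parse_newick

#: Default metazoan species topology: poriferans and ctenophores branch
#: before the placozoan/cnidarian/bilaterian clade (basal order among the
#: two earliest lineages is debated; it does not affect event counts here).
#: Internal labels name the candidate zic-origin nodes: the metazoan root
#: and the placozoan/cnidarian/bilaterian last common ancestor.
DEFAULT_TREE_NEWICK = (
    "(Porifera,(Ctenophora,(Placozoa,(Cnidaria,Bilateria)CniBil)PlaCniBil)N1)Metazoa;"
)

#: zic presence pattern across the default tree's leaves.
DEFAULT_ZIC_PRESENCE = {
    "Porifera": False,
    "Ctenophora": False,
    "Placozoa": True,
    "Cnidaria": True,
    "Bilateria": True,
}

#: The two candidate origin scenarios: gain at the base of the Metazoa
#: versus gain in the placozoan/cnidarian/bilaterian ancestor.
DEFAULT_ORIGIN_CANDIDATES = ("Metazoa", "PlaCniBil")


def default_scenario_inputs() -> tuple[SpeciesTree, PresenceMap, list[str]]:
    """The bundled species tree, zic presence map and origin candidates."""
    return (
        parse_newick(DEFAULT_TREE_NEWICK),
        PresenceMap(dict(DEFAULT_ZIC_PRESENCE)),
        list(DEFAULT_ORIGIN_CANDIDATES),
    )


@dataclass(frozen=True)
class ScenarioResult:
    """Event counts for one candidate origin node."""

    origin: str
    feasible: bool
    gains: int | None = None
    losses: int | None = None
    tie: bool = False

    @property
    def total_events(self) -> int | None:
        if not self.feasible:
            return None
        return self.gains + self.losses


def _presence_lookup(tree: SpeciesTree, presence: PresenceMap) -> dict[str, bool]:
    leaves = tree.leaf_labels()
    missing = sorted(set(leaves) - set(presence.presence))
    if missing:
        raise SeqIOError(f"presence map missing taxa: {', '.join(missing)}")
    presence.validate_against(tree)
    return dict(presence.presence)


def dollo_counts(
    tree: SpeciesTree, presence: PresenceMap, origin: str | dendropy.Node
) -> ScenarioResult:
    """Count events for a single gain at *origin* with per-edge losses.

    The loss count is the number of maximal subtrees under the origin whose
    leaves are all absent; marking each such subtree's stem edge as a loss
    reproduces exactly the observed presence pattern, and no assignment with
    a single gain does better. Infeasible (a present leaf outside the
    origin's subtree) scenarios carry no counts.
    """
    node = origin if isinstance(origin, dendropy.Node) else tree.find_node(origin)
    label = tree.node_label(node)
    pres = _presence_lookup(tree, presence)
    present = {t for t, p in pres.items() if p}
    if not present:
        raise SeqIOError("no taxon has the gene; no origin scenario is defined")

    under = tree.leaf_labels_under(node)
    if not present <= under:
        return ScenarioResult(origin=label, feasible=False)

    # all_absent[n] = every leaf under n lacks the gene
    all_absent: dict[dendropy.Node, bool] = {}
    for n in node.postorder_iter():
        if n.is_leaf():
            all_absent[n] = not pres[n.taxon.label]
        else:
            all_absent[n] = all(all_absent[c] for c in n.child_nodes())

    losses = 0
    stack = [node]
    while stack:
        n = stack.pop()
        if all_absent[n]:
            if n is node:
                # degenerate: origin subtree entirely absent — handled above
                raise AssertionError("unreachable: origin subtree has present leaves")
            losses += 1  # maximal absent subtree: one loss on its stem edge
            continue
        stack.extend(n.child_nodes())
    return ScenarioResult(origin=label, feasible=True, gains=1, losses=losses)


def fitch_min_events(tree: SpeciesTree, presence: PresenceMap) -> int:
    """Minimum state changes under unordered two-state (Fitch) parsimony."""
    pres = _presence_lookup(tree, presence)
    changes = 0
    state: dict[dendropy.Node, frozenset[bool]] = {}
    for n in tree.root.postorder_iter():
        if n.is_leaf():
            state[n] = frozenset([pres[n.taxon.label]])
        else:
            sets = [state[c] for c in n.child_nodes()]
            inter = frozenset.intersection(*sets)
            if inter:
                state[n] = inter
            else:
                # generalized Fitch for polytomies: keep majority states,
                # one change per child set dropped
                counts: dict[bool, int] = {}
                for s in sets:
                    for v in s:
                        counts[v] = counts.get(v, 0) + 1
                top = max(counts.values())
                state[n] = frozenset(v for v, c in counts.items() if c == top)
                changes += len(sets) - top
    return changes


def rank_scenarios(
    tree: SpeciesTree, presence: PresenceMap, origins: list[str]
) -> list[ScenarioResult]:
    """Score every candidate origin and sort feasible ones by total events.

    Ties on total events are reported jointly (``tie=True`` on each member).
    Infeasible scenarios trail the list; all-infeasible input is an error.
    """
    if not origins:
        raise SeqIOError("at least one candidate origin is required")
    results = [dollo_counts(tree, presence, o) for o in origins]
    feasible = sorted(
        (r for r in results if r.feasible), key=lambda r: (r.total_events, r.origin)
    )
    if not feasible:
        raise SeqIOError("all candidate origins are infeasible")
    totals = [r.total_events for r in feasible]
    feasible = [
        ScenarioResult(
            origin=r.origin,
            feasible=True,
            gains=r.gains,
            losses=r.losses,
            tie=totals.count(r.total_events) > 1,
        )
        for r in feasible
    ]
    infeasible = [r for r in results if not r.feasible]
    return feasible + infeasible


def scenario_report_rows(results: list[ScenarioResult]) -> list[dict]:
    return [
        {
            "origin": r.origin,
            "feasible": r.feasible,
            "gains": "" if r.gains is None else r.gains,
            "losses": "" if r.losses is None else r.losses,
            "total_events": "" if r.total_events is None else r.total_events,
            "tie": r.tie,
        }
        for r in results
    ]
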