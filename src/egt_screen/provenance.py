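"""Paralog purging and host-versus-endosymbiont provenance classification.

The provenance question is answered on per-family gene trees whose leaves
carry taxon roles: query taxa (the nucleomorph-bearing lineage under study),
host-side outgroups, endosymbiont-side algal references, and other reference
taxa.  A query protein is called host-related or algal-related when the clade
joining it to the reference taxa is composed (at a configurable purity) of
host outgroups or of algal references respectively, and the bootstrap support
of that joining node exceeds a threshold (strictly greater than, default 70);
otherwise the call is ambiguous.  Before classification, hits that form
well-supported clades dominated by a different family assignment are purged
over up to three realign-and-rebuild cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .homology_search import SearchHit, augment_family_alignment
from .phylo import bootstrap_supports, midpoint_root
from .profile_hmm import ProfileHMM
from .seqio import Alignment, TaxonRoleMap
from .trees import Node, PhyloTree

__all__ = [
    "AffinityCall",
    "PurgeReport",
    "annotate_leaves",
    "purge_paralogs",
    "accept_orthologs",
    "classify_affinity",
]

QUERY_ROLE = "query_host_lineage"
REFERENCE_ROLES = ("host_outgroup", "endosymbiont_algal", "other_reference")


@dataclass(frozen=True)
class AffinityCall:
    protein_id: str
    taxon: str
    family: str
    label: str  # host_related | algal_related | ambiguous | unclassifiable
    support_at_decision: int | None
    sister_composition: dict
    cycle_retained: bool = True


@dataclass
class PurgeReport:
    family: str
    removed: list[dict] = field(default_factory=list)  # one dict per cycle
    cycles_run: int = 0
    converged: bool = False
    final_tree: PhyloTree | None = None

    def all_removed_ids(self) -> set[str]:
        out: set[str] = set()
        for cycle in self.removed:
            ids = set(cycle)
            if out & ids:
                raise ValueError("a protein was removed in two cycles")
            out |= ids
        return out


def annotate_leaves(tree: PhyloTree, taxa: dict[str, str], roles: TaxonRoleMap) -> None:
    """Attach taxon and role to each leaf (leaf name -> taxon -> role)."""
    for leaf in tree.leaves():
        if leaf.name not in taxa:
            raise KeyError(f"leaf {leaf.name!r} has no taxon annotation")
        leaf.taxon = taxa[leaf.name]
        leaf.role = roles.role(leaf.taxon)


def _leaves_under(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf():
            out.append(n)
        stack.extend(n.children)
    return out


def _sister_context(leaf: Node):
    """Collapse the maximal all-query clade containing ``leaf`` and walk
    rootward to the first ancestor bringing in reference leaves.

    Returns (ancestor, reference_leaves, support): ancestor is None when the
    tree contains no reference leaf on the path to the root."""
    node = leaf
    while node.parent is not None and all(
        lf.role == QUERY_ROLE for lf in _leaves_under(node.parent)
    ):
        node = node.parent
    prev, anc = node, node.parent
    while anc is not None:
        refs = [
            lf
            for ch in anc.children
            if ch is not prev
            for lf in _leaves_under(ch)
            if lf.role != QUERY_ROLE
        ]
        if refs:
            return anc, refs, anc.support
        prev, anc = anc, anc.parent
    return None, [], None


def purge_paralogs(
    family: str,
    alignment: Alignment,
    hits: list[SearchHit],
    roles: TaxonRoleMap,
    profile: ProfileHMM,
    max_cycles: int = 3,
    support_threshold: int = 70,
    wrong_fraction: float = 0.5,
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[Alignment, PurgeReport]:
    """Iteratively remove hit clades that group with a different family.

    Per cycle: build a bootstrapped tree; find the maximal clades in which
    more than ``wrong_fraction`` of the family-annotated leaves carry an
    assignment other than ``family`` and whose support exceeds
    ``support_threshold``; drop the hit leaves inside; re-insert the
    survivors into the reference alignment.  Stops on convergence (a cycle
    that removes nothing) or after ``max_cycles`` cycles.
    """
    hit_by_id: dict[str, SearchHit] = {h.protein_id: h for h in hits}
    report = PurgeReport(family=family)
    current = alignment
    for cycle in range(max_cycles):
        tree = bootstrap_supports(current, n_reps=n_reps, seed=seed + cycle)
        taxa = {rec.id: rec.taxon for rec, _ in current.rows}
        annotate_leaves(tree, taxa, roles)
        # clades are only meaningful on a rooted tree; an arbitrary display
        # rooting can make "paralog clade + adjacent orthologs" look like one
        try:
            scan_tree = midpoint_root(tree)
        except ValueError:
            scan_tree = tree
        to_remove: dict[str, str] = {}
        stack = [scan_tree.root]
        while stack:
            node = stack.pop()
            if node.is_leaf():
                # a singleton is a trivial clade: its leaf-versus-rest split
                # holds in every replicate, i.e. support 100
                h = hit_by_id.get(node.name)
                if (
                    h is not None
                    and h.assigned_family is not None
                    and h.assigned_family != family
                ):
                    to_remove[node.name] = (
                        f"singleton assigned to {h.assigned_family}"
                    )
                continue
            leaves = _leaves_under(node)
            annotated = [
                hit_by_id[lf.name].assigned_family
                for lf in leaves
                if lf.name in hit_by_id
                and hit_by_id[lf.name].assigned_family is not None
            ]
            wrong = [a for a in annotated if a != family]
            qualifies = (
                annotated
                and len(wrong) / len(annotated) > wrong_fraction
                and node.parent is not None
                and node.support is not None
                and node.support > support_threshold
            )
            if qualifies:
                majority = max(set(wrong), key=wrong.count)
                for lf in leaves:
                    if lf.name in hit_by_id:
                        to_remove[lf.name] = (
                            f"grouped with {majority} clade "
                            f"(support {node.support})"
                        )
                continue  # maximal clade: do not descend
            stack.extend(node.children)
        report.cycles_run = cycle + 1
        if not to_remove:
            report.converged = True
            report.final_tree = tree
            break
        report.removed.append(to_remove)
        survivors = [
            rec
            for rec, _ in current.rows
            if rec.id in hit_by_id and rec.id not in to_remove
        ]
        reference = Alignment(
            family,
            [(rec, g) for rec, g in alignment.rows if rec.id not in hit_by_id],
        )
        current = augment_family_alignment(reference, survivors, profile)
    else:
        report.final_tree = bootstrap_supports(
            current, n_reps=n_reps, seed=seed + max_cycles
        )
        taxa = {rec.id: rec.taxon for rec, _ in current.rows}
        annotate_leaves(report.final_tree, taxa, roles)
    return current, report


def accept_orthologs(
    tree: PhyloTree,
    roles: TaxonRoleMap,
    hits: list[SearchHit],
    family: str,
    margin_min: float = 2.0,
) -> set[str]:
    """True-positive filter after purging.

    A query hit is retained if it clusters with reference members of the
    family (its sister context contains at least one reference leaf), or if
    its best-profile assignment is this family with a margin of at least
    ``margin_min`` bits.
    """
    if not tree.rooted:
        raise ValueError("tree must be rooted; apply midpoint_root first")
    hit_by_id = {h.protein_id: h for h in hits}
    retained: set[str] = set()
    for leaf in tree.leaves():
        if leaf.role != QUERY_ROLE or leaf.name not in hit_by_id:
            continue
        anc, refs, _ = _sister_context(leaf)
        if anc is not None and refs:
            retained.add(leaf.name)
            continue
        h = hit_by_id[leaf.name]
        if (
            h.assigned_family == family
            and h.margin is not None
            and h.margin >= margin_min
        ):
            retained.add(leaf.name)
    return retained


def classify_affinity(
    tree: PhyloTree,
    roles: TaxonRoleMap,
    family: str,
    support_threshold: int = 70,
    purity: float = 0.8,
    retained: set[str] | None = None,
) -> list[AffinityCall]:
    """Host-versus-algal affinity for every query leaf of a rooted tree.

    The query leaf's maximal all-query clade is collapsed into a unit; the
    first rootward ancestor contributing reference leaves defines the sister
    composition.  host_related / algal_related require the corresponding role
    fraction >= ``purity`` among those reference leaves AND support strictly
    above ``support_threshold`` at the joining node; otherwise ambiguous.
    Trees without reference leaves yield unclassifiable calls.
    """
    if not tree.rooted:
        raise ValueError("tree must be rooted; apply midpoint_root first")
    calls: list[AffinityCall] = []
    for leaf in tree.leaves():
        if leaf.role != QUERY_ROLE:
            continue
        anc, refs, support = _sister_context(leaf)
        if anc is None:
            calls.append(AffinityCall(
                protein_id=leaf.name, taxon=leaf.taxon, family=family,
                label="unclassifiable", support_at_decision=None,
                sister_composition={},
                cycle_retained=(retained is None or leaf.name in retained),
            ))
            continue
        comp: dict[str, int] = {}
        for r in refs:
            comp[r.role] = comp.get(r.role, 0) + 1
        total = sum(comp.values())
        host_frac = comp.get("host_outgroup", 0) / total
        algal_frac = comp.get("endosymbiont_algal", 0) / total
        if host_frac >= purity:
            label = "host_related"
        elif algal_frac >= purity:
            label = "algal_related"
        else:
            label = "ambiguous"
        if label != "ambiguous" and (support is None or support <= support_threshold):
            label = "ambiguous"
        calls.append(AffinityCall(
            protein_id=leaf.name, taxon=leaf.taxon, family=family,
            label=label,
            support_at_decision=support,
            sister_composition=comp,
            cycle_retained=(retained is None or leaf.name in retained),
        ))
    return calls
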