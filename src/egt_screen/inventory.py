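"""Per-family x per-taxon inventory matrix and subcomplex summary.

The matrix is the machine-readable form of the copy-number/affinity circle
grids used to summarize nucleoporin repertoires: one cell per (registry
family, query taxon) holding the retained copies with their phylogenetic
affinity, signal-peptide verdict, and N-terminus completeness.  A
control-family completeness proxy stands in for an external single-copy
ortholog benchmark, and consistent absences across several sufficiently
complete taxa are flagged as corroborated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .homology_search import HitTable
from .provenance import AffinityCall
from .seqio import FamilyRegistry, TaxonRoleMap
from .targeting import TargetingEvidence

__all__ = [
    "CopyEntry",
    "InventoryCell",
    "InventoryMatrix",
    "build_matrix",
    "completeness_proxy",
    "control_families",
    "corroborate_absences",
    "subcomplex_summary",
]


@dataclass(frozen=True)
class CopyEntry:
    protein_id: str
    affinity: str
    sp_flag: bool | None  # None = inconclusive / unevaluable
    nterm_complete: bool


@dataclass
class InventoryCell:
    family: str
    taxon: str
    copies: list[CopyEntry] = field(default_factory=list)
    absence_corroborated: bool = False

    @property
    def copy_count(self) -> int:
        return len(self.copies)


@dataclass
class InventoryMatrix:
    families: list[str]  # registry order
    taxa: list[str]  # role-then-name order
    cells: dict[tuple[str, str], InventoryCell]
    completeness: dict[str, float] = field(default_factory=dict)

    def cell(self, family: str, taxon: str) -> InventoryCell:
        return self.cells[(family, taxon)]

    def total_copies(self) -> int:
        return sum(c.copy_count for c in self.cells.values())


def build_matrix(
    calls: list[AffinityCall],
    evidence: dict[str, TargetingEvidence],
    registry: FamilyRegistry,
    roles: TaxonRoleMap,
) -> InventoryMatrix:
    """Assemble the inventory from retained affinity calls and targeting
    evidence.  Calls must reference registered families; the taxon axis is
    every query-role taxon, ordered by name."""
    families = registry.families()
    taxa = roles.taxa_with_role("query_host_lineage")
    cells = {
        (f, t): InventoryCell(family=f, taxon=t) for f in families for t in taxa
    }
    for call in sorted(calls, key=lambda c: (c.family, c.taxon, c.protein_id)):
        if not call.cycle_retained:
            continue
        if call.family not in registry.entries:
            raise KeyError(f"call references unregistered family {call.family!r}")
        if call.taxon not in taxa:
            continue
        ev = evidence.get(call.protein_id)
        cells[(call.family, call.taxon)].copies.append(CopyEntry(
            protein_id=call.protein_id,
            affinity=call.label,
            sp_flag=ev.sp_predicted if ev else None,
            nterm_complete=ev.nterm_complete if ev else False,
        ))
    return InventoryMatrix(families=families, taxa=taxa, cells=cells)


def control_families(
    hits: HitTable,
    registry: FamilyRegistry,
    roles: TaxonRoleMap,
    min_reference_fraction: float = 0.8,
) -> list[str]:
    """Registry families detected (>= 1 hit) in at least
    ``min_reference_fraction`` of the reference-role taxa; these serve as the
    completeness control set."""
    ref_taxa = [
        t for t, r in roles.entries.items() if r != "query_host_lineage"
    ]
    if not ref_taxa:
        raise ValueError("no reference taxa available for the control set")
    out = []
    for fam in registry.families():
        detected = {h.taxon for h in hits.for_family(fam)} & set(ref_taxa)
        if len(detected) >= min_reference_fraction * len(ref_taxa):
            out.append(fam)
    return out


def completeness_proxy(hits: HitTable, taxon: str, controls: list[str]) -> float:
    """Fraction of control families with at least one retained hit in this
    taxon — the data-set completeness stand-in."""
    if not controls:
        raise ValueError("empty control-family set")
    found = sum(
        1 for fam in controls if any(h.taxon == taxon for h in hits.for_family(fam))
    )
    return found / len(controls)


def corroborate_absences(
    matrix: InventoryMatrix,
    roles: TaxonRoleMap,
    min_taxa: int = 3,
    min_completeness: float = 0.5,
) -> InventoryMatrix:
    """Flag absences supported by consistency: a family's absence in a taxon
    group is corroborated when every sufficiently complete taxon of that
    group (and at least ``min_taxa`` of them) lacks the family."""
    by_role: dict[str, list[str]] = {}
    for t in matrix.taxa:
        by_role.setdefault(roles.role(t), []).append(t)
    for fam in matrix.families:
        for group in by_role.values():
            eligible = [
                t for t in group
                if matrix.completeness.get(t, 0.0) >= min_completeness
            ]
            if len(eligible) < min_taxa:
                continue
            if all(matrix.cell(fam, t).copy_count == 0 for t in eligible):
                for t in group:
                    if matrix.cell(fam, t).copy_count == 0:
                        matrix.cell(fam, t).absence_corroborated = True
    return matrix


def subcomplex_summary(
    matrix: InventoryMatrix, registry: FamilyRegistry
) -> dict[str, dict[str, bool]]:
    """Presence of each NPC subcomplex per compartment group.

    Groups: ``host`` (host-related copies in query taxa) and ``nucleomorph``
    (algal-related copies in query taxa — the endosymbiont-derived
    complement).  A subcomplex is present for a group when at least one of
    its families has at least one copy of that affinity in any taxon.
    """
    groups = {"host": "host_related", "nucleomorph": "algal_related"}
    subcomplexes = sorted({registry.subcomplex(f) for f in matrix.families})
    out: dict[str, dict[str, bool]] = {
        g: {s: False for s in subcomplexes} for g in groups
    }
    for (fam, _taxon), cell in matrix.cells.items():
        sub = registry.subcomplex(fam)
        for group, affinity in groups.items():
            if any(c.affinity == affinity for c in cell.copies):
                out[group][sub] = True
    return out
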