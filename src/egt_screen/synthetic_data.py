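"""Ground-truth scenario generator.

Emulates the statistical structure the screen assumes: a species tree with a
query (nucleomorph-bearing) clade, host-side outgroups, an algal
(endosymbiont-side) clade and distant other references; protein families
evolved by a background-frequency jump process; endosymbiotic gene transfer
(EGT) copies taken from the algal crown and deposited, optionally with a
signal-peptide prefix, into every query proteome; plus losses, within-taxon
duplications, paralogous decoy families, and N-terminal truncation of a
fraction of query transcripts.  Every emitted protein carries exactly one
truth-table row, which is the oracle the pipeline is evaluated against.

The generator and the targeting heuristic share one signal-peptide model by
design (Met + two basic residues + 8-10 hydrophobics + A-x-A); passing tests
demonstrates internal consistency of the chain, not predictor realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import (
    AMINO_ACIDS,
    Alignment,
    FamilyRegistry,
    ProteinRecord,
    TaxonRoleMap,
    default_registry,
    write_alignment,
    write_fasta,
    write_registry,
    write_taxon_roles,
)
from .profile_hmm import BACKGROUND
from .trees import Node, PhyloTree

__all__ = [
    "ScenarioConfig",
    "TruthRow",
    "ScenarioBundle",
    "default_species_tree",
    "evolve_family",
    "apply_events",
    "generate_scenario",
]

DEFAULT_FAMILIES = [
    "Nup98", "Rae1", "Sec13", "Seh1", "Nup85", "Nup93",
    "Nup155", "Ndc1", "Nup62", "Nup50", "Tpr", "Gle1",
]

_HYDROPHOBIC = "LVAFI"
_BASIC = "KR"


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe the standard condition: 12 families over 20 taxa
    (6 query, 4 host outgroup, 6 algal, 4 other reference), two EGT families
    (the Nup98/Rae1 analogs) whose algal-derived copies carry signal
    peptides, and no losses, duplications, decoys or truncation unless the
    scenario asks for them.
    """

    seed: int
    families: list[str] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    length_range: tuple[int, int] = (200, 600)
    rate: float = 1.0
    gamma_shape: float | None = None
    egt_families: tuple[str, ...] = ("Nup98", "Rae1")
    sp_on_egt: bool = True
    egt_stem_length: float = 0.15
    loss_events: list[tuple[str, str]] = field(default_factory=list)
    loss_rate: float = 0.0
    duplication_rate: float = 0.0
    duplication_branch_length: float = 0.05
    decoy_paralog_families: dict[str, float] = field(default_factory=dict)
    decoy_root_distance: float = 0.25
    truncation_fraction: float = 0.0
    n_query: int = 6
    n_host_outgroup: int = 4
    n_algal: int = 6
    n_other: int = 4
    species_tree_newick: str | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        unknown = set(self.egt_families) - set(self.families)
        if unknown:
            raise ValueError(f"egt_families not in families: {sorted(unknown)}")
        unknown = set(self.decoy_paralog_families) - set(self.families)
        if unknown:
            raise ValueError(f"decoy families target unknown families: {sorted(unknown)}")
        for fam, tax in self.loss_events:
            if fam not in self.families:
                raise ValueError(f"loss event references unknown family {fam!r}")
        for name, value in (
            ("rate", self.rate), ("loss_rate", self.loss_rate),
            ("duplication_rate", self.duplication_rate),
            ("truncation_fraction", self.truncation_fraction),
        ):
            if value < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 <= self.truncation_fraction <= 1):
            raise ValueError("truncation_fraction must be a fraction")


@dataclass(frozen=True)
class TruthRow:
    protein_id: str
    taxon: str
    family: str
    provenance: str  # host | algal
    has_sp: bool
    is_decoy_paralog: bool
    truncated: bool


@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    roles: TaxonRoleMap
    registry: FamilyRegistry
    proteomes: dict[str, list[ProteinRecord]]
    ref_alignments: dict[str, Alignment]
    truth: list[TruthRow]

    def truth_by_id(self) -> dict[str, TruthRow]:
        return {t.protein_id: t for t in self.truth}

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        (out / "proteomes").mkdir(parents=True, exist_ok=True)
        (out / "alignments").mkdir(parents=True, exist_ok=True)
        for taxon, records in self.proteomes.items():
            write_fasta(records, out / "proteomes" / f"{taxon}.fasta")
        for fam, aln in self.ref_alignments.items():
            write_alignment(aln, out / "alignments" / f"{fam}.fasta")
        write_taxon_roles(self.roles, out / "roles.tsv")
        write_registry(self.registry, out / "registry.tsv")
        with open(out / "truth.tsv", "w") as fh:
            fh.write(
                "protein_id\ttaxon\tfamily\tprovenance\thas_sp\t"
                "is_decoy_paralog\ttruncated\n"
            )
            for t in self.truth:
                fh.write(
                    f"{t.protein_id}\t{t.taxon}\t{t.family}\t{t.provenance}\t"
                    f"{int(t.has_sp)}\t{int(t.is_decoy_paralog)}\t{int(t.truncated)}\n"
                )


# --------------------------------------------------------------------------
# species tree


def default_species_tree(config: ScenarioConfig) -> tuple[PhyloTree, TaxonRoleMap]:
    """Fixed-shape species tree: (((query, host), algal), other).

    The EGT donor lineage departs from a labelled junction node
    (``egtjunction``) on the algal stem, below the crown radiation
    (``algalcrown``): a donor hanging exactly off the crown node would create
    a polytomy that distance trees resolve arbitrarily.  The other-reference
    clade is deep, so the midpoint root falls on its stem — the position the
    distant eukaryote references occupy in real trees.  Pendant lengths vary
    slightly within clades to avoid exact ties."""

    def clade(prefix, n, pendant, internal):
        nodes = [
            Node(name=f"{prefix}{i + 1}", length=pendant + 0.01 * (i % 3))
            for i in range(n)
        ]
        while len(nodes) > 1:
            p = Node(length=internal)
            p.add(nodes.pop(0))
            p.add(nodes.pop(0))
            nodes.append(p)
        return nodes[0]

    query = clade("query", config.n_query, 0.08, 0.04)
    host = clade("host", config.n_host_outgroup, 0.10, 0.05)
    crown = clade("algal", config.n_algal, 0.10, 0.05)
    crown.name = crown.name or "algalcrown"
    other = clade("other", config.n_other, 0.12, 0.06)

    qh = Node(length=0.25)
    query.length += 0.15
    host.length += 0.15
    qh.add(query)
    qh.add(host)
    junction = Node(name="egtjunction", length=0.25)
    crown.length += 0.20
    junction.add(crown)
    ingroup = Node(length=0.15)
    ingroup.add(qh)
    ingroup.add(junction)
    root = Node()
    other.length += 0.45
    root.add(ingroup)
    root.add(other)
    tree = PhyloTree(root, rooted=True)
    # keep total divergences well below distance-correction saturation, where
    # column-sampling noise in corrected distances would swamp backbone edges
    for node in tree.postorder():
        node.length *= 0.75

    entries: dict[str, str] = {}
    for i in range(config.n_query):
        entries[f"query{i + 1}"] = "query_host_lineage"
    for i in range(config.n_host_outgroup):
        entries[f"host{i + 1}"] = "host_outgroup"
    for i in range(config.n_algal):
        entries[f"algal{i + 1}"] = "endosymbiont_algal"
    for i in range(config.n_other):
        entries[f"other{i + 1}"] = "other_reference"
    return tree, TaxonRoleMap(entries)


# --------------------------------------------------------------------------
# sequence evolution


def _sample_excluding(rng, current: np.ndarray) -> np.ndarray:
    """Draw a background residue different from ``current`` for each site."""
    out = rng.choice(20, size=current.shape[0], p=BACKGROUND)
    clash = out == current
    while np.any(clash):
        out[clash] = rng.choice(20, size=int(clash.sum()), p=BACKGROUND)
        clash = out == current
    return out


def _decode(enc: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in enc)


def evolve_family(
    tree: PhyloTree,
    root_length: int,
    rate: float,
    seed,
    gamma_shape: float | None = None,
    fix_initiator: bool = True,
) -> dict[str, np.ndarray]:
    """Evolve one family down a species tree.

    The root sequence is i.i.d. from the background (with a fixed initiator
    methionine when ``fix_initiator``).  Along a branch of length t each site
    substitutes with probability 1 - exp(-rate * t * r_site) and is replaced
    by a background draw excluding the current residue.  Site-rate
    multipliers r_site are Gamma(shape, 1/shape) when ``gamma_shape`` is set,
    else 1.  Returns encoded sequences for every *named* node (leaves and
    labelled internal nodes).
    """
    if root_length < 1:
        raise ValueError("root_length must be positive")
    rng = np.random.default_rng(seed)
    root_seq = rng.choice(20, size=root_length, p=BACKGROUND)
    if fix_initiator:
        root_seq[0] = AMINO_ACIDS.index("M")
    if gamma_shape is not None:
        site_rates = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=root_length)
    else:
        site_rates = np.ones(root_length)

    out: dict[str, np.ndarray] = {"__root__": root_seq}

    def descend(node: Node, seq: np.ndarray):
        if node.parent is not None:
            p_sub = 1.0 - np.exp(-rate * node.length * site_rates)
            sub = rng.random(root_length) < p_sub
            if fix_initiator:
                sub[0] = False
            if np.any(sub):
                seq = seq.copy()
                seq[sub] = _sample_excluding(rng, seq[sub])
        if node.name:
            out[node.name] = seq
        for child in node.children:
            descend(child, seq)

    descend(tree.root, root_seq)
    return out


def _sp_prefix(rng) -> str:
    run = int(rng.integers(8, 11))
    return (
        "M"
        + "".join(rng.choice(list(_BASIC), size=2))
        + "".join(rng.choice(list(_HYDROPHOBIC), size=run))
        + "A"
        + AMINO_ACIDS[rng.choice(20, p=BACKGROUND)]
        + "A"
    )


def _evolve_from(rng, seq: np.ndarray, rate: float, t: float,
                 fix_initiator: bool = True) -> np.ndarray:
    p = 1.0 - np.exp(-rate * t)
    sub = rng.random(seq.shape[0]) < p
    if fix_initiator:
        sub[0] = False
    seq = seq.copy()
    if np.any(sub):
        seq[sub] = _sample_excluding(rng, seq[sub])
    return seq


# --------------------------------------------------------------------------
# events and assembly


def _mrca_subtree(tree: PhyloTree, leaf_names: set[str]) -> Node:
    """Copy of the minimal subtree of ``tree`` spanning ``leaf_names``."""
    def rec(node: Node) -> Node | None:
        if node.is_leaf():
            if node.name in leaf_names:
                return Node(name=node.name, length=node.length)
            return None
        kept = [c for c in (rec(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            return kept[0]
        out = Node(length=node.length)
        for c in kept:
            out.add(c)
        return out

    sub = rec(tree.root)
    if sub is None:
        raise ValueError("no requested leaves found in the tree")
    return sub


def apply_events(
    family: str,
    node_seqs: dict[str, np.ndarray],
    config: ScenarioConfig,
    roles: TaxonRoleMap,
    rng,
    species_tree: PhyloTree | None = None,
    is_decoy: bool = False,
) -> tuple[dict[str, list[tuple[str, str, str, bool, bool]]], list[TruthRow]]:
    """Turn evolved node sequences into per-taxon gene copies for one family.

    EGT is modelled as a single transfer on the stem of the query clade: the
    donor lineage leaves the algal crown (branch ``egt_stem_length``), and
    the transferred gene is then inherited vertically, co-diverging along the
    query subtree of the species tree.  Returns (genes, truth): genes maps
    taxon -> list of (protein_id, sequence, nterm_flag, has_sp, truncated)
    tuples.
    """
    query_taxa = roles.taxa_with_role("query_host_lineage")
    lost = {
        (f, t) for f, t in config.loss_events
    } | {
        (family, t)
        for t in query_taxa
        if config.loss_rate > 0 and rng.random() < config.loss_rate
    }
    genes: dict[str, list] = {t: [] for t in roles.entries}
    truth: list[TruthRow] = []

    def emit(taxon, tag, enc, provenance, has_sp, truncated, nterm):
        pid = f"{taxon}_{family}_{tag}"
        seq = _decode(enc)
        if has_sp:
            seq = _sp_prefix(rng) + seq
        genes[taxon].append((pid, seq, nterm, has_sp, truncated))
        truth.append(TruthRow(pid, taxon, family, provenance, has_sp,
                              is_decoy, truncated))

    for taxon in roles.entries:
        if (family, taxon) in lost:
            continue
        enc = node_seqs[taxon]
        truncated = (
            roles.role(taxon) == "query_host_lineage"
            and rng.random() < config.truncation_fraction
        )
        if truncated:
            cut = int(rng.uniform(0.1, 0.5) * enc.shape[0])
            emit(taxon, "h1", enc[cut:], "host", False, True, "incomplete")
        else:
            emit(taxon, "h1", enc, "host", False, False, "unknown")
        if (
            roles.role(taxon) == "query_host_lineage"
            and config.duplication_rate > 0
            and rng.random() < config.duplication_rate
        ):
            dup = _evolve_from(rng, enc, config.rate,
                               config.duplication_branch_length)
            emit(taxon, "d1", dup, "host", False, False, "unknown")

    if family in config.egt_families and not is_decoy:
        if species_tree is None:
            raise ValueError("EGT events need the species tree")
        anchor = node_seqs.get("egtjunction", node_seqs.get("algalcrown"))
        donor = _evolve_from(rng, anchor, config.rate, config.egt_stem_length)
        subtree = _mrca_subtree(species_tree, set(query_taxa))

        def descend(node: Node, seq: np.ndarray):
            if node.parent is not None:
                seq = _evolve_from(rng, seq, config.rate, node.length)
            if node.is_leaf():
                if (family, node.name) not in lost:
                    emit(node.name, "nm1", seq, "algal", config.sp_on_egt,
                         False, "unknown")
            for ch in node.children:
                descend(ch, seq)

        subtree.length = 0.0  # the stem is already accounted for
        descend(subtree, donor)
    return genes, truth


def generate_scenario(config: ScenarioConfig, out_dir=None) -> ScenarioBundle:
    """Produce a complete, pipeline-consumable bundle.

    Reference alignments are exact by construction (the evolutionary process
    introduces no indels, so the reference rows of a family are already
    columnwise homologous); query-side features — EGT signal-peptide
    prefixes and truncations — appear only in proteomes, never in the
    reference alignments.
    """
    config.validate()
    tree, roles = (
        default_species_tree(config)
        if config.species_tree_newick is None
        else _tree_from_newick(config)
    )
    base_registry = default_registry()
    reg_entries: dict[str, tuple[str, str, str]] = {}
    for fam in config.families:
        if fam in base_registry.entries:
            reg_entries[fam] = base_registry.entries[fam]
        else:
            reg_entries[fam] = (fam, "inner ring", "synthetic family")
    decoy_names: dict[str, str] = {}
    for fam in config.decoy_paralog_families:
        dname = f"{fam}-like"
        decoy_names[fam] = dname
        sub = reg_entries[fam][1]
        reg_entries[dname] = (dname, sub, "synthetic paralog decoy")
    registry = FamilyRegistry(reg_entries)

    master = np.random.default_rng(config.seed)
    proteomes: dict[str, list[ProteinRecord]] = {t: [] for t in roles.entries}
    ref_alignments: dict[str, Alignment] = {}
    truth: list[TruthRow] = []
    ref_taxa = [t for t, r in roles.entries.items() if r != "query_host_lineage"]

    for fam_index, fam in enumerate(config.families):
        fam_seed = np.random.SeedSequence([config.seed, fam_index])
        rng = np.random.default_rng(fam_seed)
        length = int(rng.integers(config.length_range[0],
                                  config.length_range[1] + 1))
        node_seqs = evolve_family(
            tree, length, config.rate, np.random.default_rng(fam_seed.spawn(1)[0]),
            gamma_shape=config.gamma_shape,
        )
        variants = [(fam, node_seqs, False)]
        if fam in config.decoy_paralog_families:
            mult = config.decoy_paralog_families[fam]
            decoy_root_rng = np.random.default_rng(fam_seed.spawn(2)[1])
            # re-evolve the whole tree from a diverged paralog root
            decoy_tree_seqs = _evolve_tree_from_offset(
                tree, node_seqs, config.rate,
                config.decoy_root_distance * mult, decoy_root_rng,
            )
            variants.append((decoy_names[fam], decoy_tree_seqs, True))
        for name, seqs, is_decoy in variants:
            genes, fam_truth = apply_events(name, seqs, config, roles, rng,
                                            species_tree=tree,
                                            is_decoy=is_decoy)
            truth.extend(fam_truth)
            for taxon, entries in genes.items():
                for pid, seq, nterm, _, _ in entries:
                    proteomes[taxon].append(
                        ProteinRecord(pid, taxon, seq, nterm)
                    )
            rows = []
            for taxon in sorted(ref_taxa):
                for pid, seq, nterm, _, _ in genes[taxon]:
                    rows.append((ProteinRecord(pid, taxon, seq, nterm), seq))
            ref_alignments[name] = Alignment(name, rows)

    bundle = ScenarioBundle(config, roles, registry, proteomes,
                            ref_alignments, truth)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _evolve_tree_from_offset(tree, node_seqs, rate, offset, rng):
    """Decoy families: shift the family root by ``offset`` expected
    substitutions per site, then re-evolve every branch."""
    length = next(iter(node_seqs.values())).shape[0]

    def descend(node, seq, out):
        if node.parent is not None:
            seq = _evolve_from(rng, seq, rate, node.length)
        if node.name:
            out[node.name] = seq
        for ch in node.children:
            descend(ch, seq, out)

    anchor = node_seqs["__root__"]
    paralog_root = _evolve_from(rng, anchor, rate, offset)
    out: dict[str, np.ndarray] = {}
    descend(tree.root, paralog_root, out)
    return out


def _tree_from_newick(config: ScenarioConfig):
    from .trees import read_newick

    tree = read_newick(config.species_tree_newick)
    entries = {}
    # roles are inferred from leaf-name prefixes for user-supplied trees
    for leaf in tree.leaves():
        for prefix, role in (
            ("query", "query_host_lineage"), ("host", "host_outgroup"),
            ("algal", "endosymbiont_algal"), ("other", "other_reference"),
        ):
            if leaf.name.startswith(prefix):
                entries[leaf.name] = role
                break
        else:
            raise ValueError(
                f"cannot infer a role for leaf {leaf.name!r}; use the "
                "query/host/algal/other naming convention"
            )
    return tree, TaxonRoleMap(entries)
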