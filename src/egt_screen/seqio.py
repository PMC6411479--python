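"""Readers, writers and validation for the external formats of the pipeline.

Formats: FASTA proteomes, aligned FASTA reference families, Newick trees,
and TSV tables (taxon roles, family registry).  Header metadata uses
space-separated ``key=value`` tokens after the sequence id, which lets a FASTA
file carry the N-terminus completeness call of the upstream ORF predictor
without a side table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .trees import read_newick, write_newick  # noqa: F401  (re-export)

__all__ = [
    "ProteinRecord",
    "Alignment",
    "TaxonRoleMap",
    "FamilyRegistry",
    "ROLES",
    "SUBCOMPLEXES",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_taxon_roles",
    "write_taxon_roles",
    "read_registry",
    "write_registry",
    "default_registry",
    "read_newick",
    "write_newick",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
NTERM_FLAGS = ("complete", "incomplete", "unknown")
ROLES = ("query_host_lineage", "host_outgroup", "endosymbiont_algal", "other_reference")
SUBCOMPLEXES = (
    "cytoplasmic complex",
    "outer ring",
    "inner ring",
    "transmembrane ring",
    "central channel",
    "nuclear basket",
)


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein: id, source taxon, residues, and the upstream
    ORF-caller's N-terminus completeness flag (unknown when absent)."""

    id: str
    taxon: str
    sequence: str
    nterm_flag: str = "unknown"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.nterm_flag not in NTERM_FLAGS:
            raise ValueError(
                f"record {self.id!r}: nterm_flag {self.nterm_flag!r} "
                f"not one of {NTERM_FLAGS}"
            )
        bad = [
            (i, c) for i, c in enumerate(self.sequence) if c not in VALID_RESIDUES
        ]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"record {self.id!r}: invalid residue {c!r} at position {i}"
            )

    def __len__(self):
        return len(self.sequence)


@dataclass
class Alignment:
    """A gapped protein family alignment: ordered (record, gapped row) pairs
    with a rectangular column structure."""

    family: str
    rows: list[tuple[ProteinRecord, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.rows:
            n = len(self.rows[0][1])
            for rec, gapped in self.rows:
                if len(gapped) != n:
                    raise ValueError(
                        f"alignment {self.family!r}: ragged row {rec.id!r} "
                        f"(length {len(gapped)}, expected {n})"
                    )
                if gapped.replace("-", "") != rec.sequence:
                    raise ValueError(
                        f"alignment {self.family!r}: row {rec.id!r} does not "
                        "degap to its record sequence"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ids(self) -> list[str]:
        return [rec.id for rec, _ in self.rows]

    def row(self, rec_id: str) -> tuple[ProteinRecord, str]:
        for rec, gapped in self.rows:
            if rec.id == rec_id:
                return rec, gapped
        raise KeyError(f"no row {rec_id!r} in alignment {self.family!r}")

    def drop(self, rec_ids) -> "Alignment":
        drop = set(rec_ids)
        return Alignment(
            self.family, [(r, g) for r, g in self.rows if r.id not in drop]
        )


@dataclass
class TaxonRoleMap:
    """taxon -> role over the closed vocabulary in ``ROLES``."""

    entries: dict[str, str]

    def __post_init__(self):
        for taxon, role in self.entries.items():
            if role not in ROLES:
                raise ValueError(
                    f"taxon {taxon!r}: unknown role {role!r}; allowed: {ROLES}"
                )

    def role(self, taxon: str) -> str:
        if taxon not in self.entries:
            raise KeyError(f"taxon {taxon!r} has no assigned role")
        return self.entries[taxon]

    def taxa_with_role(self, role: str) -> list[str]:
        return sorted(t for t, r in self.entries.items() if r == role)


@dataclass
class FamilyRegistry:
    """family -> (display name, NPC subcomplex, free-text notes)."""

    entries: dict[str, tuple[str, str, str]]

    def __post_init__(self):
        for fam, (_, sub, _) in self.entries.items():
            if sub not in SUBCOMPLEXES:
                raise ValueError(
                    f"family {fam!r}: unknown subcomplex {sub!r}; "
                    f"allowed: {SUBCOMPLEXES}"
                )

    def families(self) -> list[str]:
        return list(self.entries)

    def subcomplex(self, family: str) -> str:
        return self.entries[family][1]


# --------------------------------------------------------------------------
# FASTA


def _parse_header(description: str) -> tuple[str, dict[str, str]]:
    tokens = description.split()
    rec_id = tokens[0]
    meta = {}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            meta[key] = value
    return rec_id, meta


def read_fasta(path, taxon: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA into records.

    The token before the first whitespace becomes the id; an optional
    ``nterm=complete|incomplete`` header tag populates the completeness flag;
    trailing '*' stop symbols are stripped; lowercase is uppercased.  The
    taxon defaults to the file stem.
    """
    path = Path(path)
    taxon = taxon if taxon is not None else path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id, meta = _parse_header(entry.description)
        if rec_id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        seq = str(entry.seq).upper().rstrip("*")
        nterm = meta.get("nterm", "unknown")
        if nterm not in NTERM_FLAGS:
            raise ValueError(
                f"{path}: record {rec_id!r}: bad nterm tag {nterm!r}"
            )
        try:
            records.append(ProteinRecord(rec_id, taxon, seq, nterm))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            tag = f" nterm={rec.nterm_flag}" if rec.nterm_flag != "unknown" else ""
            fh.write(f">{rec.id}{tag}\n{rec.sequence}\n")


def read_alignment(path, family: str, taxa: dict[str, str] | None = None) -> Alignment:
    """Read an aligned FASTA.  ``taxa`` optionally maps row id -> taxon;
    otherwise a ``taxon=...`` header tag or the file stem is used."""
    path = Path(path)
    rows = []
    seen: set[str] = set()
    lengths: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id, meta = _parse_header(entry.description)
        if rec_id in seen:
            raise ValueError(f"{path}: duplicate row id {rec_id!r}")
        seen.add(rec_id)
        gapped = str(entry.seq).upper().rstrip("*")
        lengths[rec_id] = len(gapped)
        taxon = (taxa or {}).get(rec_id) or meta.get("taxon", path.stem)
        nterm = meta.get("nterm", "unknown")
        rec = ProteinRecord(rec_id, taxon, gapped.replace("-", ""), nterm)
        rows.append((rec, gapped))
    if not rows:
        raise ValueError(f"{path}: no alignment rows found")
    if len(set(lengths.values())) > 1:
        detail = ", ".join(f"{k}={v}" for k, v in sorted(lengths.items()))
        raise ValueError(f"{path}: ragged alignment rows ({detail})")
    return Alignment(family, rows)


def write_alignment(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rec, gapped in alignment.rows:
            tag = f" taxon={rec.taxon}"
            if rec.nterm_flag != "unknown":
                tag += f" nterm={rec.nterm_flag}"
            fh.write(f">{rec.id}{tag}\n{gapped}\n")


# --------------------------------------------------------------------------
# TSV tables


def read_taxon_roles(path) -> TaxonRoleMap:
    entries: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "taxon" not in reader.fieldnames:
            raise ValueError(f"{path}: expected TSV with 'taxon' and 'role' columns")
        for line in reader:
            taxon, role = line["taxon"], line["role"]
            if taxon in entries:
                raise ValueError(f"{path}: taxon {taxon!r} listed twice")
            if role not in ROLES:
                raise ValueError(
                    f"{path}: taxon {taxon!r}: unknown role {role!r}; "
                    f"allowed roles: {', '.join(ROLES)}"
                )
            entries[taxon] = role
    return TaxonRoleMap(entries)


def write_taxon_roles(roles: TaxonRoleMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\trole\n")
        for taxon, role in roles.entries.items():
            fh.write(f"{taxon}\t{role}\n")


def read_registry(path) -> FamilyRegistry:
    entries: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "family" not in reader.fieldnames:
            raise ValueError(
                f"{path}: expected TSV with family/display/subcomplex columns"
            )
        for line in reader:
            fam = line["family"]
            if fam in entries:
                raise ValueError(f"{path}: family {fam!r} listed twice")
            entries[fam] = (
                line.get("display", fam) or fam,
                line["subcomplex"],
                line.get("notes", "") or "",
            )
    return FamilyRegistry(entries)


def write_registry(registry: FamilyRegistry, path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tdisplay\tsubcomplex\tnotes\n")
        for fam, (display, sub, notes) in registry.entries.items():
            fh.write(f"{fam}\t{display}\t{sub}\t{notes}\n")


# The 32 canonical nucleoporin families, grouped by NPC subcomplex.  Merged
# entries (Nup120-160, Nup192-205) follow common usage where orthology between
# the fungal and animal names is uncertain.  Nup98 sits in the central channel
# here but contacts several substructures; the note records that.
_DEFAULT_REGISTRY: list[tuple[str, str, str]] = [
    ("Nup42", "cytoplasmic complex", ""),
    ("Nup88", "cytoplasmic complex", ""),
    ("Nup214", "cytoplasmic complex", ""),
    ("Gle1", "cytoplasmic complex", ""),
    ("Rae1", "cytoplasmic complex", "mobile; also nucleoplasmic mRNA export"),
    ("Nup85", "outer ring", ""),
    ("Nup96", "outer ring", ""),
    ("Nup107", "outer ring", ""),
    ("Nup120-160", "outer ring", "merged fungal/animal entry"),
    ("Nup133", "outer ring", ""),
    ("Sec13", "outer ring", "shared with COPII coat"),
    ("Seh1", "outer ring", ""),
    ("Nup37", "outer ring", "animal-specific"),
    ("Nup43", "outer ring", "animal-specific"),
    ("Aladin", "outer ring", ""),
    ("Nup35", "inner ring", ""),
    ("Nup93", "inner ring", ""),
    ("Nup155", "inner ring", ""),
    ("Nup188", "inner ring", ""),
    ("Nup192-205", "inner ring", "merged fungal/animal entry"),
    ("Ndc1", "transmembrane ring", ""),
    ("Gp210", "transmembrane ring", ""),
    ("Pom152", "transmembrane ring", "fungal; also reported in cryptophytes"),
    ("Pom121", "transmembrane ring", "animal-specific"),
    ("Pom34", "transmembrane ring", "fungal-specific"),
    ("Nup54", "central channel", ""),
    ("Nup58", "central channel", ""),
    ("Nup62", "central channel", ""),
    ("Nup98", "central channel", "multi-location; FG-repeat bearing"),
    ("Nup50", "nuclear basket", ""),
    ("Nup153", "nuclear basket", ""),
    ("Tpr", "nuclear basket", ""),
]


def default_registry() -> FamilyRegistry:
    """The shipped registry of 32 canonical nucleoporin families."""
    return FamilyRegistry({f: (f, s, n) for f, s, n in _DEFAULT_REGISTRY})
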