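"""Proteome screening with family profiles and hit triage.

The screen scores every (profile, protein) pair with local Viterbi, converts
scores to E-values under each profile's Gumbel calibration, and keeps hits at
or below the E-value threshold (default 1e-5).  Per family, only the best
``top_n`` hits (default 200) survive triage.  Family assignment — the
discriminative stand-in for annotating hits against a curated database — is
the profile with the highest forward bit score, together with the bit margin
to the runner-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .profile_hmm import (
    ProfileHMM,
    evalue,
    forward_score,
    profile_path,
    viterbi_bits,
    viterbi_score,
    _merge_rows,
)
from .seqio import Alignment, ProteinRecord

__all__ = [
    "SearchHit",
    "HitTable",
    "search_proteomes",
    "triage_top_n",
    "assign_family",
    "augment_family_alignment",
]


@dataclass(frozen=True)
class SearchHit:
    family: str
    protein_id: str
    taxon: str
    bits: float
    e_value: float
    start: int  # 0-based half-open aligned interval on the protein
    end: int
    assigned_family: str | None = None
    margin: float | None = None

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("E-value must be nonnegative")
        if not (0 <= self.start <= self.end):
            raise ValueError("bad aligned interval")


@dataclass
class HitTable:
    hits: list[SearchHit] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for h in self.hits:
            key = (h.family, h.protein_id)
            if key in seen:
                raise ValueError(f"duplicate hit for {key}")
            seen.add(key)
        self.hits.sort(key=_hit_order)

    def __len__(self):
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def for_family(self, family: str) -> list[SearchHit]:
        return [h for h in self.hits if h.family == family]

    def families(self) -> list[str]:
        return sorted({h.family for h in self.hits})


def _hit_order(h: SearchHit):
    return (h.family, h.e_value, -h.bits, h.protein_id)


def search_proteomes(
    profiles,
    proteomes,
    e_threshold: float = 1e-5,
    database_size: int | None = None,
) -> HitTable:
    """Score every profile against every protein; retain hits with
    E <= ``e_threshold``.

    ``proteomes`` is an iterable of ProteinRecord collections (one per taxon).
    ``database_size`` defaults to the total number of proteins scored, the
    per-sequence E-value convention.
    """
    records: list[ProteinRecord] = []
    for proteome in proteomes:
        proteome = list(proteome)
        if not proteome:
            warnings.warn("empty proteome supplied; it contributes no hits",
                          stacklevel=2)
        records.extend(proteome)
    db = database_size if database_size is not None else max(len(records), 1)
    hits: list[SearchHit] = []
    for profile in profiles:
        if profile.calibration is None:
            raise ValueError(
                f"profile {profile.family!r} must be calibrated before search"
            )
        for rec in records:
            bits = viterbi_bits(profile, rec.sequence, mode="local")
            if not np.isfinite(bits):
                continue
            e = evalue(profile, bits, db)
            if e <= e_threshold:
                _, _, (start, end) = viterbi_score(
                    profile, rec.sequence, mode="local"
                )
                hits.append(SearchHit(
                    family=profile.family,
                    protein_id=rec.id,
                    taxon=rec.taxon,
                    bits=float(bits),
                    e_value=float(e),
                    start=start,
                    end=end,
                ))
    return HitTable(hits)


def triage_top_n(
    hits: HitTable,
    family: str | None = None,
    top_n: int = 200,
    per_taxon: bool = False,
) -> HitTable:
    """Keep the best ``top_n`` hits per family (pooled across taxa by
    default, or per taxon with ``per_taxon``).  Ordering: ascending E-value,
    then descending bit score, then protein id."""
    kept: list[SearchHit] = []
    fams = [family] if family is not None else hits.families()
    untouched = [h for h in hits if family is not None and h.family != family]
    for fam in fams:
        fam_hits = sorted(hits.for_family(fam), key=_hit_order)
        if per_taxon:
            count: dict[str, int] = {}
            for h in fam_hits:
                count[h.taxon] = count.get(h.taxon, 0) + 1
                if count[h.taxon] <= top_n:
                    kept.append(h)
        else:
            kept.extend(fam_hits[:top_n])
    return HitTable(kept + untouched)


def assign_family(
    protein: ProteinRecord,
    profiles,
    shortlist: int | None = None,
) -> tuple[str | None, float]:
    """Best-profile family assignment by forward bit score.

    Returns (family, margin_in_bits); margin is the gap to the runner-up
    (infinite with a single profile, 0 for exact ties broken by family name).
    ``shortlist`` optionally restricts the forward computation to the top-k
    profiles ranked by the cheaper Viterbi score; inter-family score gaps are
    large enough in practice that the shortlist does not change the answer.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles supplied")
    if shortlist is not None and len(profiles) > shortlist:
        ranked = sorted(
            profiles,
            key=lambda p: (-viterbi_bits(p, protein.sequence, "local"), p.family),
        )
        profiles = ranked[:shortlist]
    scored = sorted(
        ((forward_score(p, protein.sequence, mode="local"), p.family)
         for p in profiles),
        key=lambda x: (-x[0], x[1]),
    )
    best_score, best_fam = scored[0]
    if not np.isfinite(best_score):
        return None, 0.0
    if len(scored) == 1:
        return best_fam, float("inf")
    return best_fam, float(best_score - scored[1][0])


def augment_family_alignment(
    alignment: Alignment,
    records,
    profile: ProfileHMM,
) -> Alignment:
    """Insert retained hit sequences into the family reference alignment via
    profile alignment.  Rows whose id collides with an existing row are
    suffixed with their taxon (with a warning)."""
    existing = set(alignment.ids())
    placed = []
    for rec in records:
        if rec.id in existing:
            new_id = f"{rec.id}__{rec.taxon}"
            warnings.warn(
                f"row id {rec.id!r} already present; renamed to {new_id!r}",
                stacklevel=2,
            )
            rec = ProteinRecord(new_id, rec.taxon, rec.sequence, rec.nterm_flag)
        existing.add(rec.id)
        match_row, inserts = profile_path(profile, rec.sequence)
        placed.append((rec, match_row, inserts))
    if not placed:
        return alignment
    return _merge_rows(profile, alignment, placed)
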