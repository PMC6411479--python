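"""Targeting evidence: signal peptides, N-terminus completeness, FG repeats.

Nucleomorph-targeted proteins carry a bipartite presequence whose first half
is a classical secretory signal peptide, so SP presence on an algal-related
copy is the targeting evidence of interest.  The predictor here is a
transparent three-rule heuristic over the first 40 residues (positive
n-region charge, a hydrophobic core window, and a small-residue cleavage
motif); it is deliberately simple, config-exposed, and NOT equivalent to a
neural-network predictor — an import path accepts externally computed
predictions.  Because truncated protein models produce unreliable SP calls in
both directions, the evidence layer refuses to emit an SP verdict for records
without a complete N-terminus.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, replace

from .seqio import Alignment, ProteinRecord

__all__ = [
    "TargetingEvidence",
    "SignalPeptideCall",
    "KYTE_DOOLITTLE",
    "check_nterm_complete",
    "predict_signal_peptide",
    "import_sp_predictions",
    "scan_fg_repeats",
    "evaluate_targeting",
]

KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
    "X": 0.0,
}

_SMALL = frozenset("AGSCT")  # cleavage-site (-1, -3) alphabet


@dataclass(frozen=True)
class SignalPeptideCall:
    predicted: bool | None  # None = inconclusive (sequence too short)
    score: float
    cleavage_pos: int | None  # 0-based index of the first mature residue
    source: str = "heuristic"


@dataclass(frozen=True)
class TargetingEvidence:
    protein_id: str
    sp_predicted: bool | None  # None when unevaluable (incomplete N-terminus)
    sp_score: float | None
    sp_cleavage_pos: int | None
    nterm_complete: bool
    nterm_basis: str  # metadata | aligned_methionine | unknown
    fg_count: int
    fg_density_per_100: float
    fg_flag: bool
    fxfg_count: int = 0
    glfg_count: int = 0


def check_nterm_complete(
    record: ProteinRecord,
    alignment: Alignment,
    tolerance_cols: int = 15,
) -> tuple[bool, str]:
    """Is the protein model's N-terminus complete?

    Upstream ORF-caller metadata wins when present.  Otherwise the aligned-
    methionine rule applies: the sequence must start with M and its first
    residue must sit no more than ``tolerance_cols`` columns after the modal
    start column of the reference rows.
    """
    if record.nterm_flag in ("complete", "incomplete"):
        return record.nterm_flag == "complete", "metadata"
    ids = alignment.ids()
    if record.id not in ids:
        raise KeyError(
            f"record {record.id!r} is not a row of alignment {alignment.family!r}"
        )
    starts = []
    my_start = None
    for rec, gapped in alignment.rows:
        first = next((c for c, ch in enumerate(gapped) if ch != "-"), None)
        if rec.id == record.id:
            my_start = first
        else:
            starts.append(first)
    if not starts or my_start is None:
        return False, "unknown"
    modal_start = Counter(starts).most_common(1)[0][0]
    complete = (
        record.sequence.startswith("M")
        and my_start <= modal_start + tolerance_cols
    )
    return complete, "aligned_methionine"


def predict_signal_peptide(
    seq: str,
    min_length: int = 25,
    n_region: tuple[int, int] = (1, 6),
    core_span: tuple[int, int] = (3, 21),
    core_window: int = 8,
    core_hydropathy: float = 2.0,
    cleavage_range: tuple[int, int] = (14, 34),
) -> SignalPeptideCall:
    """Three-rule signal peptide heuristic on the N-terminal 40 residues.

    Positive iff (a) the n-region (residues 1..5, 0-based) has nonnegative
    net charge (K/R = +1, D/E = -1); (b) some ``core_window`` of consecutive
    residues inside ``core_span`` has mean Kyte-Doolittle hydropathy >=
    ``core_hydropathy``; and (c) a cleavage motif exists: for some signal
    length l in ``cleavage_range``, residues l-1 and l-3 are small
    (A/G/S/C/T).  The score is the best core-window hydropathy; the reported
    cleavage position is the smallest qualifying l (index of the first mature
    residue).  Sequences shorter than ``min_length`` are inconclusive.
    """
    if len(seq) < min_length:
        return SignalPeptideCall(None, 0.0, None)
    head = seq[:40]
    charge = sum(
        (1 if c in "KR" else -1 if c in "DE" else 0)
        for c in head[n_region[0]:n_region[1]]
    )
    lo, hi = core_span
    best = -float("inf")
    for start in range(lo, hi - core_window + 1):
        window = head[start:start + core_window]
        if len(window) < core_window:
            break
        mean = sum(KYTE_DOOLITTLE.get(c, 0.0) for c in window) / core_window
        best = max(best, mean)
    cleavage = None
    for l in range(cleavage_range[0], cleavage_range[1]):
        if l - 1 >= len(seq):
            break
        if seq[l - 1] in _SMALL and seq[l - 3] in _SMALL:
            cleavage = l
            break
    positive = charge >= 0 and best >= core_hydropathy and cleavage is not None
    return SignalPeptideCall(bool(positive), float(best), cleavage)


def import_sp_predictions(path, evidence: dict[str, TargetingEvidence]) -> dict[str, TargetingEvidence]:
    """Override heuristic SP fields from an external predictor's TSV
    (columns: protein, sp_flag, score, cleavage).  Unknown proteins are
    skipped with a warning; duplicate rows: last one wins, with a warning."""
    out = dict(evidence)
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pid = row["protein"]
            if pid not in out:
                warnings.warn(f"SP import: unknown protein {pid!r} skipped",
                              stacklevel=2)
                continue
            if pid in seen:
                warnings.warn(
                    f"SP import: duplicate rows for {pid!r}; last row wins",
                    stacklevel=2,
                )
            seen.add(pid)
            flag = row["sp_flag"].strip().lower() in ("1", "true", "yes", "y")
            cleav = row.get("cleavage", "")
            ev = out[pid]
            # imported verdicts still respect the incomplete-N-terminus refusal
            if ev.nterm_complete:
                out[pid] = replace(
                    ev,
                    sp_predicted=flag,
                    sp_score=float(row.get("score") or 0.0),
                    sp_cleavage_pos=int(cleav) if cleav not in ("", "NA") else None,
                )
    return out


def scan_fg_repeats(
    seq: str,
    window: int = 200,
    min_count: int = 5,
    min_density: float = 1.5,
) -> tuple[int, float, bool, int, int]:
    """FG-dipeptide scan characteristic of central-channel nucleoporins.

    Counts FG dimer starts in the best window of length min(window, len);
    density is per 100 residues of that window.  The flag requires both
    ``min_count`` occurrences and ``min_density``.  FXFG and GLFG motif
    counts over the whole sequence are reported separately.
    Returns (count, density_per_100, flag, fxfg, glfg).
    """
    if not seq:
        raise ValueError("empty sequence")
    positions = [i for i in range(len(seq) - 1) if seq[i] == "F" and seq[i + 1] == "G"]
    wlen = min(window, len(seq))
    best = 0
    j = 0
    for i in range(len(positions)):
        while positions[i] - positions[j] >= wlen:
            j += 1
        best = max(best, i - j + 1)
    density = 100.0 * best / wlen
    flag = best >= min_count and density >= min_density
    fxfg = sum(
        1 for i in range(len(seq) - 3)
        if seq[i] == "F" and seq[i + 2] == "F" and seq[i + 3] == "G"
    )
    glfg = seq.count("GLFG")
    return best, density, flag, fxfg, glfg


def evaluate_targeting(
    record: ProteinRecord,
    alignment: Alignment,
    tolerance_cols: int = 15,
    fg_window: int = 200,
    fg_min_count: int = 5,
    fg_min_density: float = 1.5,
) -> TargetingEvidence:
    """Full evidence row for one protein.  The SP verdict is withheld
    (None) when the N-terminus is not complete."""
    complete, basis = check_nterm_complete(record, alignment, tolerance_cols)
    if complete:
        sp = predict_signal_peptide(record.sequence)
        sp_pred, sp_score, sp_cleav = sp.predicted, sp.score, sp.cleavage_pos
    else:
        sp_pred, sp_score, sp_cleav = None, None, None
    count, density, flag, fxfg, glfg = scan_fg_repeats(
        record.sequence, fg_window, fg_min_count, fg_min_density
    )
    return TargetingEvidence(
        protein_id=record.id,
        sp_predicted=sp_pred,
        sp_score=sp_score,
        sp_cleavage_pos=sp_cleav,
        nterm_complete=complete,
        nterm_basis=basis,
        fg_count=count,
        fg_density_per_100=density,
        fg_flag=flag,
        fxfg_count=fxfg,
        glfg_count=glfg,
    )
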