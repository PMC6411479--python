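"""End-to-end orchestration: profiles -> search -> purge/classify ->
targeting -> inventory.

The pipeline is deterministic given its master seed: every stochastic stage
(profile calibration, bootstrap) draws a stage seed derived from the master
seed and a stage label, so toggling one stage never perturbs another.
Outputs are TSVs with a provenance header comment (tool version, config
hash, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .homology_search import (
    HitTable,
    SearchHit,
    augment_family_alignment,
    search_proteomes,
    triage_top_n,
)
from .inventory import (
    InventoryMatrix,
    build_matrix,
    completeness_proxy,
    control_families,
    corroborate_absences,
    subcomplex_summary,
)
from .phylo import midpoint_root
from .profile_hmm import ProfileHMM, build_profile, calibrate, forward_score
from .provenance import (
    AffinityCall,
    PurgeReport,
    accept_orthologs,
    annotate_leaves,
    classify_affinity,
    purge_paralogs,
)
from .seqio import (
    Alignment,
    FamilyRegistry,
    ProteinRecord,
    TaxonRoleMap,
    read_alignment,
    read_fasta,
    read_registry,
    read_taxon_roles,
)
from .targeting import TargetingEvidence, evaluate_targeting, import_sp_predictions
from .trees import read_newick

__all__ = ["RunConfig", "ScreenResult", "derive_seed", "load_bundle",
           "run_screen", "run_all"]


def derive_seed(master: int, *labels) -> int:
    """Stable per-stage seed fan-out (below 2**31)."""
    digest = hashlib.blake2b(
        repr((int(master),) + tuple(labels)).encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    bundle_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0
    e_threshold: float = 1e-5
    top_n: int = 200
    per_taxon_cap: bool = False
    support_threshold: int = 70
    purity: float = 0.8
    max_cycles: int = 3
    bootstrap_reps: int = 100
    margin_min: float = 2.0
    occupancy_threshold: float = 0.5
    pseudocount_weight: float = 1.0
    calibration_decoys: int = 200
    external_trees_dir: str | None = None
    external_sp_tsv: str | None = None

    def validate(self) -> None:
        if not (0 < self.e_threshold):
            raise ValueError("e_threshold must be positive")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (0 <= self.support_threshold <= 100):
            raise ValueError("support_threshold must be in [0, 100]")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Hash of the scientific parameters (paths excluded, so the same
        analysis in a different directory stamps identical outputs)."""
        data = dataclasses.asdict(self)
        for key in ("bundle_dir", "out_dir"):
            data.pop(key, None)
        return hashlib.blake2b(
            json.dumps(data, sort_keys=True).encode(), digest_size=6,
        ).hexdigest()


@dataclass
class FamilyResult:
    family: str
    clean_alignment: Alignment
    purge_report: PurgeReport
    retained: set[str]
    calls: list[AffinityCall]


@dataclass
class ScreenResult:
    hits: HitTable
    families: dict[str, FamilyResult]
    evidence: dict[str, TargetingEvidence]
    matrix: InventoryMatrix
    summary: dict[str, dict[str, bool]]

    def all_calls(self) -> list[AffinityCall]:
        out = []
        for fr in self.families.values():
            out.extend(fr.calls)
        return out

    def retained_ids(self) -> set[str]:
        out: set[str] = set()
        for fr in self.families.values():
            out |= {f"{fr.family}:{pid}" for pid in fr.retained}
        return out


def load_bundle(bundle_dir):
    """Read a scenario/run bundle directory: proteomes/*.fasta,
    alignments/*.fasta, roles.tsv, registry.tsv."""
    base = Path(bundle_dir)
    roles = read_taxon_roles(base / "roles.tsv")
    registry = read_registry(base / "registry.tsv")
    proteomes = {}
    for path in sorted((base / "proteomes").glob("*.fasta")):
        proteomes[path.stem] = read_fasta(path)
    alignments = {}
    for path in sorted((base / "alignments").glob("*.fasta")):
        alignments[path.stem] = read_alignment(path, family=path.stem)
    return roles, registry, proteomes, alignments


def run_screen(
    roles: TaxonRoleMap,
    registry: FamilyRegistry,
    proteomes: dict[str, list[ProteinRecord]],
    ref_alignments: dict[str, Alignment],
    config: RunConfig,
) -> ScreenResult:
    """Execute the full screen in memory."""
    config.validate()
    families = [f for f in registry.families() if f in ref_alignments]

    all_records: dict[str, ProteinRecord] = {}
    lengths = []
    for taxon in sorted(proteomes):
        for rec in proteomes[taxon]:
            if rec.id in all_records:
                raise ValueError(f"protein id {rec.id!r} appears in two proteomes")
            all_records[rec.id] = rec
            lengths.append(len(rec))
    decoy_length = int(np.median(lengths)) if lengths else 350

    profiles: dict[str, ProfileHMM] = {}
    for fam in families:
        prof = build_profile(
            ref_alignments[fam],
            occupancy_threshold=config.occupancy_threshold,
            pseudocount_weight=config.pseudocount_weight,
        )
        calibrate(
            prof,
            n_decoys=config.calibration_decoys,
            decoy_length=decoy_length,
            seed=derive_seed(config.seed, "calibrate", fam),
        )
        profiles[fam] = prof

    ordered_proteomes = [proteomes[t] for t in sorted(proteomes)]
    hits, scores = search_proteomes_scored(
        [profiles[f] for f in families], ordered_proteomes, config.e_threshold
    )
    hits = triage_top_n(hits, top_n=config.top_n, per_taxon=config.per_taxon_cap)

    # family assignment (best forward profile) for every hit protein
    hit_proteins = sorted({h.protein_id for h in hits})
    assignment: dict[str, tuple[str | None, float]] = {}
    for pid in hit_proteins:
        ranked = sorted(
            families, key=lambda f: (-scores.get((f, pid), -np.inf), f)
        )[:3]
        fwd = sorted(
            ((forward_score(profiles[f], all_records[pid].sequence), f)
             for f in ranked),
            key=lambda x: (-x[0], x[1]),
        )
        if not np.isfinite(fwd[0][0]):
            assignment[pid] = (None, 0.0)
        elif len(fwd) == 1:
            assignment[pid] = (fwd[0][1], float("inf"))
        else:
            assignment[pid] = (fwd[0][1], float(fwd[0][0] - fwd[1][0]))
    hits = HitTable([
        replace(h, assigned_family=assignment[h.protein_id][0],
                margin=assignment[h.protein_id][1])
        for h in hits
    ])

    evidence: dict[str, TargetingEvidence] = {}
    family_results: dict[str, FamilyResult] = {}
    for fam in families:
        ref_aln = ref_alignments[fam]
        ref_ids = set(ref_aln.ids())
        fam_hits = [h for h in hits.for_family(fam) if h.protein_id not in ref_ids]
        if not fam_hits:
            family_results[fam] = FamilyResult(
                fam, ref_aln, PurgeReport(family=fam, converged=True), set(), []
            )
            continue
        records = [all_records[h.protein_id] for h in fam_hits]
        augmented = augment_family_alignment(ref_aln, records, profiles[fam])
        if config.external_trees_dir is not None:
            clean = augmented
            report = PurgeReport(family=fam, converged=True)
            tree = read_newick(
                (Path(config.external_trees_dir) / f"{fam}.nwk").read_text()
            )
            taxa = {rec.id: rec.taxon for rec, _ in clean.rows}
            annotate_leaves(tree, taxa, roles)
            report.final_tree = tree
        else:
            clean, report = purge_paralogs(
                fam, augmented, fam_hits, roles, profiles[fam],
                max_cycles=config.max_cycles,
                support_threshold=config.support_threshold,
                n_reps=config.bootstrap_reps,
                seed=derive_seed(config.seed, "purge", fam),
            )
        surviving = [h for h in fam_hits
                     if h.protein_id in {r.id for r, _ in clean.rows}]
        if not surviving:
            family_results[fam] = FamilyResult(fam, clean, report, set(), [])
            continue
        rooted = midpoint_root(report.final_tree)
        retained = accept_orthologs(rooted, roles, surviving, fam,
                                    margin_min=config.margin_min)
        calls = classify_affinity(
            rooted, roles, fam,
            support_threshold=config.support_threshold,
            purity=config.purity,
            retained=retained,
        )
        # targeting evidence for surviving query-side copies
        for h in surviving:
            evidence[h.protein_id] = evaluate_targeting(
                all_records[h.protein_id], clean
            )
        family_results[fam] = FamilyResult(fam, clean, report, retained, calls)

    if config.external_sp_tsv is not None:
        evidence = import_sp_predictions(config.external_sp_tsv, evidence)

    all_calls = [c for fr in family_results.values() for c in fr.calls]
    matrix = build_matrix(all_calls, evidence, registry, roles)
    try:
        controls = control_families(hits, registry, roles)
        for taxon in matrix.taxa:
            matrix.completeness[taxon] = completeness_proxy(hits, taxon, controls)
    except ValueError:
        pass  # no reference taxa or empty control set: completeness stays empty
    corroborate_absences(matrix, roles)
    summary = subcomplex_summary(matrix, registry)
    return ScreenResult(hits, family_results, evidence, matrix, summary)


def search_proteomes_scored(profiles, proteomes, e_threshold,
                            filter_slack_bits: float = 15.0):
    """search_proteomes plus the raw per-(family, protein) scores (used to
    shortlist profiles for forward-score family assignment).

    Pairs whose ungapped-filter score sits more than ``filter_slack_bits``
    below the reporting threshold are skipped without a full Viterbi pass;
    the filter is a lower bound on the Viterbi score, and indel excursions
    cannot close a gap that large, so no reportable hit is lost.
    """
    from .profile_hmm import (
        evalue, score_at_evalue, ungapped_filter_bits, viterbi_bits,
        viterbi_score,
    )

    records = [rec for proteome in proteomes for rec in proteome]
    db = max(len(records), 1)
    scores: dict[tuple[str, str], float] = {}
    hits = []
    for profile in profiles:
        cutoff = score_at_evalue(profile, e_threshold, db) - filter_slack_bits
        for rec in records:
            fbits = ungapped_filter_bits(profile, rec.sequence)
            if fbits < cutoff:
                scores[(profile.family, rec.id)] = fbits
                continue
            bits = viterbi_bits(profile, rec.sequence, mode="local")
            scores[(profile.family, rec.id)] = bits
            if not np.isfinite(bits):
                continue
            e = evalue(profile, bits, db)
            if e <= e_threshold:
                _, _, (start, end) = viterbi_score(profile, rec.sequence, "local")
                hits.append(SearchHit(
                    family=profile.family, protein_id=rec.id, taxon=rec.taxon,
                    bits=float(bits), e_value=float(e), start=start, end=end,
                ))
    return HitTable(hits), scores


# --------------------------------------------------------------------------
# file-level entry point


def run_all(config: RunConfig) -> ScreenResult:
    """Load the bundle, run the screen, and write the output TSVs."""
    if config.bundle_dir is None:
        raise ValueError("run_all needs a bundle_dir")
    roles, registry, proteomes, alignments = load_bundle(config.bundle_dir)
    result = run_screen(roles, registry, proteomes, alignments, config)
    if config.out_dir is not None:
        write_outputs(result, config)
    return result


def _header(config: RunConfig) -> str:
    return (f"# egt-screen v{__version__} config={config.digest()} "
            f"seed={config.seed}\n")


def write_outputs(result: ScreenResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    head = _header(config)

    with open(out / "hits.tsv", "w") as fh:
        fh.write(head)
        fh.write("family\tprotein\ttaxon\tbits\tevalue\tstart\tend\t"
                 "assigned_family\tmargin\n")
        for h in result.hits:
            fh.write(
                f"{h.family}\t{h.protein_id}\t{h.taxon}\t{h.bits:.2f}\t"
                f"{h.e_value:.3g}\t{h.start}\t{h.end}\t"
                f"{h.assigned_family or 'NA'}\t"
                f"{'NA' if h.margin is None else f'{h.margin:.2f}'}\n"
            )

    with open(out / "calls.tsv", "w") as fh:
        fh.write(head)
        fh.write("family\tprotein\ttaxon\tlabel\tsupport\tsister_roles\t"
                 "retained\n")
        for fam in sorted(result.families):
            for c in result.families[fam].calls:
                comp = ",".join(
                    f"{k}:{v}" for k, v in sorted(c.sister_composition.items())
                )
                fh.write(
                    f"{c.family}\t{c.protein_id}\t{c.taxon}\t{c.label}\t"
                    f"{'NA' if c.support_at_decision is None else c.support_at_decision}"
                    f"\t{comp or 'NA'}\t{int(c.cycle_retained)}\n"
                )

    with open(out / "evidence.tsv", "w") as fh:
        fh.write(head)
        fh.write("protein\tsp_predicted\tsp_score\tcleavage\tnterm_complete\t"
                 "basis\tfg_count\tfg_density\tfg_flag\n")
        for pid in sorted(result.evidence):
            ev = result.evidence[pid]
            sp = "NA" if ev.sp_predicted is None else int(ev.sp_predicted)
            fh.write(
                f"{pid}\t{sp}\t"
                f"{'NA' if ev.sp_score is None else f'{ev.sp_score:.2f}'}\t"
                f"{'NA' if ev.sp_cleavage_pos is None else ev.sp_cleavage_pos}\t"
                f"{int(ev.nterm_complete)}\t{ev.nterm_basis}\t{ev.fg_count}\t"
                f"{ev.fg_density_per_100:.2f}\t{int(ev.fg_flag)}\n"
            )

    with open(out / "matrix.tsv", "w") as fh:
        fh.write(head)
        fh.write("family\ttaxon\tcopy_index\tprotein\taffinity\tsp\tnterm\t"
                 "copy_count\tabsence_corroborated\tcompleteness\n")
        for fam in result.matrix.families:
            for taxon in result.matrix.taxa:
                cell = result.matrix.cell(fam, taxon)
                comp = result.matrix.completeness.get(taxon, float("nan"))
                if not cell.copies:
                    fh.write(
                        f"{fam}\t{taxon}\t0\tNA\tabsent\tNA\tNA\t0\t"
                        f"{int(cell.absence_corroborated)}\t{comp:.2f}\n"
                    )
                for i, copy in enumerate(cell.copies, 1):
                    sp = "NA" if copy.sp_flag is None else int(copy.sp_flag)
                    fh.write(
                        f"{fam}\t{taxon}\t{i}\t{copy.protein_id}\t"
                        f"{copy.affinity}\t{sp}\t{int(copy.nterm_complete)}\t"
                        f"{cell.copy_count}\t{int(cell.absence_corroborated)}\t"
                        f"{comp:.2f}\n"
                    )

    with open(out / "subcomplex_summary.tsv", "w") as fh:
        fh.write(head)
        fh.write("group\tsubcomplex\tpresent\n")
        for group in sorted(result.summary):
            for sub, present in sorted(result.summary[group].items()):
                fh.write(f"{group}\t{sub}\t{int(present)}\n")

    with open(out / "purge_reports.json", "w") as fh:
        reports = {
            fam: {
                "cycles_run": fr.purge_report.cycles_run,
                "converged": fr.purge_report.converged,
                "removed": fr.purge_report.removed,
            }
            for fam, fr in result.families.items()
        }
        json.dump(reports, fh, indent=1)
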