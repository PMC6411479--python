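"""Ground-truth evaluation of the screen on synthetic scenarios.

Shared between the test suite and the reproduction script: runs scenarios,
compares pipeline output against the generator's truth table, and reports
recovery metrics (provenance recall, false-positive rates, purge accuracy,
signal-peptide sensitivity/specificity, structural reproduction of the
two-copy EGT pattern, and threshold robustness).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .pipeline import RunConfig, derive_seed, run_screen
from .synthetic_data import ScenarioBundle, ScenarioConfig, generate_scenario
from .targeting import predict_signal_peptide

__all__ = [
    "ScenarioRun",
    "run_scenario",
    "run_default_study",
    "run_pure_host_study",
    "run_decoy_scenario",
    "run_truncation_scenario",
    "rerun_with_thresholds",
    "classifier_metrics",
    "algal_false_positive_rate",
    "purge_metrics",
    "sp_metrics",
    "headline_checks",
    "retained_set",
]


@dataclass
class ScenarioRun:
    bundle: ScenarioBundle
    result: "object"  # ScreenResult
    run_config: RunConfig


def run_scenario(scenario: ScenarioConfig, run_config: RunConfig | None = None) -> ScenarioRun:
    bundle = generate_scenario(scenario)
    rc = run_config or RunConfig(seed=scenario.seed)
    result = run_screen(bundle.roles, bundle.registry, bundle.proteomes,
                        bundle.ref_alignments, rc)
    return ScenarioRun(bundle, result, rc)


def run_default_study(n_seeds: int = 25, base_seed: int = 0) -> list[ScenarioRun]:
    """The standard condition, seed-varied: 12 families, 20 taxa, two EGT
    families with signal peptides."""
    runs = []
    for i in range(n_seeds):
        s = derive_seed(base_seed, "default-study", i)
        runs.append(run_scenario(ScenarioConfig(seed=s)))
    return runs


def run_pure_host_study(n_seeds: int = 5, base_seed: int = 0) -> list[ScenarioRun]:
    """Vertical descent only (no EGT): every algal_related call is a false
    positive."""
    runs = []
    for i in range(n_seeds):
        s = derive_seed(base_seed, "pure-host-study", i)
        runs.append(run_scenario(ScenarioConfig(seed=s, egt_families=())))
    return runs


def run_truncation_scenario(base_seed: int = 0,
                            truncation_fraction: float = 0.3) -> ScenarioRun:
    """Default condition plus N-terminal truncation of a fraction of query
    transcripts, for the targeting-evidence consistency checks."""
    s = derive_seed(base_seed, "truncation-scenario")
    return run_scenario(
        ScenarioConfig(seed=s, truncation_fraction=truncation_fraction)
    )


def run_decoy_scenario(base_seed: int = 0,
                       targets: tuple[str, ...] = ("Sec13", "Nup93")) -> ScenarioRun:
    s = derive_seed(base_seed, "decoy-scenario")
    cfg = ScenarioConfig(seed=s,
                         decoy_paralog_families={t: 1.0 for t in targets})
    return run_scenario(cfg)


# --------------------------------------------------------------------------
# metrics


def classifier_metrics(runs: list[ScenarioRun]) -> dict[str, float]:
    """Recall of true provenance labels among calls on truth-table genes."""
    n_algal = n_algal_ok = n_host = n_host_ok = 0
    for run in runs:
        truth = run.bundle.truth_by_id()
        for call in run.result.all_calls():
            t = truth.get(call.protein_id)
            if t is None or t.is_decoy_paralog:
                continue
            if t.provenance == "algal":
                n_algal += 1
                n_algal_ok += call.label == "algal_related"
            else:
                n_host += 1
                n_host_ok += call.label == "host_related"
    return {
        "algal_recall": n_algal_ok / n_algal if n_algal else float("nan"),
        "host_recall": n_host_ok / n_host if n_host else float("nan"),
        "n_algal": n_algal,
        "n_host": n_host,
    }


def algal_false_positive_rate(runs: list[ScenarioRun]) -> dict[str, float]:
    n = fp = 0
    for run in runs:
        truth = run.bundle.truth_by_id()
        for call in run.result.all_calls():
            t = truth.get(call.protein_id)
            if t is None or t.provenance != "host":
                continue
            n += 1
            fp += call.label == "algal_related"
    return {"algal_fpr": fp / n if n else float("nan"), "n_host_calls": n}


def purge_metrics(run: ScenarioRun) -> dict[str, float]:
    """Fractions of intruding decoy leaves removed and of true orthologs
    lost, pooled over the decoy-targeted families."""
    truth = run.bundle.truth_by_id()
    targets = set(run.bundle.config.decoy_paralog_families)
    n_decoy = n_decoy_removed = n_ortho = n_ortho_removed = 0
    max_cycles = 0
    for fam in targets:
        fr = run.result.families[fam]
        ref_ids = set(run.bundle.ref_alignments[fam].ids())
        aug = [h for h in run.result.hits.for_family(fam)
               if h.protein_id not in ref_ids]
        removed = fr.purge_report.all_removed_ids()
        max_cycles = max(max_cycles, fr.purge_report.cycles_run)
        for h in aug:
            if truth[h.protein_id].is_decoy_paralog:
                n_decoy += 1
                n_decoy_removed += h.protein_id in removed
            else:
                n_ortho += 1
                n_ortho_removed += h.protein_id in removed
    return {
        "decoy_removed_frac": n_decoy_removed / n_decoy if n_decoy else float("nan"),
        "ortholog_removed_frac": n_ortho_removed / n_ortho if n_ortho else float("nan"),
        "n_decoy_intruders": n_decoy,
        "n_orthologs": n_ortho,
        "max_cycles_run": max_cycles,
    }


def sp_metrics(run: ScenarioRun) -> dict[str, float]:
    """Signal-peptide heuristic vs generator truth, on complete-N-terminus
    records; plus the refusal rate on truncated records."""
    truth = run.bundle.truth_by_id()
    tp = fn = tn = fp = 0
    n_trunc = n_refused = 0
    for taxon, records in run.bundle.proteomes.items():
        for rec in records:
            t = truth[rec.id]
            if t.truncated:
                ev = run.result.evidence.get(rec.id)
                if ev is not None:
                    n_trunc += 1
                    n_refused += ev.sp_predicted is None
                continue
            call = predict_signal_peptide(rec.sequence)
            if call.predicted is None:
                continue
            if t.has_sp:
                tp += call.predicted
                fn += not call.predicted
            else:
                fp += call.predicted
                tn += not call.predicted
    return {
        "sp_sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "sp_specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "refusal_on_truncated": n_refused / n_trunc if n_trunc else float("nan"),
        "n_sp_true": tp + fn,
        "n_sp_false": tn + fp,
        "n_truncated_evaluated": n_trunc,
    }


def headline_checks(run: ScenarioRun) -> dict[str, float]:
    """Structural reproduction of the two-copy EGT pattern in the inventory:
    non-EGT families single-copy host-related in every query taxon; EGT
    families two-copy with exactly one algal-related, SP-bearing copy; the
    nucleomorph subcomplex group restricted to the EGT families'
    subcomplexes."""
    cfg = run.bundle.config
    matrix = run.result.matrix
    registry = run.bundle.registry
    egt = set(cfg.egt_families)
    ok = total = 0
    for fam in cfg.families:
        for taxon in matrix.taxa:
            cell = matrix.cell(fam, taxon)
            total += 1
            if fam in egt:
                algal = [c for c in cell.copies if c.affinity == "algal_related"]
                ok += (
                    cell.copy_count == 2
                    and len(algal) == 1
                    and algal[0].sp_flag is True
                    and all(c.affinity == "host_related"
                            for c in cell.copies if c not in algal)
                )
            else:
                ok += (
                    cell.copy_count == 1
                    and cell.copies[0].affinity == "host_related"
                )
    egt_subs = {registry.subcomplex(f) for f in egt}
    summary = run.result.summary
    nm = summary.get("nucleomorph", {})
    nm_ok = all(
        present == (sub in egt_subs) for sub, present in nm.items()
    )
    return {
        "cell_match_frac": ok / total if total else float("nan"),
        "n_cells": total,
        "nucleomorph_subcomplexes_exact": float(nm_ok),
    }


def retained_set(run: ScenarioRun) -> set[str]:
    return run.result.retained_ids()


def rerun_with_thresholds(run: ScenarioRun, e_threshold: float,
                          top_n: int) -> ScenarioRun:
    rc = replace(run.run_config, e_threshold=e_threshold, top_n=top_n)
    result = run_screen(run.bundle.roles, run.bundle.registry,
                        run.bundle.proteomes, run.bundle.ref_alignments, rc)
    return ScenarioRun(run.bundle, result, rc)
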