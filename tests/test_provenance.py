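"""Affinity classification, ortholog acceptance, and paralog purging."""

import warnings

import pytest

from egt_screen.homology_search import SearchHit
from egt_screen.provenance import (
    accept_orthologs,
    classify_affinity,
    purge_paralogs,
)
from egt_screen.seqio import TaxonRoleMap
from egt_screen.synthetic_data import ScenarioConfig
from egt_screen.trees import Node, PhyloTree

ROLES = TaxonRoleMap({
    "q1": "query_host_lineage", "q2": "query_host_lineage",
    "h1": "host_outgroup", "h2": "host_outgroup",
    "al1": "endosymbiont_algal", "al2": "endosymbiont_algal",
    "ot1": "other_reference",
})


def leaf(name, taxon, length=1.0):
    n = Node(name=name, length=length)
    n.taxon = taxon
    n.role = ROLES.role(taxon)
    return n


def quartet_tree(support):
    """Rooted tree: ((q1,q2)s, (al1,al2)) plus an outgroup pair."""
    root = Node()
    inner = Node(length=1.0, support=support)
    qs = Node(length=0.5, support=99)
    qs.add(leaf("Q1", "q1"))
    qs.add(leaf("Q2", "q2"))
    als = Node(length=0.5, support=99)
    als.add(leaf("A1", "al1"))
    als.add(leaf("A2", "al2"))
    inner.add(qs)
    inner.add(als)
    outs = Node(length=1.0, support=99)
    outs.add(leaf("H1", "h1"))
    outs.add(leaf("O1", "ot1"))
    root.add(inner)
    root.add(outs)
    return PhyloTree(root, rooted=True)


def test_query_clade_sister_to_algal_high_support():
    calls = classify_affinity(quartet_tree(85), ROLES, "F")
    by_id = {c.protein_id: c for c in calls}
    assert by_id["Q1"].label == "algal_related"
    assert by_id["Q1"].support_at_decision == 85
    assert by_id["Q1"].sister_composition == {"endosymbiont_algal": 2}


def test_low_support_demotes_to_ambiguous():
    calls = classify_affinity(quartet_tree(60), ROLES, "F")
    assert all(c.label == "ambiguous" for c in calls)


def test_support_exactly_at_threshold_is_ambiguous():
    # the rule is strictly greater-than
    calls = classify_affinity(quartet_tree(70), ROLES, "F")
    assert all(c.label == "ambiguous" for c in calls)


def test_host_sister_gives_host_related():
    root = Node()
    qs = Node(length=0.5, support=99)
    qs.add(leaf("Q1", "q1"))
    qs.add(leaf("Q2", "q2"))
    inner = Node(length=1.0, support=90)
    hs = Node(length=0.5, support=99)
    hs.add(leaf("H1", "h1"))
    hs.add(leaf("H2", "h2"))
    inner.add(qs)
    inner.add(hs)
    root.add(inner)
    root.add(leaf("A1", "al1", 2.0))
    calls = classify_affinity(PhyloTree(root, rooted=True), ROLES, "F")
    assert {c.label for c in calls} == {"host_related"}


def test_mixed_sister_below_purity_is_ambiguous():
    root = Node()
    qs = Node(length=0.5, support=99)
    qs.add(leaf("Q1", "q1"))
    qs.add(leaf("Q2", "q2"))
    mixed = Node(length=0.5, support=99)
    mixed.add(leaf("H1", "h1"))
    mixed.add(leaf("A1", "al1"))
    inner = Node(length=1.0, support=95)
    inner.add(qs)
    inner.add(mixed)
    root.add(inner)
    root.add(leaf("O1", "ot1", 2.0))
    calls = classify_affinity(PhyloTree(root, rooted=True), ROLES, "F")
    by_id = {c.protein_id: c for c in calls}
    assert by_id["Q1"].label == "ambiguous"  # 50/50 < 0.8 purity
    assert by_id["Q1"].sister_composition == {
        "host_outgroup": 1, "endosymbiont_algal": 1
    }


def test_query_only_tree_unclassifiable():
    root = Node()
    a = Node(length=1.0)
    a.add(leaf("Q1", "q1"))
    a.add(leaf("Q2", "q2"))
    root.add(a)
    root.add(leaf("Q3", "q1", 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        calls = classify_affinity(PhyloTree(root, rooted=True), ROLES, "F")
    assert {c.label for c in calls} == {"unclassifiable"}
    assert all(c.sister_composition == {} for c in calls)


def test_unrooted_tree_rejected():
    t = quartet_tree(90)
    t.rooted = False
    with pytest.raises(ValueError, match="midpoint"):
        classify_affinity(t, ROLES, "F")
    with pytest.raises(ValueError, match="midpoint"):
        accept_orthologs(t, ROLES, [], "F")


def test_no_confident_label_at_or_below_threshold():
    for support in (0, 40, 70, 71, 100):
        calls = classify_affinity(quartet_tree(support), ROLES, "F")
        for c in calls:
            if c.label in ("host_related", "algal_related"):
                assert c.support_at_decision > 70


def test_classification_deterministic():
    c1 = classify_affinity(quartet_tree(85), ROLES, "F")
    c2 = classify_affinity(quartet_tree(85), ROLES, "F")
    assert c1 == c2


# -- ortholog acceptance ----------------------------------------------------


def _hit(pid, assigned, margin):
    return SearchHit("F", pid, "q1", bits=50.0, e_value=1e-9, start=0,
                     end=10, assigned_family=assigned, margin=margin)


def test_accept_by_sister_context_despite_mismatched_assignment():
    tree = quartet_tree(85)
    hits = [_hit("Q1", "OtherFam", 5.0), _hit("Q2", "OtherFam", 5.0)]
    retained = accept_orthologs(tree, ROLES, hits, "F")
    assert retained == {"Q1", "Q2"}  # reference leaves in sister context


def test_accept_isolated_leaf_by_assignment_margin():
    # Q1 alone on a long branch, no reference sister context available
    root = Node()
    root.add(leaf("Q1", "q1", 5.0))
    inner = Node(length=1.0, support=99)
    inner.add(leaf("Q2", "q1", 0.5))
    inner.add(leaf("Q3", "q2", 0.5))
    root.add(inner)
    tree = PhyloTree(root, rooted=True)
    hits = [_hit("Q1", "F", 10.0), _hit("Q2", "G", 0.5), _hit("Q3", "G", 0.5)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        retained = accept_orthologs(tree, ROLES, hits, "F")
    assert "Q1" in retained  # rule (b): matching assignment, margin >= 2
    assert "Q2" not in retained and "Q3" not in retained  # neither rule


# -- paralog purge ----------------------------------------------------------


@pytest.fixture(scope="module")
def mini_decoy_run():
    from egt_screen.evaluation import run_scenario

    cfg = ScenarioConfig(
        seed=19,
        families=["Nup98", "Sec13", "Nup62"],
        egt_families=(),
        decoy_paralog_families={"Sec13": 1.0},
        length_range=(150, 250),
        n_query=4, n_host_outgroup=3, n_algal=4, n_other=3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_scenario(cfg)


def test_planted_decoys_removed_orthologs_kept(mini_decoy_run):
    run = mini_decoy_run
    truth = run.bundle.truth_by_id()
    fr = run.result.families["Sec13"]
    removed = fr.purge_report.all_removed_ids()
    ref_ids = set(run.bundle.ref_alignments["Sec13"].ids())
    aug = [h.protein_id for h in run.result.hits.for_family("Sec13")
           if h.protein_id not in ref_ids]
    decoys = [p for p in aug if truth[p].is_decoy_paralog]
    orthos = [p for p in aug if not truth[p].is_decoy_paralog]
    assert decoys, "scenario must plant intruding decoys"
    assert set(decoys) <= removed
    assert not (set(orthos) & removed)
    assert fr.purge_report.cycles_run <= 3


def test_purge_without_paralogs_converges_immediately(mini_decoy_run):
    run = mini_decoy_run
    rep = run.result.families["Nup62"].purge_report
    assert rep.converged
    assert rep.cycles_run == 1
    assert rep.all_removed_ids() == set()


def test_purge_idempotent_once_converged(mini_decoy_run):
    run = mini_decoy_run
    fr = run.result.families["Sec13"]
    hits = [h for h in run.result.hits.for_family("Sec13")]
    from egt_screen.profile_hmm import build_profile

    profile = build_profile(run.bundle.ref_alignments["Sec13"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean2, rep2 = purge_paralogs(
            "Sec13", fr.clean_alignment, hits, run.bundle.roles, profile,
            seed=123,
        )
    assert rep2.all_removed_ids() == set()
    assert rep2.converged


def test_max_cycles_is_a_hard_cap(mini_decoy_run):
    run = mini_decoy_run
    truth = run.bundle.truth_by_id()
    ref_aln = run.bundle.ref_alignments["Sec13"]
    ref_ids = set(ref_aln.ids())
    hits = [h for h in run.result.hits.for_family("Sec13")
            if h.protein_id not in ref_ids]
    from egt_screen.homology_search import augment_family_alignment
    from egt_screen.profile_hmm import build_profile

    profile = build_profile(ref_aln)
    records = {r.id: r for t in run.bundle.proteomes.values() for r in t}
    augmented = augment_family_alignment(
        ref_aln, [records[h.protein_id] for h in hits], profile
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, rep = purge_paralogs(
            "Sec13", augmented, hits, run.bundle.roles, profile,
            max_cycles=1, seed=77,
        )
    assert rep.cycles_run == 1
    assert not rep.converged  # a removal happened and no empty cycle was seen
    assert any(truth[p].is_decoy_paralog for p in rep.all_removed_ids())
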