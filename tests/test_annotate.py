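"""Classification transfer, tiered substrate prediction and full annotation."""

import random

import pytest

from transaap.annotate import (
    Annotation,
    TransferTiers,
    annotate_proteome,
    assign_classification,
    best_reference_hit,
    predict_substrate,
)
from transaap.evidence import build_bundles
from transaap.io import DomainHit, ProteinRecord, ReferenceEntry, SearchHit
from transaap.tm import TmTopology

REF = {
    "TDB001": ReferenceEntry("TDB001", "ABC", "CUT1", "3.A.1.1.1", "sugars", "maltose"),
    "TDB002": ReferenceEntry("TDB002", "ABC", "CUT1", "3.A.1.1.2", "sugars", "galactose"),
    "TDBX": ReferenceEntry("TDBX", "MFS", None, None, None, None),
}


def _hit(subject, bitscore, evalue=1e-40, identity=80.0, coverage=90.0, track="curated_tdb"):
    return SearchHit("p1", subject, "", identity, 100, evalue, bitscore, coverage, track)


def _bundle(hits=(), domains=(), topology=None):
    protein = ProteinRecord("p1", "", "MKTAAAGG")
    [bundle] = build_bundles(
        [protein], hits, domains,
        topologies={"p1": topology} if topology else None,
    )
    return bundle


# --- best reference hit ------------------------------------------------------


def test_best_hit_is_highest_bitscore_resolvable():
    bundle = _bundle([_hit("TDB001", 300.0), _hit("TDB002", 250.0)])
    hit, entry = best_reference_hit(bundle, REF)
    assert hit.bitscore == 300.0 and entry.accession == "TDB001"


def test_best_hit_tie_breaks_on_evalue_then_subject_id():
    bundle = _bundle([_hit("TDB002", 300.0, 1e-40), _hit("TDB001", 300.0, 1e-40)])
    assert best_reference_hit(bundle, REF)[1].accession == "TDB001"
    bundle = _bundle([_hit("TDB002", 300.0, 1e-50), _hit("TDB001", 300.0, 1e-40)])
    assert best_reference_hit(bundle, REF)[1].accession == "TDB002"


def test_unresolvable_or_failing_hits_give_no_best():
    assert best_reference_hit(_bundle([_hit("UNKNOWN", 400.0)]), REF) is None
    assert best_reference_hit(_bundle([_hit("TDB001", 400.0, evalue=1e-3)]), REF) is None


def test_nr_track_never_used_for_transfer():
    bundle = _bundle([_hit("TDB001", 500.0, track="nr")])
    assert best_reference_hit(bundle, REF) is None


# --- classification ----------------------------------------------------------


def test_classification_copied_from_reference():
    bundle = _bundle([_hit("TDB001", 300.0)])
    best = best_reference_hit(bundle, REF)
    assert assign_classification(bundle, best) == ("ABC", "CUT1", "3.A.1.1.1")


def test_profile_fallback_maps_family_without_tc():
    bundle = _bundle(domains=[DomainHit("p1", "PF00005", "ABC_tran", 1e-12, 80.0, 1, 50)])
    assert assign_classification(bundle, None) == ("ABC", None, None)


def test_no_evidence_fallback_is_unclassified():
    topo = TmTopology(7, [(i * 40 + 1, i * 40 + 20) for i in range(7)])
    bundle = _bundle(topology=topo)
    assert assign_classification(bundle, None) == ("unclassified", None, None)


# --- substrate tiers ---------------------------------------------------------


@pytest.mark.parametrize(
    "identity,coverage,expected",
    [
        (85.0, 95.0, ("sugars", "maltose")),  # specific tier
        (40.0, 80.0, ("sugars", None)),  # class tier only
        (25.0, 80.0, (None, None)),  # abstain: identity below class tier
        (85.0, 40.0, (None, None)),  # abstain: coverage below class tier
        (62.0, 70.0, ("sugars", "maltose")),  # inclusive boundaries
    ],
)
def test_substrate_transfer_tiers(identity, coverage, expected):
    bundle = _bundle([_hit("TDB001", 300.0, identity=identity, coverage=coverage)])
    best = best_reference_hit(bundle, REF)
    assert predict_substrate(best, TransferTiers()) == expected


def test_unknown_coverage_fails_every_tier():
    bundle = _bundle([_hit("TDB001", 300.0, identity=90.0, coverage=None)])
    best = best_reference_hit(bundle, REF)
    assert predict_substrate(best, TransferTiers()) == (None, None)


def test_missing_reference_fields_propagate_as_abstention():
    bundle = _bundle([_hit("TDBX", 300.0, identity=90.0, coverage=95.0)])
    best = best_reference_hit(bundle, REF)
    assert predict_substrate(best, TransferTiers()) == (None, None)


def test_no_best_hit_abstains():
    assert predict_substrate(None, TransferTiers()) == (None, None)


def test_raising_specific_identity_never_adds_specific_calls():
    """Abstention monotonicity in the specific-tier identity cutoff."""
    rng = random.Random(42)
    hits = [
        _hit("TDB001", 300.0, identity=rng.uniform(10, 100), coverage=rng.uniform(10, 100))
        for _ in range(100)
    ]
    counts = []
    for min_id in (30.0, 50.0, 60.0, 80.0, 95.0):
        tiers = TransferTiers(specific_min_identity=min_id)
        n = sum(
            1
            for h in hits
            if predict_substrate((h, REF["TDB001"]), tiers)[1] is not None
        )
        counts.append(n)
    assert counts == sorted(counts, reverse=True)


# --- full annotation ---------------------------------------------------------


def _annotate_one(hits=(), domains=(), topologies=None):
    protein = ProteinRecord("p1", "", "MKTAAAGG")
    return annotate_proteome(
        [protein], hits=hits, domains=domains,
        topologies=topologies or {"p1": TmTopology(0, [])}, reference=REF,
    )[0]


def test_specific_tier_annotation_is_high_confidence():
    ann = _annotate_one([_hit("TDB001", 300.0, identity=85.0, coverage=95.0)])
    assert ann.status == "retained" and ann.confidence == "high"
    assert (ann.family, ann.substrate_class, ann.substrate) == ("ABC", "sugars", "maltose")
    assert "curated_tdb" in ann.evidence_summary


def test_class_tier_annotation_is_medium_confidence():
    ann = _annotate_one([_hit("TDB001", 300.0, identity=40.0, coverage=80.0)])
    assert ann.confidence == "medium" and ann.substrate is None
    assert ann.substrate_class == "sugars"


def test_tm_only_annotation_is_low_confidence_unclassified():
    topo = TmTopology(7, [(i * 40 + 1, i * 40 + 20) for i in range(7)])
    ann = _annotate_one(topologies={"p1": topo})
    assert ann.status == "retained" and ann.confidence == "low"
    assert ann.family == "unclassified" and ann.substrate is None
    assert ann.tm_count == 7 and "tm:7" in ann.evidence_summary


def test_hit_order_permutation_never_changes_annotations():
    rng = random.Random(8)
    hits = [
        _hit(s, b, identity=i)
        for s, b, i in [("TDB001", 300.0, 85.0), ("TDB002", 290.0, 70.0), ("UNKNOWN", 400.0, 90.0)]
    ]
    baseline = _annotate_one(list(hits))
    for _ in range(10):
        rng.shuffle(hits)
        assert _annotate_one(list(hits)) == baseline


def test_empty_proteome_gives_empty_annotation_list():
    assert annotate_proteome([], reference=REF) == []


def test_every_retained_annotation_names_a_passing_track(bench_annotations):
    for ann in bench_annotations:
        if ann.status == "retained":
            assert ann.evidence_summary != ""


def test_annotation_invariants_enforced():
    with pytest.raises(ValueError):
        Annotation("p1", "retained", substrate="maltose")  # substrate without class
    with pytest.raises(ValueError):
        Annotation("p1", "excluded", family="ABC")  # classification on non-retained
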