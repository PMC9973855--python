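"""Evidence aggregation: per-track thresholds and the inclusive candidate union."""

import logging
import random

import pytest

from conftest import random_bundle

from transaap.evidence import (
    DEFAULT_TRANSPORTER_COGS,
    CandidateStatus,
    Thresholds,
    build_bundles,
    flag_candidate,
)
from transaap.io import CogHit, DomainHit, ProteinRecord, SearchHit
from transaap.tm import TmTopology


def _hit(pid, track, evalue, bitscore=100.0, subject="S1", desc=""):
    return SearchHit(pid, subject, desc, 50.0, 100, evalue, bitscore, 80.0, track)


def _protein(pid="p1"):
    return ProteinRecord(pid, "", "MKTAAAGG")


# --- track_pass --------------------------------------------------------------


def test_passing_curated_hit_sets_track_pass():
    [b] = build_bundles([_protein()], [_hit("p1", "curated_tdb", 1e-30)])
    assert b.track_pass["curated_tdb"] is True
    assert not any(b.track_pass[t] for t in ("tcdb", "nr", "hmm", "cog", "tm"))


def test_all_evidence_above_ceilings_fails_every_track():
    [b] = build_bundles(
        [_protein()],
        [_hit("p1", t, 1e-3) for t in ("curated_tdb", "tcdb", "nr")],
        [DomainHit("p1", "PF00005", "ABC_tran", 1e-2, 40.0, 1, 50)],
        [CogHit("p1", "COG3839", 1e-3, 50.0)],
        {"p1": TmTopology(2, [(1, 20), (40, 60)])},
    )
    assert not any(b.track_pass.values())


def test_track_pass_matches_independent_predicates_on_random_bundles():
    """Per-track pass flags equal an independently coded predicate per track."""
    rng = random.Random(21)
    thresholds = Thresholds()
    for _ in range(200):
        protein, hits, domains, cogs, topology = random_bundle(rng)
        [b] = build_bundles([protein], hits, domains, cogs,
                            {protein.protein_id: topology}, thresholds)
        expected = {
            "curated_tdb": any(h.evalue <= 1e-5 for h in hits if h.source_track == "curated_tdb"),
            "tcdb": any(h.evalue <= 1e-5 for h in hits if h.source_track == "tcdb"),
            "nr": any(h.evalue <= 1e-5 for h in hits if h.source_track == "nr"),
            "hmm": any(d.domain_evalue <= 1e-4 for d in domains),
            "cog": any(c.evalue <= 1e-5 and c.cog_id in DEFAULT_TRANSPORTER_COGS for c in cogs),
            "tm": topology.tm_count >= 6,
        }
        assert b.track_pass == expected


def test_unknown_query_ids_dropped_with_warning(caplog):
    with caplog.at_level(logging.WARNING, logger="transaap.evidence"):
        [b] = build_bundles([_protein()], [_hit("ghost", "nr", 1e-30)])
    assert b.blast_hits["nr"] == []
    assert any("ghost" in r.message for r in caplog.records)


def test_bundle_sort_orders():
    hits = [_hit("p1", "nr", 1e-10, bitscore=s, subject=f"S{s}") for s in (100.0, 300.0, 200.0)]
    doms = [DomainHit("p1", f"PF0000{i}", "m", e, 50.0, 1, 50) for i, e in [(1, 1e-5), (2, 1e-9)]]
    [b] = build_bundles([_protein()], hits, doms)
    assert [h.bitscore for h in b.blast_hits["nr"]] == [300.0, 200.0, 100.0]
    assert [d.domain_evalue for d in b.domain_hits] == [1e-9, 1e-5]


# --- candidacy ---------------------------------------------------------------


def test_hmm_only_evidence_nominates_candidate():
    [b] = build_bundles([_protein()], domains=[DomainHit("p1", "PF00005", "ABC_tran", 1e-10, 80.0, 1, 50)])
    status = flag_candidate(b)
    assert status.is_candidate and status.triggering_tracks == ("hmm",)


def test_no_passing_track_means_not_a_candidate():
    [b] = build_bundles([_protein()])
    assert flag_candidate(b) == CandidateStatus(False, ())


@pytest.mark.parametrize("tm_count,expected", [(7, True), (6, True), (5, False)])
def test_tm_count_standalone_candidacy_threshold(tm_count, expected):
    topo = TmTopology(tm_count, [(i * 40 + 1, i * 40 + 20) for i in range(tm_count)])
    [b] = build_bundles([_protein()], topologies={"p1": topo})
    status = flag_candidate(b)
    assert status.is_candidate is expected
    if expected:
        assert status.triggering_tracks == ("tm",)


def test_exclusion_list_cogs_do_not_nominate_candidates():
    """A hit to a negative-rule COG is not positive transporter evidence."""
    [b] = build_bundles([_protein()], cogs=[CogHit("p1", "COG0178", 1e-40, 200.0)])
    assert not flag_candidate(b).is_candidate


def test_allowlisted_transporter_cog_nominates():
    [b] = build_bundles([_protein()], cogs=[CogHit("p1", "COG3839", 1e-40, 200.0)])
    assert flag_candidate(b).triggering_tracks == ("cog",)


# --- monotonicity properties -------------------------------------------------


def test_adding_evidence_never_revokes_candidacy():
    rng = random.Random(33)
    for _ in range(100):
        protein, hits, domains, cogs, topology = random_bundle(rng)
        [base] = build_bundles([protein], hits, domains, cogs, {protein.protein_id: topology})
        extra_hits = hits + [_hit(protein.protein_id, "curated_tdb", 1e-40)]
        [grown] = build_bundles([protein], extra_hits, domains, cogs, {protein.protein_id: topology})
        if flag_candidate(base).is_candidate:
            assert flag_candidate(grown).is_candidate


def test_relaxing_thresholds_never_shrinks_candidate_set():
    rng = random.Random(34)
    strict = Thresholds()
    relaxed = Thresholds(
        blast_evalue_max={"curated_tdb": 1e-2, "tcdb": 1e-2, "nr": 1e-2},
        hmm_domain_evalue_max=1e-1,
        cog_evalue_max=1e-2,
        tm_standalone_min=3,
    )
    for _ in range(100):
        protein, hits, domains, cogs, topology = random_bundle(rng)
        topo_map = {protein.protein_id: topology}
        [b_strict] = build_bundles([protein], hits, domains, cogs, topo_map, strict)
        [b_relaxed] = build_bundles([protein], hits, domains, cogs, topo_map, relaxed)
        if flag_candidate(b_strict).is_candidate:
            assert flag_candidate(b_relaxed).is_candidate


def test_candidate_status_invariant_enforced():
    with pytest.raises(ValueError):
        CandidateStatus(is_candidate=True, triggering_tracks=())
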