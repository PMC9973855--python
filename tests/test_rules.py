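"""The negative decision tree: default ruleset content and firing semantics."""

import random

import pytest

from conftest import random_built_bundle

from transaap.evidence import Thresholds, build_bundles, flag_candidate
from transaap.io import CogHit, DomainHit, ProteinRecord, SearchHit
from transaap.rules import (
    NegativeRule,
    RuleSet,
    apply_rules,
    default_ruleset,
    load_ruleset,
    save_ruleset,
)

# --- independent brute-force oracle for arming/firing semantics -------------


def oracle_apply(bundle, candidate, ruleset):
    """Direct re-implementation of the arming/firing semantics."""
    if not candidate.is_candidate:
        return ("never_candidate", None, None)
    passing_doms = {
        d.model_accession
        for d in bundle.domain_hits
        if d.domain_evalue <= bundle.thresholds.hmm_domain_evalue_max
    }
    for rule in ruleset.rules:
        if not any(a in passing_doms for a in rule.scope_accessions):
            continue
        if rule.rule_kind == "cog_exclusion":
            passing_cogs = {
                c.cog_id for c in bundle.cog_hits
                if c.evalue <= bundle.thresholds.cog_evalue_max
            }
            for cog in rule.payload:
                if cog in passing_cogs:
                    return ("excluded", rule.rule_id, cog)
        else:
            nr = sorted(
                bundle.blast_hits.get("nr", []),
                key=lambda h: (-h.bitscore, h.evalue, h.subject_id),
            )[: ruleset.nr_top_k]
            for hit in nr:
                for kw in rule.payload:
                    if kw.lower() in hit.subject_description.lower():
                        return ("excluded", rule.rule_id, kw)
    return ("retained", None, None)


# --- default ruleset ---------------------------------------------------------


def test_default_cog_exclusion_payload():
    rs = default_ruleset()
    cog_rule = rs.rules[0]
    assert cog_rule.rule_kind == "cog_exclusion"
    assert cog_rule.scope_accessions == frozenset({"PF00005"})
    assert len(cog_rule.payload) == 12
    assert set(cog_rule.payload) == {
        "COG0178", "COG1196", "COG1106", "COG1195", "COG0419", "COG3910",
        "COG1192", "COG0489", "COG2524", "COG2905", "COG4109", "COG0517",
    }


def test_default_keyword_exclusion_payload():
    kw_rule = default_ruleset().rules[1]
    assert kw_rule.rule_kind == "keyword_exclusion"
    assert len(kw_rule.payload) == 8
    assert set(kw_rule.payload) == {
        "cAMP-binding", "CBS domain", "Chromosome partition",
        "Cytochrome c assembly", "Cytochrome c biogenesis",
        "Excinuclease", "RNase L inhibitor", "UvrABC",
    }


def test_ruleset_file_round_trip_reproduces_default(tmp_path):
    path = tmp_path / "rules.yaml"
    save_ruleset(default_ruleset(), path)
    assert load_ruleset(path) == default_ruleset()


def test_rule_validation():
    with pytest.raises(ValueError):
        NegativeRule("r", frozenset({"PF00005"}), "cog_exclusion", ())
    with pytest.raises(ValueError):
        RuleSet(rules=(default_ruleset().rules[0], default_ruleset().rules[0]))


# --- firing semantics --------------------------------------------------------


def _abc_bundle(cogs=(), nr_descs=(), with_pf00005=True, pf_evalue=1e-10, curated=()):
    protein = ProteinRecord("p1", "", "MKTAAAGG")
    domains = (
        [DomainHit("p1", "PF00005", "ABC_tran", pf_evalue, 80.0, 1, 50)]
        if with_pf00005 else []
    )
    cog_hits = [CogHit("p1", c, 1e-30, 150.0) for c in cogs]
    hits = [
        SearchHit("p1", f"N{i}", d, 60.0, 100, 1e-30, 300.0 - i, 90.0, "nr")
        for i, d in enumerate(nr_descs)
    ]
    hits += [
        SearchHit("p1", s, "", 70.0, 100, 1e-40, 350.0, 90.0, "curated_tdb")
        for s in curated
    ]
    [bundle] = build_bundles([protein], hits, domains, cog_hits)
    return bundle


def test_payload_cog_excludes_armed_candidate():
    bundle = _abc_bundle(cogs=["COG0178"])
    call = apply_rules(bundle, flag_candidate(bundle), default_ruleset())
    assert call.status == "excluded"
    assert call.excluded_by == "abc_non_transporter_cogs"
    assert call.matched_payload == "COG0178"


def test_keyword_in_top_nr_hit_excludes_armed_candidate():
    bundle = _abc_bundle(nr_descs=["excinuclease ABC subunit A"])
    call = apply_rules(bundle, flag_candidate(bundle), default_ruleset())
    assert call.status == "excluded"
    assert call.excluded_by == "abc_nr_keywords"
    assert call.matched_payload == "Excinuclease"


def test_keyword_match_is_case_insensitive_substring():
    bundle = _abc_bundle(nr_descs=["putative CYTOCHROME C ASSEMBLY protein"])
    call = apply_rules(bundle, flag_candidate(bundle), default_ruleset())
    assert call.status == "excluded" and call.matched_payload == "Cytochrome c assembly"


def test_keyword_beyond_nr_top_k_does_not_fire():
    descs = ["benign protein"] * 5 + ["excinuclease ABC subunit A"]  # rank 6 of 6
    bundle = _abc_bundle(nr_descs=descs)
    call = apply_rules(bundle, flag_candidate(bundle), default_ruleset())
    assert call.status == "retained"


def test_clean_abc_transporter_retained():
    bundle = _abc_bundle(curated=["TDB0001"], nr_descs=["maltose ABC transporter"])
    call = apply_rules(bundle, flag_candidate(bundle), default_ruleset())
    assert call.status == "retained" and call.excluded_by is None


def test_unarmed_rule_cannot_exclude():
    """Payload evidence without a scope domain hit leaves the protein alone."""
    bundle = _abc_bundle(cogs=["COG0178"], nr_descs=["excinuclease"],
                         with_pf00005=False, curated=["TDB0001"])
    call = apply_rules(bundle, flag_candidate(bundle), default_ruleset())
    assert call.status == "retained"


def test_subthreshold_scope_domain_hit_does_not_arm():
    bundle = _abc_bundle(cogs=["COG0178"], pf_evalue=1e-2, curated=["TDB0001"])
    call = apply_rules(bundle, flag_candidate(bundle), default_ruleset())
    assert call.status == "retained"


def test_non_candidate_passes_through_untouched():
    bundle = _abc_bundle(with_pf00005=False)
    call = apply_rules(bundle, flag_candidate(bundle), default_ruleset())
    assert call.status == "never_candidate" and call.excluded_by is None


def test_empty_ruleset_retains_every_candidate():
    rng = random.Random(55)
    empty = RuleSet(rules=())
    for _ in range(50):
        bundle = random_built_bundle(rng)
        candidate = flag_candidate(bundle)
        call = apply_rules(bundle, candidate, empty)
        assert call.status == ("retained" if candidate.is_candidate else "never_candidate")


def test_first_firing_rule_wins():
    # both rules could fire; ruleset order decides
    bundle = _abc_bundle(cogs=["COG0517"], nr_descs=["CBS domain protein"])
    call = apply_rules(bundle, flag_candidate(bundle), default_ruleset())
    assert call.excluded_by == "abc_non_transporter_cogs"
    reordered = RuleSet(rules=tuple(reversed(default_ruleset().rules)))
    call2 = apply_rules(bundle, flag_candidate(bundle), reordered)
    assert call2.excluded_by == "abc_nr_keywords"


def test_rule_outside_scope_never_changes_calls():
    """Adding a rule scoped to an unseen accession is a no-op."""
    rng = random.Random(56)
    base = default_ruleset()
    extended = RuleSet(
        rules=base.rules
        + (
            NegativeRule(
                "other_family", frozenset({"PF99999"}), "cog_exclusion",
                ("COG0178", "COG3839"),
            ),
        ),
        nr_top_k=base.nr_top_k,
    )
    for _ in range(100):
        bundle = random_built_bundle(rng)
        candidate = flag_candidate(bundle)
        assert apply_rules(bundle, candidate, base) == apply_rules(bundle, candidate, extended)


def test_cpa3_style_confusable_not_excluded_by_default_ruleset():
    """Antiporter-subunit lookalikes carry no PF00005, so no rule arms:
    the classic false-positive path stays open by design."""
    bundle = _abc_bundle(
        with_pf00005=False,
        curated=["TDBCPA001"],
        nr_descs=["NADH-quinone oxidoreductase subunit N"],
    )
    call = apply_rules(bundle, flag_candidate(bundle), default_ruleset())
    assert call.status == "retained"


def test_apply_rules_matches_bruteforce_oracle():
    rng = random.Random(77)
    ruleset = default_ruleset()
    for _ in range(300):
        bundle = random_built_bundle(rng)
        candidate = flag_candidate(bundle)
        call = apply_rules(bundle, candidate, ruleset)
        assert (call.status, call.excluded_by, call.matched_payload) == oracle_apply(
            bundle, candidate, ruleset
        )
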