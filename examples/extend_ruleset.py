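"""Inspect the shipped negative ruleset and extend it with a custom rule.

Prints the built-in ABC exclusion rules, adds a user rule for a second
profile, and shows a candidate being deleted by the new rule.
"""

from transaap import NegativeRule, RuleSet, apply_rules, default_ruleset
from transaap.evidence import build_bundles, flag_candidate
from transaap.io import CogHit, DomainHit, ProteinRecord

ruleset = default_ruleset()
for rule in ruleset.rules:
    print(f"{rule.rule_id}: scope={sorted(rule.scope_accessions)} "
          f"{rule.rule_kind} payload size={len(rule.payload)}")

# Extend: treat ArsA-like ATPase COG hits on a hypothetical profile as
# non-transporter evidence.
extended = RuleSet(
    rules=ruleset.rules + (
        NegativeRule(
            rule_id="custom_arsa_like",
            scope_accessions=frozenset({"PF02374"}),
            rule_kind="cog_exclusion",
            payload=("COG0003",),
            description="anion-pump ATPase lookalikes",
        ),
    ),
    nr_top_k=ruleset.nr_top_k,
)

protein = ProteinRecord("cand1", "", "MKTAAAGGHH")
[bundle] = build_bundles(
    [protein],
    domains=[DomainHit("cand1", "PF02374", "ArsA_ATPase", 1e-12, 90.0, 1, 60)],
    cogs=[CogHit("cand1", "COG0003", 1e-30, 200.0)],
)
call = apply_rules(bundle, flag_candidate(bundle), extended)
print(f"\ncand1 -> {call.status} (rule {call.excluded_by}, matched {call.matched_payload})")

# The default ruleset would have retained cand1 (its rules are scoped to
# PF00005); the custom rule arms on PF02374 and fires on COG0003.
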