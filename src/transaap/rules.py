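"""The negative decision tree: declarative post-filters on candidate proteins.

The candidate union is intentionally promiscuous — the conserved
ATP-binding-cassette profile PF00005, for instance, matches not only ABC
transporter ATPases but also excinucleases (UvrA), chromosome
segregation/partitioning ATPases (Smc, Soj, Mrp, RecF, SbcC) and
CBS-domain regulators. Negative rules delete those candidates again: each
rule is *armed* by a set of profile accessions and *fires* on either a COG
hit from its exclusion payload or a keyword in the descriptions of the top
NR alignment hits. The shipped default ruleset encodes the ABC
(ATP-binding cassette) exclusions; rulesets are user-extensible via a YAML
file so further families can be filtered the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evidence import CandidateStatus, EvidenceBundle

RULE_KINDS = ("cog_exclusion", "keyword_exclusion")

STATUS_RETAINED = "retained"
STATUS_EXCLUDED = "excluded"
STATUS_NEVER_CANDIDATE = "never_candidate"


@dataclass(frozen=True)
class NegativeRule:
    """One exclusion rule.

    scope_accessions: profile accessions that arm the rule (the rule can
    only touch proteins with a threshold-passing domain hit in scope).
    payload: COG accessions (``cog_exclusion``) or keyword strings
    (``keyword_exclusion``, case-insensitive substring match against NR hit
    descriptions).
    """

    rule_id: str
    scope_accessions: frozenset[str]
    rule_kind: str
    payload: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if self.rule_kind not in RULE_KINDS:
            raise ValueError(f"unknown rule_kind {self.rule_kind!r}")
        if not self.payload:
            raise ValueError("rule payload must be non-empty")
        if not self.scope_accessions:
            raise ValueError("rule scope must be non-empty")


@dataclass(frozen=True)
class RuleSet:
    """Ordered rules plus the NR-description scan depth (first fire wins)."""

    rules: tuple[NegativeRule, ...]
    nr_top_k: int = 5

    def __post_init__(self):
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise ValueError("rule_ids must be unique")
        if self.nr_top_k < 1:
            raise ValueError("nr_top_k must be >= 1")


@dataclass(frozen=True)
class TransporterCall:
    """Post-filter verdict for one protein."""

    protein_id: str
    status: str
    triggering_tracks: tuple[str, ...] = ()
    excluded_by: str | None = None
    matched_payload: str | None = None

    def __post_init__(self):
        if (self.status == STATUS_EXCLUDED) != (self.excluded_by is not None):
            raise ValueError("excluded_by must be present exactly when status is excluded")


# Non-transporter ATPase and CBS-domain COGs that share the ABC_tran
# (PF00005) nucleotide-binding profile.
_ABC_EXCLUSION_COGS = (
    "COG0178",  # UvrA, excinuclease ATPase subunit
    "COG1196",  # Smc, chromosome segregation ATPase
    "COG1106",  # predicted ATPase
    "COG1195",  # RecF, recombinational DNA repair ATPase
    "COG0419",  # SbcC, ATPase involved in DNA repair
    "COG3910",  # predicted ATPase
    "COG1192",  # Soj, chromosome partitioning ATPase
    "COG0489",  # Mrp, chromosome partitioning ATPase
    "COG2524",  # predicted transcriptional regulator with CBS domains
    "COG2905",  # signal-transduction protein with cAMP-binding and CBS domains
    "COG4109",  # predicted transcriptional regulator with CBS domains
    "COG0517",  # FOG: CBS domain
)

_ABC_EXCLUSION_KEYWORDS = (
    "cAMP-binding",
    "CBS domain",
    "Chromosome partition",
    "Cytochrome c assembly",
    "Cytochrome c biogenesis",
    "Excinuclease",
    "RNase L inhibitor",
    "UvrABC",
)


def default_ruleset() -> RuleSet:
    """The shipped ABC (ATP-binding cassette) negative ruleset.

    Two rules, both armed by a passing PF00005 domain hit: a COG exclusion
    for the non-transporter ATPase / CBS-domain COGs, and a keyword
    exclusion scanned against the top NR hit descriptions.
    """
    return RuleSet(
        rules=(
            NegativeRule(
                rule_id="abc_non_transporter_cogs",
                scope_accessions=frozenset({"PF00005"}),
                rule_kind="cog_exclusion",
                payload=_ABC_EXCLUSION_COGS,
                description=(
                    "PF00005 candidates also hitting COGs of non-transporter "
                    "ATPases or CBS-domain regulators are deleted"
                ),
            ),
            NegativeRule(
                rule_id="abc_nr_keywords",
                scope_accessions=frozenset({"PF00005"}),
                rule_kind="keyword_exclusion",
                payload=_ABC_EXCLUSION_KEYWORDS,
                description=(
                    "PF00005 candidates whose top NR hit descriptions contain "
                    "non-transporter keywords are deleted"
                ),
            ),
        ),
        nr_top_k=5,
    )


def apply_rules(
    bundle: EvidenceBundle, candidate: CandidateStatus, ruleset: RuleSet
) -> TransporterCall:
    """Run the negative decision tree over one candidate.

    Non-candidates pass through untouched. For candidates, rules are
    evaluated in ruleset order and the first firing rule wins: a rule is
    armed iff any of its scope accessions is among the protein's
    threshold-passing domain hits; an armed ``cog_exclusion`` fires on any
    payload COG among the threshold-passing COG hits; an armed
    ``keyword_exclusion`` fires on a case-insensitive substring match of
    any payload keyword in the description of one of the top ``nr_top_k``
    NR hits by bitscore.
    """
    pid = bundle.protein.protein_id
    if not candidate.is_candidate:
        return TransporterCall(protein_id=pid, status=STATUS_NEVER_CANDIDATE)

    passing_accessions = bundle.passing_domain_accessions()
    for rule in ruleset.rules:
        if not (rule.scope_accessions & passing_accessions):
            continue
        matched = _fire(rule, bundle, ruleset.nr_top_k)
        if matched is not None:
            return TransporterCall(
                protein_id=pid,
                status=STATUS_EXCLUDED,
                triggering_tracks=candidate.triggering_tracks,
                excluded_by=rule.rule_id,
                matched_payload=matched,
            )
    return TransporterCall(
        protein_id=pid,
        status=STATUS_RETAINED,
        triggering_tracks=candidate.triggering_tracks,
    )


def _fire(rule: NegativeRule, bundle: EvidenceBundle, nr_top_k: int) -> str | None:
    """Return the payload element that fires, or None."""
    if rule.rule_kind == "cog_exclusion":
        passing = bundle.passing_cog_ids()
        for cog in rule.payload:
            if cog in passing:
                return cog
        return None
    # keyword_exclusion: NR hits are pre-sorted by descending bitscore
    top_hits = bundle.blast_hits.get("nr", [])[:nr_top_k]
    for hit in top_hits:
        desc = hit.subject_description.lower()
        for keyword in rule.payload:
            if keyword.lower() in desc:
                return keyword
    return None


# ---------------------------------------------------------------------------
# Ruleset file format (YAML)
# ---------------------------------------------------------------------------


def save_ruleset(ruleset: RuleSet, path) -> None:
    """Serialize a ruleset to the YAML rules-file format."""
    doc = {
        "nr_top_k": ruleset.nr_top_k,
        "rules": [
            {
                "rule_id": r.rule_id,
                "scope": sorted(r.scope_accessions),
                "kind": r.rule_kind,
                "payload": list(r.payload),
                "description": r.description,
            }
            for r in ruleset.rules
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_ruleset(path) -> RuleSet:
    """Load a ruleset from the YAML rules-file format."""
    with open(Path(path)) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "rules" not in doc:
        raise ValueError(f"{path}: rules file must be a mapping with a 'rules' list")
    rules = tuple(
        NegativeRule(
            rule_id=str(r["rule_id"]),
            scope_accessions=frozenset(str(s) for s in r["scope"]),
            rule_kind=str(r["kind"]),
            payload=tuple(str(p) for p in r["payload"]),
            description=str(r.get("description", "")),
        )
        for r in doc["rules"]
    )
    return RuleSet(rules=rules, nr_top_k=int(doc.get("nr_top_k", 5)))
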