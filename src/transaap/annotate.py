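"""Family/TC classification and tiered substrate prediction with abstention.

Retained transporters are classified by homology transfer from the best
curated reference hit: family, subfamily and Transporter Classification
(TC) number are copied from the reference entry; substrate predictions are
tiered — a close hit transfers the specific substrate ("maltose"), a more
distant one only the general class ("sugars"), and anything weaker
abstains. When in doubt, no substrate call is made.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .evidence import (
    EvidenceBundle,
    Thresholds,
    build_bundles,
    flag_candidate,
    DEFAULT_TRANSPORTER_COGS,
)
from .io import (
    CogHit,
    DomainHit,
    ProteinRecord,
    ReferenceEntry,
    SearchHit,
)
from .rules import (
    RuleSet,
    STATUS_RETAINED,
    TransporterCall,
    apply_rules,
    default_ruleset,
)
from .tm import HydropathyParams, TmTopology, predict_topology

#: Minimal profile-accession -> transporter-family fallback map, used when
#: no curated/TCDB hit resolves. User-extensible.
DEFAULT_PROFILE_FAMILY_MAP = {"PF00005": "ABC"}

CONFIDENCE_HIGH = "high"
CONFIDENCE_MEDIUM = "medium"
CONFIDENCE_LOW = "low"


@dataclass(frozen=True)
class TransferTiers:
    """Identity/coverage cutoffs for the two substrate-transfer tiers.

    At or above the *specific* tier both the named substrate and its class
    transfer; at the *class* tier only the general class transfers; below
    it the prediction abstains. Unknown coverage fails every coverage
    cutoff.
    """

    specific_min_identity: float = 60.0
    specific_min_coverage: float = 70.0
    class_min_identity: float = 30.0
    class_min_coverage: float = 50.0

    def __post_init__(self):
        if (
            self.specific_min_identity < self.class_min_identity
            or self.specific_min_coverage < self.class_min_coverage
        ):
            raise ValueError("specific tier thresholds must be >= class tier thresholds")


@dataclass(frozen=True)
class Annotation:
    """Final per-protein call."""

    protein_id: str
    status: str
    family: str | None = None
    subfamily: str | None = None
    tc_number: str | None = None
    substrate_class: str | None = None
    substrate: str | None = None
    confidence: str | None = None
    tm_count: int = 0
    evidence_summary: str = ""
    excluded_by: str | None = None

    def __post_init__(self):
        if self.substrate is not None and self.substrate_class is None:
            raise ValueError("a specific substrate requires a substrate class")
        if self.status != STATUS_RETAINED and (
            self.family or self.substrate_class or self.substrate
        ):
            raise ValueError("only retained proteins carry classification fields")


def best_reference_hit(
    bundle: EvidenceBundle, reference: Mapping[str, ReferenceEntry]
) -> tuple[SearchHit, ReferenceEntry] | None:
    """The best resolvable curated/TCDB hit for homology transfer.

    Highest bitscore among threshold-passing hits on the curated and TCDB
    tracks whose subject resolves in the reference table; ties broken by
    lower E-value, then lexicographic subject id.
    """
    candidates = [
        h
        for track in ("curated_tdb", "tcdb")
        for h in bundle.passing_blast_hits(track)
        if h.subject_id in reference
    ]
    if not candidates:
        return None
    best = min(candidates, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return best, reference[best.subject_id]


def assign_classification(
    bundle: EvidenceBundle,
    best: tuple[SearchHit, ReferenceEntry] | None,
    profile_family_map: Mapping[str, str] = DEFAULT_PROFILE_FAMILY_MAP,
) -> tuple[str, str | None, str | None]:
    """(family, subfamily, tc_number) for a retained protein.

    Copied from the best reference entry when available; otherwise a
    passing transporter-family profile maps to its family (no TC number);
    otherwise ``unclassified``.
    """
    if best is not None:
        entry = best[1]
        return entry.family, entry.subfamily, entry.tc_number
    passing = bundle.passing_domain_accessions()
    for accession in sorted(passing):
        if accession in profile_family_map:
            return profile_family_map[accession], None, None
    return "unclassified", None, None


def predict_substrate(
    best: tuple[SearchHit, ReferenceEntry] | None,
    tiers: TransferTiers = TransferTiers(),
) -> tuple[str | None, str | None]:
    """(substrate_class, substrate), either of which may abstain (None).

    Specific tier: identity and coverage at or above the specific cutoffs
    transfer both the named substrate and its class. Class tier: only the
    general class transfers. Otherwise, or when coverage is unknown per
    the cutoff in question, abstain. Missing reference fields propagate as
    abstention at that level.
    """
    if best is None:
        return None, None
    hit, entry = best
    identity = hit.percent_identity
    coverage = hit.query_coverage

    def meets(min_id: float, min_cov: float) -> bool:
        return identity >= min_id and coverage is not None and coverage >= min_cov

    if meets(tiers.specific_min_identity, tiers.specific_min_coverage):
        if entry.substrate is not None and entry.substrate_class is not None:
            return entry.substrate_class, entry.substrate
        return entry.substrate_class, None
    if meets(tiers.class_min_identity, tiers.class_min_coverage):
        return entry.substrate_class, None
    return None, None


def _confidence(
    call: TransporterCall,
    best: tuple[SearchHit, ReferenceEntry] | None,
    tiers: TransferTiers,
) -> str:
    if call.triggering_tracks == ("tm",):
        return CONFIDENCE_LOW
    if best is not None:
        hit = best[0]
        if (
            hit.percent_identity >= tiers.specific_min_identity
            and hit.query_coverage is not None
            and hit.query_coverage >= tiers.specific_min_coverage
        ):
            return CONFIDENCE_HIGH
    return CONFIDENCE_MEDIUM


def _evidence_summary(bundle: EvidenceBundle) -> str:
    """Compact per-track digest of the passing evidence."""
    parts = []
    for track in ("curated_tdb", "tcdb", "nr"):
        passing = bundle.passing_blast_hits(track)
        if passing:
            top = passing[0]
            parts.append(f"{track}:{top.subject_id}(id={top.percent_identity:.0f},E={top.evalue:.0e})")
    doms = bundle.passing_domain_hits()
    if doms:
        parts.append("hmm:" + "+".join(sorted({d.model_accession for d in doms})))
    cogs = sorted(bundle.passing_cog_ids() & bundle.transporter_cogs)
    if cogs:
        parts.append("cog:" + "+".join(cogs))
    if bundle.track_pass.get("tm"):
        parts.append(f"tm:{bundle.topology.tm_count}")
    return ";".join(parts)


def annotate_bundle(
    bundle: EvidenceBundle,
    reference: Mapping[str, ReferenceEntry],
    ruleset: RuleSet,
    tiers: TransferTiers = TransferTiers(),
    profile_family_map: Mapping[str, str] = DEFAULT_PROFILE_FAMILY_MAP,
) -> Annotation:
    """Candidacy -> negative rules -> classification -> substrate, one protein."""
    candidate = flag_candidate(bundle)
    call = apply_rules(bundle, candidate, ruleset)
    tm_count = bundle.topology.tm_count
    if call.status != STATUS_RETAINED:
        return Annotation(
            protein_id=call.protein_id,
            status=call.status,
            tm_count=tm_count,
            evidence_summary=_evidence_summary(bundle),
            excluded_by=call.excluded_by,
        )
    best = best_reference_hit(bundle, reference)
    family, subfamily, tc_number = assign_classification(bundle, best, profile_family_map)
    substrate_class, substrate = predict_substrate(best, tiers)
    return Annotation(
        protein_id=call.protein_id,
        status=STATUS_RETAINED,
        family=family,
        subfamily=subfamily,
        tc_number=tc_number,
        substrate_class=substrate_class,
        substrate=substrate,
        confidence=_confidence(call, best, tiers),
        tm_count=tm_count,
        evidence_summary=_evidence_summary(bundle),
    )


def annotate_proteome(
    proteome: Iterable[ProteinRecord],
    hits: Iterable[SearchHit] = (),
    domains: Iterable[DomainHit] = (),
    cogs: Iterable[CogHit] = (),
    topologies: Mapping[str, TmTopology] | None = None,
    reference: Mapping[str, ReferenceEntry] | None = None,
    ruleset: RuleSet | None = None,
    thresholds: Thresholds | None = None,
    tiers: TransferTiers = TransferTiers(),
    tm_params: HydropathyParams = HydropathyParams(),
    profile_family_map: Mapping[str, str] = DEFAULT_PROFILE_FAMILY_MAP,
    transporter_cogs: frozenset[str] = DEFAULT_TRANSPORTER_COGS,
) -> list[Annotation]:
    """Run the full pipeline over a proteome; output order = input order.

    When ``topologies`` is None the built-in hydropathy predictor is run on
    every protein; otherwise the supplied (e.g. externally predicted)
    topologies are used as-is.
    """
    proteome = list(proteome)
    if topologies is None:
        topologies = {p.protein_id: predict_topology(p, tm_params) for p in proteome}
    bundles = build_bundles(
        proteome, hits, domains, cogs, topologies,
        thresholds or Thresholds(), transporter_cogs,
    )
    ruleset = ruleset if ruleset is not None else default_ruleset()
    reference = reference or {}
    return [
        annotate_bundle(b, reference, ruleset, tiers, profile_family_map)
        for b in bundles
    ]
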