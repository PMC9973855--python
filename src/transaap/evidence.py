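"""Per-protein evidence aggregation and the mutually-inclusive candidate rule.

All search tracks feed one union: a protein is nominated as a candidate
transporter when ANY track produces evidence above its threshold —
curated-database, TCDB or NR protein alignments, transporter profile-HMM
domains, an allowlisted transporter COG, or (optionally) a membrane-protein-
like topology on its own. The union is deliberately promiscuous; false
positives are dealt with downstream by the negative rule engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io import ALL_TRACKS, BLAST_TRACKS, CogHit, DomainHit, ProteinRecord, SearchHit
from .tm import TmTopology

logger = logging.getLogger(__name__)

#: COGs accepted as *positive* transporter evidence. Deliberately minimal:
#: a COG hit only nominates a candidate when the COG itself describes a
#: transporter component. Exclusion-list COGs are handled by the rule
#: engine and must never nominate.
DEFAULT_TRANSPORTER_COGS = frozenset(
    {
        "COG0477",  # MFS permease
        "COG0531",  # amino acid transporter
        "COG1175",  # ABC sugar transport, permease component
        "COG3839",  # ABC sugar transport, ATPase component
        "COG1176",  # ABC polyamine transport, permease component
        "COG0025",  # NhaP-type Na+/H+ and K+/H+ antiporter
        "COG1055",  # anion permease ArsB/NhaD
        "COG0168",  # Trk-type K+ transport
        "COG2211",  # Na+/melibiose symporter
        "COG0697",  # permease of the drug/metabolite transporter superfamily
    }
)


@dataclass(frozen=True)
class Thresholds:
    """Per-track evidence thresholds.

    E-value ceilings gate the alignment/profile tracks; ``tm_standalone_min``
    is the minimum predicted TM segment count for topology alone to nominate
    a candidate (set above any realistic proteome size to disable).
    """

    blast_evalue_max: Mapping[str, float] = field(
        default_factory=lambda: {"curated_tdb": 1e-5, "tcdb": 1e-5, "nr": 1e-5}
    )
    hmm_domain_evalue_max: float = 1e-4
    cog_evalue_max: float = 1e-5
    tm_standalone_min: int = 6

    def __post_init__(self):
        for track in BLAST_TRACKS:
            if self.blast_evalue_max.get(track, 0) <= 0:
                raise ValueError(f"blast E-value ceiling for {track} must be > 0")
        if self.hmm_domain_evalue_max <= 0 or self.cog_evalue_max <= 0:
            raise ValueError("E-value ceilings must be > 0")
        if self.tm_standalone_min < 1:
            raise ValueError("tm_standalone_min must be >= 1")


@dataclass
class EvidenceBundle:
    """Everything the pipeline knows about one protein.

    Blast hits are grouped per track and sorted by descending bitscore;
    domain and COG hits by ascending E-value. ``track_pass[t]`` records
    whether at least one hit on track *t* meets its threshold (for ``tm``,
    whether the predicted segment count reaches the standalone minimum).
    """

    protein: ProteinRecord
    blast_hits: dict[str, list[SearchHit]]
    domain_hits: list[DomainHit]
    cog_hits: list[CogHit]
    topology: TmTopology
    thresholds: Thresholds
    transporter_cogs: frozenset[str] = DEFAULT_TRANSPORTER_COGS
    track_pass: dict[str, bool] = field(default_factory=dict)

    def passing_blast_hits(self, track: str) -> list[SearchHit]:
        ceiling = self.thresholds.blast_evalue_max[track]
        return [h for h in self.blast_hits.get(track, []) if h.evalue <= ceiling]

    def passing_domain_hits(self) -> list[DomainHit]:
        return [
            h for h in self.domain_hits
            if h.domain_evalue <= self.thresholds.hmm_domain_evalue_max
        ]

    def passing_domain_accessions(self) -> set[str]:
        return {h.model_accession for h in self.passing_domain_hits()}

    def passing_cog_hits(self) -> list[CogHit]:
        return [h for h in self.cog_hits if h.evalue <= self.thresholds.cog_evalue_max]

    def passing_cog_ids(self) -> set[str]:
        return {h.cog_id for h in self.passing_cog_hits()}


@dataclass(frozen=True)
class CandidateStatus:
    """Outcome of the mutually-inclusive union for one protein."""

    is_candidate: bool
    triggering_tracks: tuple[str, ...]

    def __post_init__(self):
        if self.is_candidate != bool(self.triggering_tracks):
            raise ValueError("is_candidate must equal (triggering_tracks non-empty)")


def _compute_track_pass(bundle: EvidenceBundle) -> dict[str, bool]:
    passes = {}
    for track in BLAST_TRACKS:
        passes[track] = bool(bundle.passing_blast_hits(track))
    passes["hmm"] = bool(bundle.passing_domain_hits())
    passes["cog"] = any(
        h.cog_id in bundle.transporter_cogs for h in bundle.passing_cog_hits()
    )
    passes["tm"] = bundle.topology.tm_count >= bundle.thresholds.tm_standalone_min
    return passes


def build_bundles(
    proteome: Iterable[ProteinRecord],
    hits: Iterable[SearchHit] = (),
    domains: Iterable[DomainHit] = (),
    cogs: Iterable[CogHit] = (),
    topologies: Mapping[str, TmTopology] | None = None,
    thresholds: Thresholds | None = None,
    transporter_cogs: frozenset[str] = DEFAULT_TRANSPORTER_COGS,
) -> list[EvidenceBundle]:
    """Group all evidence by protein into one bundle per proteome member.

    Evidence lines whose query id is not in the proteome are dropped with a
    logged warning. Every protein gets a bundle, possibly evidence-empty;
    proteins missing from ``topologies`` get an empty topology.
    """
    thresholds = thresholds or Thresholds()
    topologies = topologies or {}
    proteome = list(proteome)
    known = {p.protein_id for p in proteome}

    by_track: dict[str, dict[str, list[SearchHit]]] = {t: {} for t in BLAST_TRACKS}
    for h in hits:
        if h.query_id not in known:
            logger.warning("alignment hit for unknown protein %r dropped", h.query_id)
            continue
        by_track[h.source_track].setdefault(h.query_id, []).append(h)
    dom_by_query: dict[str, list[DomainHit]] = {}
    for d in domains:
        if d.query_id not in known:
            logger.warning("domain hit for unknown protein %r dropped", d.query_id)
            continue
        dom_by_query.setdefault(d.query_id, []).append(d)
    cog_by_query: dict[str, list[CogHit]] = {}
    for c in cogs:
        if c.query_id not in known:
            logger.warning("COG hit for unknown protein %r dropped", c.query_id)
            continue
        cog_by_query.setdefault(c.query_id, []).append(c)

    bundles = []
    for protein in proteome:
        pid = protein.protein_id
        blast = {
            track: sorted(
                by_track[track].get(pid, []),
                key=lambda h: (-h.bitscore, h.evalue, h.subject_id),
            )
            for track in BLAST_TRACKS
        }
        bundle = EvidenceBundle(
            protein=protein,
            blast_hits=blast,
            domain_hits=sorted(
                dom_by_query.get(pid, []),
                key=lambda d: (d.domain_evalue, -d.score, d.model_accession),
            ),
            cog_hits=sorted(
                cog_by_query.get(pid, []),
                key=lambda c: (c.evalue, -c.bitscore, c.cog_id),
            ),
            topology=topologies.get(pid, TmTopology(0, [])),
            thresholds=thresholds,
            transporter_cogs=transporter_cogs,
        )
        bundle.track_pass = _compute_track_pass(bundle)
        bundles.append(bundle)
    return bundles


def flag_candidate(bundle: EvidenceBundle) -> CandidateStatus:
    """Apply the mutually-inclusive union: any passing track nominates."""
    triggering = tuple(t for t in ALL_TRACKS if bundle.track_pass.get(t, False))
    return CandidateStatus(is_candidate=bool(triggering), triggering_tracks=triggering)
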