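"""Readers and writers for the external formats the pipeline touches.

Every downstream stage consumes only the domain records defined here:
proteins (FASTA), protein-vs-protein alignment hits (12+-column tabular,
the common blastp export), profile-HMM domain hits (HMMER3 per-domain
table), COG hits (tabular, rpsblast-style), transmembrane topology
summaries (TMHMM "short" one-line-per-protein output), the curated
reference-metadata table (TSV) and the final annotation table (TSV).

Conventions: residue coordinates are 1-based inclusive; accession version
suffixes (``PF00005.27`` -> ``PF00005``) are stripped on ingest; absent
values serialize as ``-``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The three protein-alignment reference tracks.
BLAST_TRACKS = ("curated_tdb", "tcdb", "nr")

#: All evidence tracks, in canonical reporting order.
ALL_TRACKS = ("curated_tdb", "tcdb", "nr", "hmm", "cog", "tm")

#: 20 standard residues plus the ambiguity/rare codes seen in real proteomes.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")

COG_PATTERN = re.compile(r"COG\d{4}")
TC_PATTERN = re.compile(r"^\d+\.[A-Za-z]\.\d+(\.\d+(\.\d+)?)?$")

MISSING = "-"


class ParseError(ValueError):
    """A malformed input file; carries the offending path and line number."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{self.path}:{lineno}" if lineno is not None else self.path
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id (first defline token), defline remainder, sequence."""

    protein_id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class SearchHit:
    """One protein-alignment hit on one of the three blastp tracks.

    ``query_coverage`` is percent of the query aligned; ``None`` means the
    input carried no coverage column and no query length was available to
    compute it — downstream, unknown coverage fails every coverage
    threshold (conservative).
    """

    query_id: str
    subject_id: str
    subject_description: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_coverage: float | None
    source_track: str

    def __post_init__(self):
        if self.source_track not in BLAST_TRACKS:
            raise ValueError(f"unknown source_track {self.source_track!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")
        if self.query_coverage is not None and not 0 <= self.query_coverage <= 100:
            raise ValueError("query_coverage outside [0, 100]")


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain hit (Pfam/TIGRFAM model vs protein)."""

    query_id: str
    model_accession: str
    model_name: str
    domain_evalue: float
    score: float
    env_start: int
    env_end: int

    def __post_init__(self):
        if self.domain_evalue < 0:
            raise ValueError("domain_evalue must be >= 0")
        if not 1 <= self.env_start <= self.env_end:
            raise ValueError("envelope coordinates must satisfy 1 <= start <= end")


@dataclass(frozen=True)
class CogHit:
    """One COG (cluster of orthologous groups) profile hit."""

    query_id: str
    cog_id: str
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not COG_PATTERN.fullmatch(self.cog_id):
            raise ValueError(f"malformed COG accession {self.cog_id!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class ReferenceEntry:
    """One row of the curated reference table used for homology transfer."""

    accession: str
    family: str
    subfamily: str | None = None
    tc_number: str | None = None
    substrate_class: str | None = None
    substrate: str | None = None

    def __post_init__(self):
        if self.tc_number is not None and not TC_PATTERN.match(self.tc_number):
            raise ValueError(f"malformed TC number {self.tc_number!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into an ordered list of records.

    The protein id is the first whitespace-delimited defline token; input
    order is preserved. Duplicate ids, empty files and residues outside the
    accepted alphabet are hard errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - AMINO_ALPHABET
        if bad:
            raise ParseError(
                path,
                _find_residue_line(path, rec.id, bad),
                f"illegal residue(s) {sorted(bad)} in record {rec.id!r}",
            )
        if not seq:
            raise ParseError(path, None, f"record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ParseError(path, None, f"duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        description = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, description, seq))
    if not records:
        raise ParseError(path, None, "no FASTA records found")
    return records


def _find_residue_line(path: Path, protein_id: str, bad: set[str]) -> int | None:
    """Locate the first sequence line of ``protein_id`` containing a bad residue."""
    current = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                current = line[1:].split()[0] if line[1:].split() else ""
            elif current == protein_id and set(line.strip().upper()) & bad:
                return lineno
    return None


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            defline = f">{rec.protein_id}"
            if rec.description:
                defline += f" {rec.description}"
            fh.write(defline + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular protein-alignment hits (blastp outfmt-6-style, 12+ columns)
# ---------------------------------------------------------------------------

# qseqid sseqid pident length mismatch gapopen qstart qend sstart send
# evalue bitscore [qcovs] [stitle]
_N_MANDATORY = 12


def read_tabular_hits(
    path,
    source_track: str,
    query_lengths: Mapping[str, int] | None = None,
) -> list[SearchHit]:
    """Read a 12+-column tabular alignment file into SearchHits.

    Coverage comes from the optional 13th column (qcovs); failing that it is
    computed as ``100*(qend-qstart+1)/query_length`` when ``query_lengths``
    is supplied, else recorded as unknown (``None``). The optional 14th
    column is the subject title. Lines starting with ``#`` are skipped.
    """
    path = Path(path)
    hits: list[SearchHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _N_MANDATORY:
                raise ParseError(
                    path, lineno,
                    f"expected >= {_N_MANDATORY} tab-separated columns, got {len(fields)}",
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric mandatory column: {exc}") from None
            coverage: float | None = None
            if len(fields) >= 13 and fields[12] not in ("", MISSING):
                try:
                    coverage = float(fields[12])
                except ValueError as exc:
                    raise ParseError(path, lineno, f"bad qcovs column: {exc}") from None
            elif query_lengths is not None and qseqid in query_lengths:
                coverage = 100.0 * (qend - qstart + 1) / query_lengths[qseqid]
            stitle = fields[13] if len(fields) >= 14 else ""
            try:
                hits.append(
                    SearchHit(
                        query_id=qseqid,
                        subject_id=sseqid,
                        subject_description=stitle,
                        percent_identity=pident,
                        alignment_length=length,
                        evalue=evalue,
                        bitscore=bitscore,
                        query_coverage=coverage,
                        source_track=source_track,
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return hits


def write_tabular_hits(hits: Iterable[SearchHit], path) -> None:
    """Write hits back to the 14-column tabular dialect (qcovs ``-`` if unknown)."""
    with open(path, "w") as fh:
        for h in hits:
            qcov = MISSING if h.query_coverage is None else f"{h.query_coverage:.3f}"
            span = max(h.alignment_length, 1)
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.3f}",
                        str(h.alignment_length),
                        "0",
                        "0",
                        "1",
                        str(span),
                        "1",
                        str(span),
                        f"{h.evalue:.3e}",
                        f"{h.bitscore:.1f}",
                        qcov,
                        h.subject_description,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# HMMER3 per-domain table (domtblout)
# ---------------------------------------------------------------------------

# hmmscan domtblout: 22 fixed whitespace-delimited columns, then free-text
# description. Column indices (0-based): 0 target name, 1 target accession,
# 3 query name, 12 i-Evalue, 13 domain score, 19 env from, 20 env to.
_DOMTBL_FIXED = 22


def _strip_version(accession: str) -> str:
    return accession.rsplit(".", 1)[0] if re.search(r"\.\d+$", accession) else accession


def read_domain_table(path) -> list[DomainHit]:
    """Read a HMMER3 per-domain table (hmmscan domtblout dialect).

    The target (model) accession is version-stripped; when it is ``-`` the
    model name stands in. The independent (i-)E-value is used as the
    per-domain E-value.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(None, _DOMTBL_FIXED)
            if len(fields) < _DOMTBL_FIXED:
                raise ParseError(
                    path, lineno,
                    f"expected >= {_DOMTBL_FIXED} columns in per-domain table, got {len(fields)}",
                )
            model_name = fields[0]
            accession = fields[1]
            if accession == MISSING:
                accession = model_name
            try:
                hit = DomainHit(
                    query_id=fields[3],
                    model_accession=_strip_version(accession),
                    model_name=model_name,
                    domain_evalue=float(fields[12]),
                    score=float(fields[13]),
                    env_start=int(fields[19]),
                    env_end=int(fields[20]),
                )
            except ValueError as exc:
                raise ParseError(path, lineno, f"malformed fixed column: {exc}") from None
            hits.append(hit)
    return hits


def write_domain_table(hits: Iterable[DomainHit], path) -> None:
    """Write DomainHits in the hmmscan per-domain table layout."""
    header = (
        "#                                                                            "
        "--- full sequence --- -------------- this domain -------------   hmm coord   "
        "ali coord   env coord\n"
        "# target name        accession   tlen query name           accession   qlen"
        "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
        "  from    to  from    to  acc description of target\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for h in hits:
            span = h.env_end - h.env_start + 1
            fh.write(
                f"{h.model_name:<20s} {h.model_accession:<11s} {span:4d} "
                f"{h.query_id:<20s} {MISSING:<11s} {h.env_end:4d} "
                f"{h.domain_evalue:9.2e} {h.score:6.1f}   0.0   1   1 "
                f"{h.domain_evalue:9.2e} {h.domain_evalue:9.2e} {h.score:6.1f}   0.0 "
                f"{1:5d} {span:5d} {h.env_start:5d} {h.env_end:5d} "
                f"{h.env_start:5d} {h.env_end:5d}  0.90 -\n"
            )


# ---------------------------------------------------------------------------
# COG hits
# ---------------------------------------------------------------------------


def read_cog_hits(path) -> list[CogHit]:
    """Read a tabular COG hit file (rpsblast-style export).

    The COG accession is extracted from the subject field, which may carry
    it directly (``COG0178``) or embedded (``gnl|CDD|223256 COG0178``).
    Lines with no extractable accession are skipped with a logged warning.
    """
    path = Path(path)
    hits: list[CogHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _N_MANDATORY:
                raise ParseError(
                    path, lineno,
                    f"expected >= {_N_MANDATORY} tab-separated columns, got {len(fields)}",
                )
            match = COG_PATTERN.search(fields[1])
            if match is None and len(fields) >= 14:
                match = COG_PATTERN.search(fields[13])
            if match is None:
                logger.warning(
                    "%s:%d: no COG accession in subject %r; line skipped",
                    path, lineno, fields[1],
                )
                continue
            try:
                hits.append(
                    CogHit(
                        query_id=fields[0],
                        cog_id=match.group(0),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric mandatory column: {exc}") from None
    return hits


# ---------------------------------------------------------------------------
# TMHMM "short" output
# ---------------------------------------------------------------------------

_TOPO_SEGMENT = re.compile(r"(\d+)-(\d+)")


def read_tm_short(path) -> dict[str, "TmTopology"]:
    """Read a TMHMM short-format file: one summary line per protein.

    Lines look like ``p1 len=450 ExpAA=110.2 First60=0.1 PredHel=5
    Topology=i12-34o56-78i...``. Returns a mapping protein id -> topology;
    segment boundaries are 1-based inclusive.
    """
    from .tm import TmTopology  # local import: tm module depends on io types

    path = Path(path)
    out: dict[str, TmTopology] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            protein_id = fields[0]
            kv = {}
            for f in fields[1:]:
                if "=" in f:
                    k, _, v = f.partition("=")
                    kv[k] = v
            if "PredHel" not in kv:
                raise ParseError(path, lineno, "missing PredHel field")
            try:
                tm_count = int(kv["PredHel"])
            except ValueError:
                raise ParseError(path, lineno, f"bad PredHel value {kv['PredHel']!r}") from None
            segments = [
                (int(a), int(b)) for a, b in _TOPO_SEGMENT.findall(kv.get("Topology", ""))
            ]
            if len(segments) != tm_count:
                raise ParseError(
                    path, lineno,
                    f"PredHel={tm_count} but topology string has {len(segments)} segments",
                )
            out[protein_id] = TmTopology(tm_count=tm_count, segments=segments)
    return out


def write_tm_short(topologies: Mapping[str, "TmTopology"], lengths: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for pid, topo in topologies.items():
            parts, state = [], "i"
            for a, b in topo.segments:
                parts.append(f"{state}{a}-{b}")
                state = "o" if state == "i" else "i"
            topo_str = "".join(parts) + state if parts else "o"
            exp_aa = sum(b - a + 1 for a, b in topo.segments)
            fh.write(
                f"{pid}\tlen={lengths[pid]}\tExpAA={exp_aa:.2f}\tFirst60=0.00\t"
                f"PredHel={topo.tm_count}\tTopology={topo_str}\n"
            )


# ---------------------------------------------------------------------------
# Reference table, gold standard, annotation TSV
# ---------------------------------------------------------------------------


def _opt(value: str) -> str | None:
    value = value.strip()
    return None if value in ("", MISSING) else value


REFERENCE_COLUMNS = ("accession", "family", "subfamily", "tc_number", "substrate_class", "substrate")


def read_reference_table(path) -> dict[str, ReferenceEntry]:
    """Read the curated reference-metadata TSV (accession -> entry)."""
    path = Path(path)
    entries: dict[str, ReferenceEntry] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if tuple(h.strip() for h in header) != REFERENCE_COLUMNS:
            raise ParseError(path, 1, f"expected header {list(REFERENCE_COLUMNS)}, got {header}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(REFERENCE_COLUMNS):
                raise ParseError(path, lineno, f"expected {len(REFERENCE_COLUMNS)} columns")
            accession = fields[0].strip()
            if accession in entries:
                raise ParseError(path, lineno, f"duplicate reference accession {accession!r}")
            try:
                entries[accession] = ReferenceEntry(
                    accession=accession,
                    family=fields[1].strip(),
                    subfamily=_opt(fields[2]),
                    tc_number=_opt(fields[3]),
                    substrate_class=_opt(fields[4]),
                    substrate=_opt(fields[5]),
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return entries


def write_reference_table(entries: Iterable[ReferenceEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REFERENCE_COLUMNS) + "\n")
        for e in entries:
            fh.write(
                "\t".join(
                    [
                        e.accession,
                        e.family,
                        e.subfamily or MISSING,
                        e.tc_number or MISSING,
                        e.substrate_class or MISSING,
                        e.substrate or MISSING,
                    ]
                )
                + "\n"
            )


ANNOTATION_COLUMNS = (
    "protein_id",
    "status",
    "family",
    "subfamily",
    "tc_number",
    "substrate_class",
    "substrate",
    "confidence",
    "tm_count",
    "evidence_summary",
    "excluded_by",
)


def write_annotations(annotations, path, provenance: Sequence[str] = ()) -> None:
    """Write the annotation table as TSV (absent values as ``-``).

    ``provenance`` lines are emitted first as ``#``-prefixed comments so a
    run's parameters travel with its output.
    """
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for a in annotations:
            fh.write(
                "\t".join(
                    [
                        a.protein_id,
                        a.status,
                        a.family or MISSING,
                        a.subfamily or MISSING,
                        a.tc_number or MISSING,
                        a.substrate_class or MISSING,
                        a.substrate or MISSING,
                        a.confidence or MISSING,
                        str(a.tm_count),
                        a.evidence_summary or MISSING,
                        a.excluded_by or MISSING,
                    ]
                )
                + "\n"
            )


def read_annotations(path):
    """Read an annotation TSV back into Annotation records."""
    from .annotate import Annotation  # annotate depends on io; import locally

    path = Path(path)
    annotations = []
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if tuple(fields) != ANNOTATION_COLUMNS:
                    raise ParseError(path, lineno, f"unexpected annotation header {fields}")
                header = fields
                continue
            if len(fields) != len(ANNOTATION_COLUMNS):
                raise ParseError(path, lineno, f"expected {len(ANNOTATION_COLUMNS)} columns")
            try:
                tm_count = int(fields[8])
            except ValueError:
                raise ParseError(path, lineno, f"bad tm_count {fields[8]!r}") from None
            annotations.append(
                Annotation(
                    protein_id=fields[0],
                    status=fields[1],
                    family=_opt(fields[2]),
                    subfamily=_opt(fields[3]),
                    tc_number=_opt(fields[4]),
                    substrate_class=_opt(fields[5]),
                    substrate=_opt(fields[6]),
                    confidence=_opt(fields[7]),
                    tm_count=tm_count,
                    evidence_summary=_opt(fields[9]) or "",
                    excluded_by=_opt(fields[10]),
                )
            )
    if header is None:
        raise ParseError(path, None, "no header line found")
    return annotations
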