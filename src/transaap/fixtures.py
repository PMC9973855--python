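"""Deterministic synthetic proteome + evidence generator.

Builds a complete, internally consistent input set for the pipeline:
proteome FASTA, curated reference table, gold standard, alignment hits on
all three tracks, a profile-HMM domain table, COG hits and a TM-topology
summary — with planted ground truth per protein recorded in a manifest.

Planted scenarios cover the pipeline's decision space:

* ABC transporter ATP-binding subunits — passing PF00005 + curated hits at
  identities drawn per a specific/class/abstain tier mixture, no exclusion
  evidence; soluble (no TM runs).
* MFS-like transporters — curated hits at the specific tier plus 12
  planted membrane-spanning hydrophobic runs.
* UvrA-like decoys — passing PF00005 plus the excinuclease COG (COG0178)
  and "excinuclease" NR descriptions: the COG exclusion rule must delete
  them.
* CBS-domain decoys — passing PF00005 plus either a CBS-domain COG or a
  "CBS domain" NR description: either exclusion route must delete them.
* CPA3-like confusables — curated hits to a cation:proton antiporter
  reference plus NADH-oxidoreductase NR descriptions and no PF00005: the
  shipped ruleset cannot exclude them (the classic false-positive
  anatomy, toggled in/out of the gold standard).
* Low-identity membrane subunits — only sub-threshold alignment hits and
  too few TM segments to qualify standalone: planted false negatives.
* Background — polar sequences with no passing evidence.

Evidence values are planted directly rather than produced by running
search engines, with a x10 guard margin around every threshold so no
generated value sits on a decision boundary. Identical seeds give
byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .io import (
    CogHit,
    DomainHit,
    ProteinRecord,
    ReferenceEntry,
    SearchHit,
    write_domain_table,
    write_fasta,
    write_reference_table,
    write_tabular_hits,
    write_tm_short,
)
from .evaluate import GoldStandard, write_gold_standard
from .tm import TmTopology

# Residue pools chosen so topology is unambiguous under the default
# hydropathy parameters for ANY seed: the polar pool's most hydrophobic
# residue (P, -1.6) keeps every windowed mean far below threshold, and the
# hydrophobic pool's least hydrophobic residue (F, 2.8) keeps planted runs
# recoverable at full count.
POLAR_POOL = "DEKRNQHP"
HYDROPHOBIC_POOL = "LIVF"

TM_SEGMENT_LEN = 28
LOOP_LEN = 30

CATEGORIES = (
    "abc", "mfs", "uvra_decoy", "cbs_decoy", "cpa3",
    "membrane_subunit", "tm_only", "background",
)

TIER_SPECIFIC = "specific"
TIER_CLASS = "class"
TIER_ABSTAIN = "abstain"


@dataclass(frozen=True)
class FixtureSpec:
    """Counts, seed and substrate-tier mixture for one generated proteome.

    ``tier_mix`` gives the fractions of ABC transporters whose curated-hit
    identities land in the specific-transfer, class-only and abstention
    tiers (must sum to 1). ``cpa3_in_gold`` controls whether the CPA3-like
    confusables count as true transporters in the gold standard.
    """

    n_abc_transporters: int = 50
    n_mfs_like: int = 10
    n_uvra_decoys: int = 10
    n_cbs_decoys: int = 5
    n_cpa3_confusables: int = 5
    n_membrane_subunits_lowid: int = 5
    n_background: int = 30
    seed: int = 42
    tier_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)
    cpa3_in_gold: bool = True

    def __post_init__(self):
        if abs(sum(self.tier_mix) - 1.0) > 1e-9:
            raise ValueError("tier_mix must sum to 1")
        for name in (
            "n_abc_transporters", "n_mfs_like", "n_uvra_decoys", "n_cbs_decoys",
            "n_cpa3_confusables", "n_membrane_subunits_lowid", "n_background",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ManifestRow:
    """Planted ground truth for one generated protein."""

    protein_id: str
    category: str
    tier: str | None
    reference_accession: str | None
    planted_substrate: str | None
    tm_count: int
    expected_status: str
    expected_rule: str | None


@dataclass
class FixtureBundle:
    """Paths to one generated input set, plus its in-memory manifest."""

    out_dir: Path
    proteome_path: Path
    reference_path: Path
    gold_path: Path
    blast_paths: dict[str, Path]
    domain_path: Path
    cog_path: Path
    tm_path: Path
    manifest_path: Path
    manifest: list[ManifestRow] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Reference catalog
# ---------------------------------------------------------------------------

_ABC_SUBSTRATES = [
    ("CUT1", "sugars", "maltose"),
    ("CUT1", "sugars", "galactose"),
    ("PAAT", "amino acids", "histidine"),
    ("PAAT", "amino acids", "arginine"),
    ("PepT", "peptides", "dipeptide"),
    ("MZT", "metal ions", "zinc"),
    ("MZT", "metal ions", "manganese"),
    ("SulT", "anions", "sulfate"),
    ("PhoT", "anions", "phosphate"),
    ("ThiT", "vitamins", "thiamine"),
]

_MFS_SUBSTRATES = [
    ("SP", "sugars", "lactose"),
    ("SP", "sugars", "arabinose"),
    ("DHA1", "drugs", "tetracycline"),
    ("MHS", "organic acids", "citrate"),
]


def _reference_catalog() -> list[ReferenceEntry]:
    entries = []
    for i, (sub, cls, substrate) in enumerate(_ABC_SUBSTRATES, 1):
        entries.append(
            ReferenceEntry(
                accession=f"TDBABC{i:03d}", family="ABC", subfamily=sub,
                tc_number=f"3.A.1.{i}.1", substrate_class=cls, substrate=substrate,
            )
        )
    for i, (sub, cls, substrate) in enumerate(_MFS_SUBSTRATES, 1):
        entries.append(
            ReferenceEntry(
                accession=f"TDBMFS{i:03d}", family="MFS", subfamily=sub,
                tc_number=f"2.A.1.{i}.1", substrate_class=cls, substrate=substrate,
            )
        )
    for i, substrate in enumerate(("sodium", "potassium"), 1):
        entries.append(
            ReferenceEntry(
                accession=f"TDBCPA{i:03d}", family="CPA3", subfamily="Pha",
                tc_number=f"2.A.63.1.{i}", substrate_class="cations", substrate=substrate,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------


def _soluble_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(POLAR_POOL) for _ in range(length))


def _membrane_sequence(rng: random.Random, n_tm: int) -> tuple[str, list[tuple[int, int]]]:
    """A protein with ``n_tm`` planted hydrophobic runs; returns 1-based segments."""
    parts = [_soluble_sequence(rng, LOOP_LEN)]
    segments = []
    pos = LOOP_LEN
    for _ in range(n_tm):
        parts.append("".join(rng.choice(HYDROPHOBIC_POOL) for _ in range(TM_SEGMENT_LEN)))
        segments.append((pos + 1, pos + TM_SEGMENT_LEN))
        pos += TM_SEGMENT_LEN
        parts.append(_soluble_sequence(rng, LOOP_LEN))
        pos += LOOP_LEN
    return "".join(parts), segments


# ---------------------------------------------------------------------------
# Evidence value bands (x10 guard margins around the default thresholds)
# ---------------------------------------------------------------------------


def _log_uniform(rng: random.Random, lo: float, hi: float) -> float:
    import math

    return 10 ** rng.uniform(math.log10(lo), math.log10(hi))


def _pass_evalue(rng):  # blast/cog ceiling 1e-5 -> stay <= 1e-6
    return _log_uniform(rng, 1e-60, 1e-6)


def _fail_evalue(rng):  # blast ceiling 1e-5 -> stay >= 1e-4
    return _log_uniform(rng, 1e-4, 1e-1)


def _pass_domain_evalue(rng):  # hmm ceiling 1e-4 -> stay <= 1e-5
    return _log_uniform(rng, 1e-40, 1e-5)


def _tier_identity_coverage(rng: random.Random, tier: str) -> tuple[float, float]:
    # 5-point guard margins around the default 60/70 and 30/50 tier cutoffs
    if tier == TIER_SPECIFIC:
        return rng.uniform(65, 95), rng.uniform(78, 98)
    if tier == TIER_CLASS:
        return rng.uniform(35, 55), rng.uniform(58, 95)
    return rng.uniform(18, 25), rng.uniform(58, 95)


def _tier_counts(n: int, mix: tuple[float, float, float]) -> tuple[int, int, int]:
    c0 = int(round(mix[0] * n))
    c1 = int(round(mix[1] * n))
    c1 = min(c1, n - c0)
    return c0, c1, n - c0 - c1


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self, seed: int):
        self.rng = random.Random(seed)
        self.proteins: list[ProteinRecord] = []
        self.hits: list[SearchHit] = []
        self.domains: list[DomainHit] = []
        self.cogs: list[CogHit] = []
        self.topologies: dict[str, TmTopology] = {}
        self.manifest: list[ManifestRow] = []

    def _blast(self, pid, subject, track, identity, coverage, evalue, desc=""):
        seqlen = len(next(p.sequence for p in self.proteins if p.protein_id == pid))
        aln_len = max(int(coverage / 100 * seqlen), 10)
        self.hits.append(
            SearchHit(
                query_id=pid, subject_id=subject, subject_description=desc,
                percent_identity=round(identity, 1), alignment_length=aln_len,
                evalue=evalue, bitscore=round(2 * identity + coverage + self.rng.uniform(0, 20), 1),
                query_coverage=round(coverage, 1), source_track=track,
            )
        )

    def _domain(self, pid, accession, name, evalue):
        seqlen = len(next(p.sequence for p in self.proteins if p.protein_id == pid))
        start = self.rng.randint(1, max(1, seqlen // 3))
        end = min(seqlen, start + self.rng.randint(80, 160))
        self.domains.append(
            DomainHit(
                query_id=pid, model_accession=accession, model_name=name,
                domain_evalue=evalue, score=round(self.rng.uniform(50, 300), 1),
                env_start=start, env_end=end,
            )
        )

    def _cog(self, pid, cog_id, evalue):
        self.cogs.append(
            CogHit(query_id=pid, cog_id=cog_id, evalue=evalue,
                   bitscore=round(self.rng.uniform(80, 300), 1))
        )

    def add_protein(self, pid, description, sequence, segments):
        self.proteins.append(ProteinRecord(pid, description, sequence))
        self.topologies[pid] = TmTopology(tm_count=len(segments), segments=segments)


def generate(spec: FixtureSpec, out_dir) -> FixtureBundle:
    """Generate a full fixture bundle under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    b = _Builder(spec.seed)
    rng = b.rng
    reference = _reference_catalog()
    abc_refs = [e for e in reference if e.family == "ABC"]
    mfs_refs = [e for e in reference if e.family == "MFS"]
    cpa_refs = [e for e in reference if e.family == "CPA3"]

    # --- ABC ATP-binding subunits, identities per tier mixture
    n_spec, n_class, n_abst = _tier_counts(spec.n_abc_transporters, spec.tier_mix)
    tiers = [TIER_SPECIFIC] * n_spec + [TIER_CLASS] * n_class + [TIER_ABSTAIN] * n_abst
    for i, tier in enumerate(tiers, 1):
        pid = f"abc_{i:04d}"
        ref = abc_refs[(i - 1) % len(abc_refs)]
        b.add_protein(pid, f"ABC transporter ATP-binding protein ({tier} tier)",
                      _soluble_sequence(rng, rng.randint(280, 360)), [])
        identity, coverage = _tier_identity_coverage(rng, tier)
        b._blast(pid, ref.accession, "curated_tdb", identity, coverage, _pass_evalue(rng),
                 f"{ref.substrate} ABC transporter ATP-binding protein")
        b._domain(pid, "PF00005", "ABC_tran", _pass_domain_evalue(rng))
        b._cog(pid, "COG3839", _pass_evalue(rng))
        b._blast(pid, f"WP_{900000 + i:09d}.1", "nr", min(identity + 2, 99), coverage,
                 _pass_evalue(rng), f"{ref.substrate} ABC transporter ATP-binding protein")
        b.manifest.append(ManifestRow(pid, "abc", tier, ref.accession, ref.substrate,
                                      0, "retained", None))

    # --- MFS-like permeases: specific-tier curated hits + 12 TM runs
    for i in range(1, spec.n_mfs_like + 1):
        pid = f"mfs_{i:04d}"
        ref = mfs_refs[(i - 1) % len(mfs_refs)]
        seq, segments = _membrane_sequence(rng, 12)
        b.add_protein(pid, "MFS permease", seq, segments)
        identity, coverage = _tier_identity_coverage(rng, TIER_SPECIFIC)
        b._blast(pid, ref.accession, "curated_tdb", identity, coverage, _pass_evalue(rng),
                 f"{ref.substrate} MFS transporter")
        b._blast(pid, f"WP_{910000 + i:09d}.1", "nr", identity, coverage,
                 _pass_evalue(rng), "major facilitator superfamily transporter")
        b.manifest.append(ManifestRow(pid, "mfs", TIER_SPECIFIC, ref.accession,
                                      ref.substrate, 12, "retained", None))

    # --- UvrA-like decoys: PF00005 + COG0178 + excinuclease NR descriptions
    for i in range(1, spec.n_uvra_decoys + 1):
        pid = f"uvr_{i:04d}"
        b.add_protein(pid, "excinuclease-like ATPase",
                      _soluble_sequence(rng, rng.randint(700, 900)), [])
        b._domain(pid, "PF00005", "ABC_tran", _pass_domain_evalue(rng))
        b._cog(pid, "COG0178", _pass_evalue(rng))
        b._blast(pid, f"WP_{920000 + i:09d}.1", "nr", rng.uniform(60, 95), rng.uniform(80, 99),
                 _pass_evalue(rng), "excinuclease ABC subunit A")
        b.manifest.append(ManifestRow(pid, "uvra_decoy", None, None, None, 0,
                                      "excluded", "abc_non_transporter_cogs"))

    # --- CBS-domain decoys: PF00005 + (CBS COG | "CBS domain" NR keyword)
    for i in range(1, spec.n_cbs_decoys + 1):
        pid = f"cbs_{i:04d}"
        b.add_protein(pid, "CBS-domain regulator",
                      _soluble_sequence(rng, rng.randint(200, 300)), [])
        b._domain(pid, "PF00005", "ABC_tran", _pass_domain_evalue(rng))
        if i % 2 == 1:
            b._cog(pid, "COG0517", _pass_evalue(rng))
            b._blast(pid, f"WP_{930000 + i:09d}.1", "nr", rng.uniform(50, 90),
                     rng.uniform(70, 99), _pass_evalue(rng),
                     "signal transduction protein")
            rule = "abc_non_transporter_cogs"
        else:
            b._blast(pid, f"WP_{930000 + i:09d}.1", "nr", rng.uniform(50, 90),
                     rng.uniform(70, 99), _pass_evalue(rng),
                     "CBS domain-containing protein")
            rule = "abc_nr_keywords"
        b.manifest.append(ManifestRow(pid, "cbs_decoy", None, None, None, 0,
                                      "excluded", rule))

    # --- CPA3-like confusables: curated CPA3 hits, NADH-style NR text, no PF00005
    for i in range(1, spec.n_cpa3_confusables + 1):
        pid = f"cpa_{i:04d}"
        ref = cpa_refs[(i - 1) % len(cpa_refs)]
        seq, segments = _membrane_sequence(rng, 3)
        b.add_protein(pid, "multicomponent cation:proton antiporter subunit", seq, segments)
        identity, coverage = _tier_identity_coverage(rng, TIER_CLASS)
        b._blast(pid, ref.accession, "curated_tdb", identity, coverage, _pass_evalue(rng),
                 "cation:proton antiporter subunit")
        b._blast(pid, f"WP_{940000 + i:09d}.1", "nr", rng.uniform(40, 70), rng.uniform(70, 95),
                 _pass_evalue(rng), "NADH-quinone oxidoreductase subunit N")
        b.manifest.append(ManifestRow(pid, "cpa3", TIER_CLASS, ref.accession,
                                      ref.substrate, 3, "retained", None))

    # --- low-identity ABC membrane subunits: sub-threshold hits, 5 TM runs
    for i in range(1, spec.n_membrane_subunits_lowid + 1):
        pid = f"mem_{i:04d}"
        ref = abc_refs[(i - 1) % len(abc_refs)]
        seq, segments = _membrane_sequence(rng, 5)
        b.add_protein(pid, "ABC transporter permease (weakly conserved)", seq, segments)
        b._blast(pid, ref.accession, "curated_tdb", rng.uniform(15, 25), rng.uniform(30, 60),
                 _fail_evalue(rng), "ABC transporter permease")
        b.manifest.append(ManifestRow(pid, "membrane_subunit", None, ref.accession,
                                      None, 5, "never_candidate", None))

    # --- background: no passing evidence, no TM runs
    for i in range(1, spec.n_background + 1):
        pid = f"bgd_{i:04d}"
        b.add_protein(pid, "hypothetical protein",
                      _soluble_sequence(rng, rng.randint(150, 400)), [])
        if i % 2 == 0:
            b._blast(pid, f"WP_{950000 + i:09d}.1", "nr", rng.uniform(20, 40),
                     rng.uniform(20, 60), _fail_evalue(rng), "hypothetical protein")
        b.manifest.append(ManifestRow(pid, "background", None, None, None, 0,
                                      "never_candidate", None))

    gold_entries: dict[str, str | None] = {}
    for row in b.manifest:
        is_true_transporter = row.category in ("abc", "mfs", "membrane_subunit") or (
            row.category == "cpa3" and spec.cpa3_in_gold
        )
        if is_true_transporter:
            gold_entries[row.protein_id] = row.planted_substrate

    return _write_bundle(out_dir, b, reference, GoldStandard(gold_entries))


def worked_example(out_dir, cpa3_in_gold: bool = False) -> FixtureBundle:
    """A minimal six-protein bundle exercising every decision branch.

    One MalK-like ABC ATPase (retained, specific-tier maltose transfer),
    one UvrA decoy (COG exclusion), one excinuclease keyword decoy, one
    CPA3-like confusable (retained; a false positive unless
    ``cpa3_in_gold``), one TM-only membrane protein (retained at low
    confidence) and one background protein.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    b = _Builder(seed=7)
    rng = b.rng
    reference = _reference_catalog()

    b.add_protein("malK", "maltose ABC transporter ATP-binding protein",
                  _soluble_sequence(rng, 320), [])
    b._blast("malK", "TDBABC001", "curated_tdb", 85.0, 95.0, 1e-80,
             "maltose ABC transporter ATP-binding protein MalK")
    b._domain("malK", "PF00005", "ABC_tran", 1e-20)
    b._cog("malK", "COG3839", 1e-30)
    b._blast("malK", "WP_000000001.1", "nr", 88.0, 96.0, 1e-70,
             "maltose/maltodextrin ABC transporter ATP-binding protein MalK")
    b.manifest.append(ManifestRow("malK", "abc", TIER_SPECIFIC, "TDBABC001",
                                  "maltose", 0, "retained", None))

    b.add_protein("uvrA", "excinuclease ABC subunit A", _soluble_sequence(rng, 800), [])
    b._domain("uvrA", "PF00005", "ABC_tran", 1e-15)
    b._cog("uvrA", "COG0178", 1e-40)
    b._blast("uvrA", "WP_000000002.1", "nr", 90.0, 97.0, 1e-90,
             "excinuclease ABC subunit A")
    b.manifest.append(ManifestRow("uvrA", "uvra_decoy", None, None, None, 0,
                                  "excluded", "abc_non_transporter_cogs"))

    b.add_protein("uvrX", "excinuclease-like protein", _soluble_sequence(rng, 750), [])
    b._domain("uvrX", "PF00005", "ABC_tran", 1e-12)
    b._blast("uvrX", "WP_000000003.1", "nr", 75.0, 90.0, 1e-60,
             "excinuclease ABC subunit A, partial")
    b.manifest.append(ManifestRow("uvrX", "cbs_decoy", None, None, None, 0,
                                  "excluded", "abc_nr_keywords"))

    phaA_seq, phaA_segments = _membrane_sequence(rng, 3)
    b.add_protein("phaA", "putative cation:proton antiporter subunit", phaA_seq, phaA_segments)
    b._blast("phaA", "TDBCPA001", "curated_tdb", 52.0, 84.0, 1e-45,
             "multicomponent K+/H+ antiporter subunit A")
    b._blast("phaA", "WP_000000004.1", "nr", 55.0, 85.0, 1e-40,
             "NADH-quinone oxidoreductase subunit N")
    b.manifest.append(ManifestRow("phaA", "cpa3", TIER_CLASS, "TDBCPA001",
                                  "sodium", 3, "retained", None))

    tmo_seq, tmo_segments = _membrane_sequence(rng, 6)
    b.add_protein("tmo1", "uncharacterized membrane protein", tmo_seq, tmo_segments)
    b.manifest.append(ManifestRow("tmo1", "tm_only", None, None, None, 6, "retained", None))

    b.add_protein("bgd1", "hypothetical protein", _soluble_sequence(rng, 250), [])
    b.manifest.append(ManifestRow("bgd1", "background", None, None, None, 0,
                                  "never_candidate", None))

    gold_entries: dict[str, str | None] = {"malK": "maltose", "tmo1": None}
    if cpa3_in_gold:
        gold_entries["phaA"] = "sodium"
    return _write_bundle(out_dir, b, reference, GoldStandard(gold_entries))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "protein_id", "category", "tier", "reference_accession",
    "planted_substrate", "tm_count", "expected_status", "expected_rule",
)


def _write_bundle(out_dir: Path, b: _Builder, reference, gold: GoldStandard) -> FixtureBundle:
    proteome_path = out_dir / "proteome.faa"
    reference_path = out_dir / "reference.tsv"
    gold_path = out_dir / "gold.tsv"
    blast_paths = {t: out_dir / f"{t}.blast.tsv" for t in ("curated_tdb", "tcdb", "nr")}
    domain_path = out_dir / "domains.domtbl"
    cog_path = out_dir / "cogs.tsv"
    tm_path = out_dir / "tm_short.txt"
    manifest_path = out_dir / "manifest.tsv"

    write_fasta(b.proteins, proteome_path)
    write_reference_table(reference, reference_path)
    write_gold_standard(gold, gold_path)
    for track, path in blast_paths.items():
        write_tabular_hits([h for h in b.hits if h.source_track == track], path)
    write_domain_table(b.domains, domain_path)
    with open(cog_path, "w") as fh:
        for c in b.cogs:
            # rpsblast-style subject ids with the COG accession embedded
            fh.write(
                f"{c.query_id}\tgnl|CDD|{c.cog_id}\t40.0\t120\t60\t2\t1\t120\t1\t120\t"
                f"{c.evalue:.3e}\t{c.bitscore:.1f}\n"
            )
    lengths = {p.protein_id: len(p.sequence) for p in b.proteins}
    write_tm_short(b.topologies, lengths, tm_path)
    with open(manifest_path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for row in b.manifest:
            fh.write(
                "\t".join(
                    [
                        row.protein_id, row.category, row.tier or "-",
                        row.reference_accession or "-", row.planted_substrate or "-",
                        str(row.tm_count), row.expected_status, row.expected_rule or "-",
                    ]
                )
                + "\n"
            )
    return FixtureBundle(
        out_dir=out_dir,
        proteome_path=proteome_path,
        reference_path=reference_path,
        gold_path=gold_path,
        blast_paths=blast_paths,
        domain_path=domain_path,
        cog_path=cog_path,
        tm_path=tm_path,
        manifest_path=manifest_path,
        manifest=list(b.manifest),
    )


def read_manifest(path) -> list[ManifestRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if tuple(header) != MANIFEST_COLUMNS:
            raise ValueError(f"unexpected manifest header {header}")
        for raw in fh:
            f = raw.rstrip("\r\n").split("\t")
            rows.append(
                ManifestRow(
                    protein_id=f[0], category=f[1],
                    tier=None if f[2] == "-" else f[2],
                    reference_accession=None if f[3] == "-" else f[3],
                    planted_substrate=None if f[4] == "-" else f[4],
                    tm_count=int(f[5]), expected_status=f[6],
                    expected_rule=None if f[7] == "-" else f[7],
                )
            )
    return rows
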