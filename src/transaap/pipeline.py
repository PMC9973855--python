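"""File-level orchestration: read every input, run the pipeline, write output.

This is the layer the command-line interface (and the examples) sit on:
it maps paths to the readers in :mod:`transaap.io`, chooses between the
built-in hydropathy predictor and an external TM-summary file, and
assembles the provenance header recorded with each annotation table.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotate import (
    Annotation,
    DEFAULT_PROFILE_FAMILY_MAP,
    TransferTiers,
    annotate_proteome,
)
from .evidence import DEFAULT_TRANSPORTER_COGS, Thresholds
from .io import (
    read_cog_hits,
    read_domain_table,
    read_fasta,
    read_reference_table,
    read_tabular_hits,
    read_tm_short,
    write_annotations,
)
from .rules import RuleSet, default_ruleset, load_ruleset
from .tm import HydropathyParams


@dataclass
class RunConfig:
    """Everything one annotation run needs: input paths plus parameters."""

    proteome: Path
    reference: Path
    curated_hits: Path | None = None
    tcdb_hits: Path | None = None
    nr_hits: Path | None = None
    domain_table: Path | None = None
    cog_hits: Path | None = None
    tm_file: Path | None = None  # None -> built-in hydropathy predictor
    rules: Path | None = None  # None -> shipped default ruleset
    thresholds: Thresholds = field(default_factory=Thresholds)
    tiers: TransferTiers = field(default_factory=TransferTiers)
    tm_params: HydropathyParams = field(default_factory=HydropathyParams)
    transporter_cogs: frozenset[str] = DEFAULT_TRANSPORTER_COGS
    profile_family_map: dict = field(
        default_factory=lambda: dict(DEFAULT_PROFILE_FAMILY_MAP)
    )

    def input_paths(self) -> list[Path]:
        paths = [self.proteome, self.reference]
        for p in (self.curated_hits, self.tcdb_hits, self.nr_hits,
                  self.domain_table, self.cog_hits, self.tm_file, self.rules):
            if p is not None:
                paths.append(p)
        return [Path(p) for p in paths]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()[:16]


def provenance_lines(config: RunConfig) -> list[str]:
    """Parameter + input-digest header recorded with every output table."""
    t, tiers, tm = config.thresholds, config.tiers, config.tm_params
    lines = [
        f"transaap {__version__}",
        "thresholds: "
        + " ".join(
            [
                f"blast_evalue_max={{curated_tdb:{t.blast_evalue_max['curated_tdb']:g},"
                f"tcdb:{t.blast_evalue_max['tcdb']:g},nr:{t.blast_evalue_max['nr']:g}}}",
                f"hmm_domain_evalue_max={t.hmm_domain_evalue_max:g}",
                f"cog_evalue_max={t.cog_evalue_max:g}",
                f"tm_standalone_min={t.tm_standalone_min}",
            ]
        ),
        f"transfer_tiers: specific={tiers.specific_min_identity:g}/{tiers.specific_min_coverage:g}"
        f" class={tiers.class_min_identity:g}/{tiers.class_min_coverage:g}",
        f"tm_params: window={tm.window} threshold={tm.threshold:g}"
        f" min_len={tm.min_len} merge_gap={tm.merge_gap}"
        f" mode={'external' if config.tm_file else 'builtin'}",
        f"rules: {'file:' + str(config.rules) if config.rules else 'builtin-default'}",
    ]
    for path in config.input_paths():
        lines.append(f"input {path.name} sha256:{_sha256(path)}")
    return lines


def load_ruleset_for(config: RunConfig) -> RuleSet:
    return load_ruleset(config.rules) if config.rules else default_ruleset()


def run_annotation(config: RunConfig) -> list[Annotation]:
    """Read every configured input and annotate the proteome."""
    proteome = read_fasta(config.proteome)
    lengths = {p.protein_id: len(p.sequence) for p in proteome}
    hits = []
    for track, path in (
        ("curated_tdb", config.curated_hits),
        ("tcdb", config.tcdb_hits),
        ("nr", config.nr_hits),
    ):
        if path is not None:
            hits.extend(read_tabular_hits(path, track, query_lengths=lengths))
    domains = read_domain_table(config.domain_table) if config.domain_table else []
    cogs = read_cog_hits(config.cog_hits) if config.cog_hits else []
    topologies = read_tm_short(config.tm_file) if config.tm_file else None
    reference = read_reference_table(config.reference)
    return annotate_proteome(
        proteome,
        hits=hits,
        domains=domains,
        cogs=cogs,
        topologies=topologies,
        reference=reference,
        ruleset=load_ruleset_for(config),
        thresholds=config.thresholds,
        tiers=config.tiers,
        tm_params=config.tm_params,
        profile_family_map=config.profile_family_map,
        transporter_cogs=config.transporter_cogs,
    )


def run_and_write(config: RunConfig, out_path) -> list[Annotation]:
    annotations = run_annotation(config)
    write_annotations(annotations, out_path, provenance=provenance_lines(config))
    return annotations
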