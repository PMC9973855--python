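"""Shared test fixtures: generated input bundles and random evidence builders."""

from __future__ import annotations

import random

import pytest

from transaap.evidence import Thresholds, build_bundles
from transaap.fixtures import FixtureSpec, generate, worked_example
from transaap.io import CogHit, DomainHit, ProteinRecord, SearchHit
from transaap.pipeline import RunConfig, run_annotation
from transaap.tm import TmTopology


@pytest.fixture(scope="session")
def worked_bundle(tmp_path_factory):
    return worked_example(tmp_path_factory.mktemp("worked"))


@pytest.fixture(scope="session")
def bench_bundle(tmp_path_factory):
    return generate(FixtureSpec(seed=123), tmp_path_factory.mktemp("bench"))


def config_for(bundle, **overrides) -> RunConfig:
    """RunConfig wired to every evidence file of a generated bundle."""
    kwargs = dict(
        proteome=bundle.proteome_path,
        reference=bundle.reference_path,
        curated_hits=bundle.blast_paths["curated_tdb"],
        tcdb_hits=bundle.blast_paths["tcdb"],
        nr_hits=bundle.blast_paths["nr"],
        domain_table=bundle.domain_path,
        cog_hits=bundle.cog_path,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def worked_annotations(worked_bundle):
    return run_annotation(config_for(worked_bundle))


@pytest.fixture(scope="session")
def bench_annotations(bench_bundle):
    return run_annotation(config_for(bench_bundle))


# ---------------------------------------------------------------------------
# Random evidence-bundle builder for oracle-equivalence tests
# ---------------------------------------------------------------------------

_PAYLOAD_COGS = ["COG0178", "COG0517", "COG1196", "COG1192"]
_OTHER_COGS = ["COG3839", "COG0477", "COG1234", "COG2000"]
_KEYWORD_DESCS = [
    "excinuclease ABC subunit A",
    "CBS domain-containing protein",
    "chromosome partition protein Smc",
    "RNase L inhibitor homolog",
    "cytochrome c biogenesis protein CcmA",
]
_BENIGN_DESCS = [
    "maltose ABC transporter ATP-binding protein",
    "MFS transporter",
    "hypothetical protein",
    "amino acid permease",
]
_ACCESSIONS = ["PF00005", "PF07690", "PF00083", "TIGR01184"]


def random_bundle(rng: random.Random, pid: str = "p1"):
    """One protein with randomized evidence straddling every threshold."""
    protein = ProteinRecord(pid, "random test protein", "MKT" + "A" * 50)
    hits = []
    for track in ("curated_tdb", "tcdb", "nr"):
        for _ in range(rng.randint(0, 5)):
            desc = rng.choice(_KEYWORD_DESCS + _BENIGN_DESCS) if track == "nr" else ""
            hits.append(
                SearchHit(
                    query_id=pid,
                    subject_id=f"S{rng.randint(0, 999):03d}",
                    subject_description=desc,
                    percent_identity=rng.uniform(10, 99),
                    alignment_length=rng.randint(50, 400),
                    evalue=10 ** rng.uniform(-30, 0),
                    bitscore=rng.uniform(20, 500),
                    query_coverage=rng.uniform(5, 100),
                    source_track=track,
                )
            )
    domains = [
        DomainHit(
            query_id=pid,
            model_accession=rng.choice(_ACCESSIONS),
            model_name="m",
            domain_evalue=10 ** rng.uniform(-20, 0),
            score=rng.uniform(10, 300),
            env_start=1,
            env_end=rng.randint(30, 53),
        )
        for _ in range(rng.randint(0, 3))
    ]
    cogs = [
        CogHit(
            query_id=pid,
            cog_id=rng.choice(_PAYLOAD_COGS + _OTHER_COGS),
            evalue=10 ** rng.uniform(-30, 0),
            bitscore=rng.uniform(20, 400),
        )
        for _ in range(rng.randint(0, 3))
    ]
    k = rng.randint(0, 8)
    topology = TmTopology(k, [(i * 50 + 1, i * 50 + 20) for i in range(k)])
    return protein, hits, domains, cogs, topology


def random_built_bundle(rng: random.Random, thresholds: Thresholds | None = None):
    protein, hits, domains, cogs, topology = random_bundle(rng)
    [bundle] = build_bundles(
        [protein], hits, domains, cogs,
        {protein.protein_id: topology}, thresholds or Thresholds(),
    )
    return bundle
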