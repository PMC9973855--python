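# Methods

## The annotation model

The pipeline treats transporter annotation as a three-stage decision
process over per-protein evidence bundles.

**Candidate nomination (inclusive union).** Six evidence tracks are
evaluated independently: alignment hits against a curated transporter
database, against TCDB and against NR; profile-HMM domain hits; COG hits;
and predicted membrane topology. A protein becomes a candidate when *any*
track passes its threshold. The union is deliberately promiscuous — the
design assumption is that recall is cheap at this stage and precision is
recovered downstream. Two asymmetries are built in:

* Only COGs on a transporter-COG allowlist count as positive evidence.
  The exclusion-list COGs used by the negative rules describe
  non-transporter ATPases; letting them nominate candidates would make
  the rule engine filter proteins that its own evidence invited in. The
  shipped allowlist is minimal (ten well-known transporter COGs) and
  user-extensible.
* Membrane topology alone qualifies only at `tm_standalone_min` (default
  6) predicted segments — the canonical minimum for a transporter
  permease domain — and such candidates are capped at the lowest
  confidence tier, because hydrophobicity without homology is weak
  evidence.

**Negative decision tree.** Rules are declarative and ordered;
evaluation is first-fire-wins, which makes the outcome independent of
payload ordering within a rule and well-defined when several rules could
fire. A rule is *armed* only when one of its scope profile accessions is
among the protein's threshold-passing domain hits: a rule can therefore
never touch proteins outside the profile family it was written for
(tested as a structural property). Armed rules fire on exclusion-payload
COGs among threshold-passing COG hits, or on case-insensitive substring
keywords in the descriptions of the top `nr_top_k` NR hits by bitscore.
`nr_top_k` defaults to 5 — "top hits" needs a concrete depth; five is
deep enough to catch consistent annotation text and shallow enough not
to fire on stray distant homologs. Keyword matching is plain substring
with no tokenization: the keywords are distinctive multi-word phrases
("RNase L inhibitor", "Cytochrome c assembly") where substring semantics
are unambiguous and simplest to reason about.

The shipped ruleset covers the ABC ATP-binding-cassette family only (12
exclusion COGs, 8 keywords, both rules scoped to PF00005). Negative
rules for other families belong in user rules files; the engine is
family-agnostic.

**Classification and substrate transfer.** The best reference hit is the
highest-bitscore threshold-passing hit on the curated/TCDB tracks whose
subject resolves in the reference-metadata table (ties: lower E-value,
then lexicographic subject id, making the choice total and
order-independent). Family/subfamily/TC number are copied from that
entry; failing that, a passing profile accession maps through a small
profile→family table ({PF00005→ABC} by default); failing that the
protein is `unclassified`. Substrate prediction is a two-tier homology
transfer with abstention:

| tier | identity | coverage | transfers |
|---|---|---|---|
| specific | ≥ 60 % | ≥ 70 % | substrate + class |
| class | ≥ 30 % | ≥ 50 % | class only |
| below / unknown coverage | — | — | abstains |

The tier cutoffs are conventional homology-transfer practice (function
is generally conserved above ~60 % identity; family membership down to
~30 %), configurable, and recorded in every output's provenance header.
Unknown query coverage (possible when a 12-column alignment file is
supplied without the proteome's query lengths) fails every coverage
cutoff — abstaining is the conservative reading of "when in doubt, do
not predict". Confidence tiers follow the same logic: `high` = specific-
tier curated hit, `medium` = class-tier or profile-only, `low` =
topology-only.

Annotation is strictly per protein. Multi-subunit transport systems
(ABC importers, multicomponent antiporters) are annotated subunit by
subunit; no system-level grouping or operon-context rescue is attempted.

## Transmembrane prediction

The built-in TM caller is a transparent hydropathy method, not an HMM:
per-residue Kyte–Doolittle indices, averaged over a sliding window
(default 19 residues, truncated at the termini), thresholded at 1.6;
supra-threshold runs separated by ≤ 3 sub-threshold positions are
merged, and merged runs shorter than 15 residues are discarded. These
are the literature-standard settings for KD membrane-helix scanning; all
four are configurable. Ambiguity codes (X/B/Z/U) score 0 so real
proteomes never error. The caller reports counts and 1-based segment
intervals only — no inside/outside orientation, no signal-peptide
discrimination. Users with a dedicated TM predictor can supply its
one-line-per-protein short-format output instead (`--tm-file`); the
pipeline consumes only the topology, so the two routes are
interchangeable, and on generated proteomes they produce identical
candidate sets (tested).

## Evidence thresholds

Default E-value ceilings are 1e-5 for the alignment and COG tracks and
1e-4 for per-domain (independent) E-values — conventional
homology-screen values, deliberately permissive because the negative
rules and the transfer tiers, not the ceilings, carry the precision.
Per-domain thresholding uses the independent (i-)E-value rather than the
full-sequence E-value: the rule engine reasons about the presence of a
specific domain, and the i-E-value is the statistic that measures one
domain on its own. All thresholds are configurable per track and
recorded in the output provenance header.

## Evaluation arithmetic

For a predicted set *P* and a manual gold set *M*: confirmed = |P∩M|,
FP = |P| − confirmed with rate FP/|P|, FN = |M| − confirmed with rate
FN/|M|. The asymmetric denominators are the only choice under which both
rates answer their natural question (what fraction of predictions were
wrong; what fraction of real transporters were missed). Reports print
the FP rate to the nearest integer percent and the FN rate to one
decimal. Substrate corrections count confirmed proteins where a
*specific* substrate was predicted, the gold standard records one, and
the two differ after case-folding and trimming; abstentions never count,
and the comparison is exact string match — no substrate-synonym
ontology is attempted. Whether corrections should be counted over all
predictions or confirmed ones only is a genuine ambiguity; confirmed-only
is implemented, since a correction presupposes the protein itself was
annotated correctly.

## The synthetic-data generator

`transaap.fixtures` emulates the *formats and decision-relevant
distributions* of real search output, not the underlying biology: no
alignment is computed, evidence values are planted directly. Scenario
counts in the standard preset are 50 ABC transporters, 10 MFS-like
permeases, 10 UvrA-like decoys, 5 CBS-domain decoys, 5 CPA3-like
confusables, 5 low-identity membrane subunits and 30 background
proteins — large enough that every decision branch is exercised many
times, small enough that the full pipeline runs in well under a second.
Design choices that matter for interpretation:

* **Guard margins.** E-values are drawn log-uniformly within pass/fail
  bands kept a factor of 10 away from every ceiling, and tier identities
  5 percentage points away from every cutoff, so no generated value sits
  on a decision boundary and results are seed-independent.
* **Unambiguous topology.** Membrane proteins are built from residue
  pools chosen so the windowed-mean caller recovers the planted segment
  count for *any* seed: the polar pool's most hydrophobic residue (P,
  −1.6) keeps loops below threshold, the hydrophobic pool's least
  hydrophobic residue (F, 2.8) keeps 28-residue runs above it.
* **Tier mixture is exact.** The specific/class/abstain split of ABC
  identities uses exact counts, not sampling, so the abstention fraction
  of a run equals the engineered fraction identically.
* **Planted false negatives.** The low-identity membrane-subunit class
  carries only sub-threshold hits and five TM segments — one below the
  standalone-topology minimum — so these proteins fail candidacy
  entirely, reproducing the canonical miss (weakly conserved permease
  subunits with no dedicated profile). The CPA3-like confusables carry
  curated antiporter hits and oxidoreductase-style NR text but no
  PF00005, so no shipped rule can exclude them — the canonical false
  positive. A toggle places them in or out of the gold standard
  (in by default, where they count as true transporters; out when the
  false-positive anatomy itself is under test).

What passing tests on these fixtures shows: the decision logic —
thresholding, union, arming/firing, tie-breaks, tier transfer,
bookkeeping — is correct and deterministic. What it cannot show:
performance on real proteomes, which depends on the quality and coverage
of the user's reference database and search results. The published-scale
benchmark figures reproduced by the evaluation module are arithmetic
checks on printed set sizes, not re-runs of those genome annotations.

## Numerical and degenerate-input choices

* Accession version suffixes are stripped on ingest (`PF00005.27` →
  `PF00005`) so rule scopes match by bare accession.
* A domain-table accession of `-` falls back to the model name.
* COG lines with no extractable accession are skipped with a logged
  warning (not fatal); all other malformed input is a hard error naming
  file and line.
* Empty proteomes, empty rule sets (every candidate retained), empty
  evidence files and zero-denominator rates (reported as 0) are all
  defined, tested cases.
* Output row order equals input proteome order, and provenance headers
  contain no timestamps, so identical runs are byte-identical.

## Known limitations

Per-protein calls only (no system assembly); no signal-peptide or
orientation modelling in the TM caller; substrate comparison has no
synonym handling; the shipped negative ruleset covers only the ABC
family; the COG allowlist is illustrative rather than exhaustive; the
generator does not emulate alignment-score statistics, compositional
bias or real sequence evolution.
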