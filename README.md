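# transaap

Membrane-transporter annotation for microbial proteomes: aggregate
multi-source search evidence per protein, prune false positives with a
negative decision tree, assign transporter family / Transporter
Classification (TC) numbers by homology transfer, and predict substrates
in tiers that abstain when the evidence is weak.

Transport proteins are hard to annotate automatically because their most
conserved domains are shared with non-transporters: the ATP-binding
cassette profile PF00005, for instance, matches ABC transporter ATPases
but also excinucleases (UvrA), chromosome segregation and partitioning
ATPases (Smc, Soj, Mrp, RecF, SbcC) and CBS-domain regulators. This
package implements the inclusive-then-filter strategy used by production
transporter-annotation pipelines:

1. **Evidence aggregation** — protein-alignment hits against a curated
   transporter database, TCDB and NR (12+-column tabular exports),
   profile-HMM domain hits (HMMER3 per-domain tables), COG hits and
   membrane topology (an external TM-summary file or the built-in
   Kyte–Doolittle hydropathy caller). The tracks are *mutually
   inclusive*: any single track passing its threshold nominates the
   protein as a candidate transporter.
2. **Negative decision tree** — ordered, declarative exclusion rules.
   Each rule is armed by profile accessions (e.g. PF00005) and fires on
   either an exclusion-list COG hit or a keyword in the top NR hit
   descriptions; the first firing rule deletes the candidate. The
   shipped default encodes the ABC (ATP-binding cassette) rules —
   12 non-transporter ATPase / CBS-domain COGs and 8 description
   keywords — and rulesets are user-extensible via a YAML file.
3. **Classification and substrate transfer** — family, subfamily and TC
   number are copied from the best curated reference hit; substrate
   prediction is tiered: a close hit (default ≥60 % identity, ≥70 %
   coverage) transfers the specific substrate ("maltose"), a more
   distant one (≥30 %/≥50 %) only the general class ("sugars"), anything
   weaker abstains.
4. **Evaluation** — concordance of a predicted transporter set with a
   manual gold standard: confirmed = intersection, false-positive rate
   over the predicted count, false-negative rate over the manual count,
   plus substrate-correction counts.

A deterministic synthetic-data generator (`transaap.fixtures`) plants
true transporters, rule-triggering decoys and the known failure modes
(antiporter-subunit lookalikes that evade the rules, weakly conserved
membrane subunits that are missed) with a ground-truth manifest, so the
whole pipeline is testable without external search tools or databases.

## Worked example

```
transaap fixtures --out demo --preset worked-example
transaap annotate --proteome demo/proteome.faa --reference demo/reference.tsv \
    --curated-hits demo/curated_tdb.blast.tsv --tcdb-hits demo/tcdb.blast.tsv \
    --nr-hits demo/nr.blast.tsv --domtbl demo/domains.domtbl \
    --cog-hits demo/cogs.tsv --out demo/annotations.tsv
transaap evaluate --predictions demo/annotations.tsv --gold demo/gold.tsv
```

The annotation table contains (abridged):

```
protein_id  status           family        substrate  confidence  excluded_by
malK        retained         ABC           maltose    high        -
uvrA        excluded         -             -          -           abc_non_transporter_cogs
uvrX        excluded         -             -          -           abc_nr_keywords
phaA        retained         CPA3          -          medium      -
tmo1        retained         unclassified  -          low         -
bgd1        never_candidate  -             -          -           -
```

malK is a clean ABC ATPase: its close curated hit transfers family,
TC number and the specific substrate at high confidence. The two
excinuclease-style decoys carry PF00005 but are deleted — one by the COG
exclusion rule (COG0178), one by the "Excinuclease" NR keyword. phaA, a
cation:proton antiporter-subunit lookalike without PF00005, is retained
(no rule covers it — the pipeline's characteristic false-positive
source), with a class-tier hit that transfers only the substrate class.
tmo1 enters on membrane topology alone (6 predicted TM segments) at low
confidence; bgd1 has no passing evidence. The evaluation step then
reports, against the bundled gold standard:

```
Predicted transporters   3
Manual annotation        2
Confirmed (overlap)      2
False positives          1 (33%)
False negatives          0 (0.0%)
Substrate corrections    0
```

The same operations are available as a library (`import transaap`);
see `examples/` for short narrative scripts covering annotation,
evaluation, TM prediction and ruleset extension.

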