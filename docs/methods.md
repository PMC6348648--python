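# Methods

## The problem

Gene-expression compendia combine experiments measured on heterogeneous
platforms — different microarray generations, RNA-seq — into one coherent
collection. The obstacle to coherence is annotation: each microarray
vendor maps its probes to genes against its own, often outdated, gene
models. `compendia` fixes the gene set first (the *genomic background*, a
FASTA file of gene sequences) and re-derives every probe-to-gene mapping
against it by sequence alignment, so that every platform in the collection
speaks the same gene vocabulary. RNA-seq experiments skip the probe layer:
gene-level counts are keyed directly to background feature ids.

The store holds only **raw** values (array intensities, read counts). No
normalization, transformation or imputation is ever applied; downstream
analysis decides that.

## The two-step filter

Alignment alone does not give a mapping. A probe may align to several
genes (cross-hybridization: its signal would be a mixture) or align only
poorly (its signal would be noise). A single score threshold cannot
address both failure modes at once:

* a *low* threshold lets a cross-hybridizing probe's secondary placements
  be counted, but if only the best one clears the bar the probe looks
  falsely unique;
* a *high* threshold removes weak probes but silently discards good probes
  sitting just under it, and still mis-handles a probe whose two
  placements straddle the bar.

The two-step filter separates the two concerns. Each hit is judged by a
`FilterThreshold` — minimum aligned fraction of probe length, maximum gap
opens, maximum mismatches, optional minimum percent identity. Two
thresholds make a `TwoStepConfig`:

1. **Sensitivity step** (lenient; default 95% of probe length aligned,
   0 gap opens, ≤3 mismatches). All hits of a probe passing this bar are
   deduplicated by placement; a probe with more than one surviving
   placement is discarded as **ambiguous**. The leniency is the point:
   secondary placements must remain visible to be counted.
2. **Specificity step** (strict; default 98% aligned, 0 gaps,
   ≤1 mismatch). A probe unique after step 1 is **retained** only if its
   single placement also passes this bar; otherwise it is discarded as
   **low quality**.

Probes with no hits at all are **unaligned**. The four outcomes partition
the probe set — an invariant the tests enforce on random inputs. The
configuration is validated so that every sensitivity field is at least as
lenient as the specificity field; an inverted configuration is rejected
before any computation.

Retained (probe, gene) pairs become a `ReporterMapping` whose provenance
records the aligner and both thresholds, making a re-annotation exactly
reproducible. Filtering is pure and cheap relative to alignment, so
thresholds can be explored repeatedly over one hit file.

### Ambiguity granularity

Uniqueness counts distinct surviving *placements* — (gene, strand,
coordinates) — not distinct genes: a probe matching one gene at two
positions is still ambiguous, since the duplicated sequence context makes
the signal uninterpretable. `unique_per_gene=True` (CLI
`--unique-per-gene`) relaxes this to per-gene counting for users who
consider same-gene multi-placements benign. No score-gap parameter (e.g.
"second hit must be ≥3% worse") is exposed: the separation between best
and second-best placements is governed by where the sensitivity threshold
sits, which is the mechanism the two-step design relies on.

## The built-in aligner

`align_probes` is an exhaustive ungapped scanner: for every probe it
examines **every** full-probe-length window on both strands of every
background gene and reports each placement with at most a caller-set
number of mismatches (default 5 = stock sensitivity limit + 2, leaving
headroom for threshold exploration without re-aligning). Windows and
probes are one-hot encoded and match counts are computed as a single
matrix product, so the scan is a dense BLAS operation rather than a
Python loop; 1,000 25-mers against 200 × 500 b take a few seconds on one
core.

Design consequences:

* hits are complete up to the mismatch ceiling — no seeding heuristic can
  miss a placement, which is what makes planted-truth recovery exact;
* `alignment_length` always equals probe length and `gap_opens` is 0;
  identity is `100·(L−mm)/L`. This is the right regime for short oligo
  probes (25–60 nt). Gapped or partial alignments are supported through
  the 12-column tabular hit reader, fed by an external aligner (e.g.
  BLAST+); the filters are agnostic to the hit producer.
* an `N` in probe or gene one-hot encodes to the zero vector and therefore
  never matches anything: it always counts as a mismatch;
* e-values are not modelled (`evalue` = 0.0, `bit_score` = 2·matches);
  significance filtering belongs to external aligners.

Coordinates follow the tabular convention everywhere at the I/O boundary:
1-based inclusive, minus-strand hits reported with `feature_start >
feature_end` in forward coordinates. Internal arithmetic is 0-based
half-open and converts only at that boundary.

## The data model and store

`Compendium` is an embedded single-process relational store (sqlite3)
under one directory, with a `compendium.json` manifest carrying the name,
schema version and background checksum. Entities mirror the domain:
background features, platforms with reporters, experiments with samples,
measurements keyed by reporter id (microarray) or feature id (RNA-seq),
reporter mappings with provenance, and an append-only log. Choices that
matter:

* **Background immutability.** The background may be replaced freely
  while the compendium is empty, but is frozen once any experiment is
  imported — mixing annotations against different gene sets is exactly
  the incoherence the tool exists to prevent.
* **Atomic commits.** An experiment import either lands completely or not
  at all (one sqlite transaction); a failed validation is logged and the
  store is untouched. Stored measurement count always equals staged count.
* **Missing is missing.** A cell with no measurement is NaN in memory and
  HDF5, `"NA"` in TSV — never 0, which is a valid intensity/count.
* **Deterministic exports.** Raw matrices order rows (keys) and columns
  (sample names) lexicographically. Orientation is keys-as-rows.
* **Metadata is free-form strings.** Repeated SOFT attribute keys
  accumulate in the parser and are joined with `"; "` when flattened into
  entity metadata.
* **Replay identity.** `snapshot()`/`content_digest()` cover all stored
  data *except* the log and provenance timestamps, which are wall-clock
  by nature; "replaying an ingestion plan reproduces an identical store"
  is asserted on that digest.

## Ingestion

Parsing is driven by *file assignments* — (file, entity, parser,
parameters) tuples built by two rules: `assign_all` (every file to every
entity; used for the SOFT family file that feeds experiment, platform and
samples at once) and `match_entity_name` (file base name = sample name,
case-insensitive; used for per-sample value files). Parsers are a
registry of named readers (`soft_experiment`, `soft_platform`,
`soft_sample`, `probe_table`, `value_table`); `register_parser` adds new
ones under the same contract, which is how other quantitative data types
would be accommodated.

The engine is synchronous and deterministic: assignments are processed in
canonical order, so results are independent of the order the caller built
the list in; a failing file becomes an error issue without disturbing
sibling parses; and two files asserting different values for the same
metadata key is an *error*, never last-writer-wins. Assignment plans
serialize to YAML and replay exactly.

Measurements for one sample may come from its SOFT data table or from a
separate value table (`soft_sample` takes `include_table=false` to
suppress the former); providing both is flagged as a duplicate-source
error. Value tables reject non-numeric and duplicate-key cells rather
than imputing. Binary vendor formats (e.g. CEL) are not decoded; the
supported intensity route is tab-delimited text, which vendor tooling and
GEO supplementary files provide.

## Synthetic data

The generators produce everything the pipeline ingests, deterministically
from a seed.

* `generate_background(n_genes, gene_length, seed)`: i.i.d. uniform
  A/C/G/T sequences.
* `generate_platform_with_truth`: probes in four planted classes, default
  mix 70% unique / 10% ambiguous / 10% low-identity / 10% unmappable,
  default length 25 nt (the short-oligo regime the built-in aligner
  targets). Unique probes are exact substrings; ambiguous probes are
  substrings *copied into a second gene* (this mutates the background
  list in place, before the compendium adopts it); low-identity probes
  carry 2–3 planted mismatches (beyond the specificity limit of 1, within
  the sensitivity limit of 3); unmappable probes are random sequences.
  Every class membership is then **verified by exhaustive Hamming scan**
  over the final background (windows are drawn non-overlapping so planted
  copies cannot clobber each other); candidates failing verification are
  redrawn, so recovery by the two-step filter is exact by construction
  rather than with high probability. The verification scan compares coded
  windows directly and shares no code path with the one-hot-matmul
  aligner.
* `five_probe_fixture`: five 100-mer probes, two full-length ungapped hits
  each. The cross-hybridizing probe scores 95 and 94; the other scores
  are constraint-chosen so that the three filtering scenarios (single
  step at 95%, single step at 96%, two-step 94% → 95%) produce three
  different retained sets, demonstrating that no single threshold
  reproduces the two-step outcome. Tests assert the outcomes, which any
  score assignment satisfying the constraints yields.
* `generate_soft_experiment` / `write_dataset_dir`: syntactically valid
  SOFT family text (series + platform + samples with ID_REF/VALUE
  tables), probe tables and value tables, with the expected staged
  experiment returned for round-trip assertions; the same seed gives
  byte-identical files.

What the generators do **not** emulate: realistic intensity
distributions, batch effects, probe GC/affinity biases, transcript
isoforms, or genes sharing homologous sequence beyond the planted copies.
Passing tests therefore demonstrate that the machinery is correct —
formats round-trip, the filter implements its definition, recovery is
exact when classes are separated by construction — not that any
particular threshold choice is optimal for a real platform, where probe
families and paralogs blur the class boundaries and thresholds must be
tuned per platform.

## Problem sizes and numerics

The recovery studies run 200 genes × 500 b with 1,000 probes across five
seeds — large enough that every probe class is exercised hundreds of
times, small enough to iterate on a laptop core. Threshold comparisons
use `≥` / `≤` exactly as stated (24/25 = 0.96 passes a 0.95 length bar);
identities are plain float ratios of small integers, so no tolerance is
needed at the stock thresholds. Report lists are sorted by reporter id;
among duplicate hits at one placement the highest (identity, bit score)
wins. Degenerate inputs are defined, not special-cased: an empty hit list
classifies every probe unaligned, an empty experiment selection yields a
0×0 matrix, an empty matrix a header-only TSV.

## Known limitations

* Single-process store; concurrent writers unsupported.
* The built-in aligner is exhaustive and dense — ideal at desk scale,
  wrong tool for, say, 5M probes × 100k transcripts; use an external
  aligner and the tabular hit reader there.
* SOFT dialect is the tolerant subset described above; MINiML (XML) is
  not read.
* Sample names must be unique across experiments selected into one
  export (the matrix would otherwise have colliding columns; the export
  raises instead of silently renaming).
* No network access by design: GEO/SRA/ArrayExpress retrieval is out of
  scope (`fetch` is a stub); inputs are local files.
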