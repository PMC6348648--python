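# compendia

Build local gene-expression compendia from files on disk: ingest
microarray and RNA-seq experiments into one relational store, re-annotate
microarray probes against a gene set you choose, and export coherent
raw-data matrices.

**Who it is for.** Anyone assembling a cross-platform expression
collection — meta-analysis of public microarray series, mixed
microarray/RNA-seq compendia for a non-model organism, curation of a
lab-internal archive — who needs every platform annotated against the
*same* gene sequences rather than each vendor's own gene models.

## The core method: two-step probe re-annotation

A fixed **genomic background** (FASTA of gene sequences) is installed
first. Each microarray probe is then aligned against both strands of
every gene, and the hits are filtered in two steps:

1. **Sensitivity step** — a lenient threshold (default: ≥95% of the probe
   length aligned, 0 gap opens, ≤3 mismatches) keeps every plausible
   placement visible. A probe with more than one surviving placement is
   discarded as *ambiguous*: its signal would mix several genes
   (cross-hybridization).
2. **Specificity step** — a strict threshold (default: ≥98% aligned,
   0 gaps, ≤1 mismatch) retains a unique probe only if its single
   placement is of high quality; otherwise the probe is discarded as
   *low quality*.

A single threshold cannot do both jobs: set it low and a multi-site probe
whose secondary placement falls below the bar looks falsely unique; set
it high and good probes just under the bar are lost. Running the lenient
test first, demanding uniqueness, then applying the strict test to the
survivors avoids both failure modes. Retained (probe, gene) pairs form a
mapping whose provenance records the aligner and both thresholds, so a
re-annotation is exactly reproducible and cheap to re-run with different
thresholds over one alignment result.

A built-in exhaustive ungapped scanner (complete up to a mismatch
ceiling, vectorised; right-sized for short oligo probes at desk scale)
produces hits directly, or you can feed standard 12-column tabular hit
files from an external aligner such as BLAST+.

RNA-seq experiments bypass the probe layer: gene-level count matrices are
imported with counts keyed directly to background gene ids.

## Worked example

```python
from compendia import (
    create_compendium, align_probes, two_step_filter,
    probe_lengths_of, TwoStepConfig,
)
from compendia.synthetic import generate_background, generate_platform_with_truth

# a synthetic background and a 100-probe array with known ground truth
background = generate_background(n_genes=60, gene_length=400, seed=3)
platform, truth = generate_platform_with_truth(background, n_probes=100, seed=3)

c = create_compendium("demo", "demo-store")
c.set_genomic_background(background, source_name="synthetic")

hits = align_probes(platform.reporters, background, max_mismatches=5)
mapping, report = two_step_filter(
    hits, probe_lengths_of(platform.reporters), TwoStepConfig.default(),
    platform_id=platform.id,
)
print(f"{len(hits)} hits")
print(f"retained {len(report.retained)} | ambiguous {len(report.discarded_ambiguous)} "
      f"| low-quality {len(report.discarded_low_quality)} "
      f"| unaligned {len(report.unaligned)}")
print("recovered planted truth:", dict(report.retained) == truth.unique_probes)
```

prints

```
101 hits
retained 70 | ambiguous 10 | low-quality 10 | unaligned 10
recovered planted truth: True
```

100 probes were planted in four classes (70 uniquely mappable, 10 copied
into a second gene, 10 with 2–3 mismatches, 10 random): the default
thresholds (0.95/0 gaps/3 mismatches, then 0.98/0/1) recover the
classification exactly — every retained probe maps to its true gene, and
every discarded probe is discarded for the planted reason.

The same pipeline from the shell:

```
compendia --store st init demo
compendia --store st background set genes.fasta
compendia --store st ingest plan --soft exp.soft --probe-table probes.tsv \
          --values-dir values/ --out plan.yaml
compendia --store st ingest run plan.yaml
compendia --store st map align --platform PLAT1 --out hits.tsv
compendia --store st map filter --hits hits.tsv --platform PLAT1 --out mapping.tsv
compendia --store st map import mapping.tsv
compendia --store st export tsv raw.tsv
compendia --store st export hdf5 raw.h5 --platform PLAT1
```

Exports carry keys (probe or gene ids) as rows and sample names as
columns; missing cells are `NA` in TSV and NaN in HDF5. See
`docs/methods.md` for the data model, filter semantics and design notes.

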