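# isoscope

Full-length mRNA isoform identification from UMI-tagged long single-cell
reads, with a synthetic read generator that provides complete ground truth.

## The problem

Single-cell RNA-seq with short reads cannot define full-length isoforms, and
bulk long-read data cannot assign isoforms to individual cells. Long-read
(circular-consensus) sequencing of barcoded, UMI-tagged full-length cDNA from
single cells can do both — but the raw reads need careful handling before any
isoform can be called:

* each pre-circularization molecule follows a strict grammar
  (`barcode — Illumina adapter — UMI(6) — GGG — template — polyA —
  rc(adapter) — rc(barcode)`, or its reverse complement when the other
  strand was read);
* a substantial fraction of records are **concatemers** of 2–4 molecules
  ligated end-to-end during circularization and must be split at internal
  adapter boundaries;
* PCR produces several reads per original molecule; reads sharing a UMI must
  be collapsed into a consensus **transcript**;
* transcript coordinates carry ~±1 bp jitter at splice junctions and a few
  bp at the 5'/3' ends, so isoforms must be defined with explicit tolerances.

`isoscope` implements this whole path — extraction, UMI consensus, isoform
definition and the downstream diversity statistics — for anyone analysing
STRT-style barcoded long-read single-cell libraries, plus a simulator that
emulates every noise source so the pipeline can be validated against known
truth.

## The model in brief

For each gene (one annotated reference structure per gene) transcripts are
grouped into isoforms at three strictness levels:

* **full** — identical exact junction chain, plus shared 5' and 3' end
  clusters, where end clusters are single-linkage groups of end positions
  linked whenever |a − b| ≤ 5 bp (ranges extend by chaining);
* **conservative** — only transcripts containing the annotated first exon
  and a poly(A) tail; junction coordinates differing by ≤ 1 bp are the same
  position (single-linkage over the gene's pooled junction values);
* **cassette** — identity of annotated exon membership only
  (e.g. structure 1-2-3-4 vs 1-3-4).

Isoform-generating events are classified as TSS, TTS, exon-position and
exon-cassette events, counting only variants beyond the first per context.
Technical accuracy is profiled as offsets from the per-context median
(5' end, 3' end, junction donor/acceptor), against ERCC spike-ins of known
ends, and within UMI groups. Splice sites are labelled coding/non-coding
against CCDS-style intervals; coding vs non-coding |offset| distributions
are compared with two-sided Wilcoxon rank tests, and pairwise exon
co-inclusion with two-sided Fisher exact tests.

## Worked example

```bash
isoscope run --outdir demo --seed 7
```

or in Python:

```python
from isoscope.pipeline import run_pipeline, validate_config

cfg = validate_config({"seed": 7, "simulate": {"n_genes": 20, "n_cells": 3,
                                               "molecules_per_cell": 400}})
manifest = run_pipeline(cfg, outdir="demo")
```

With that config the run prints (in `manifest["stages"]`):

```
simulate : 1200 molecules -> 1176 FASTQ records containing 1915 subreads
extract  : 1915/1915 subreads parsed as valid reads (0 rejected)
assemble : 1199 transcripts (UMI consensus), 398 full-length,
           singleton-UMI fraction 0.633
isoforms : 1061 full / 66 conservative / 40 cassette,
           5.3 transcripts per conservative isoform
stats    : ERCC ends 100% within +-5 bp (68%/74% within +-1 bp at 5'/3');
           event mix 48.9% TSS, 0.0% TTS, 3.2% position, 47.9% cassette;
           mean major-isoform fraction 0.485;
           isoform sharing: 85.7% in >=2 cells, 44.4% in all 3 cells
```

Reading the numbers: 1915 subreads from 1176 records means roughly a third
of records were concatemers that were split; 1200 molecules collapsing to
1199 transcripts reflects a rare UMI collision; only 398 transcripts are
full-length because the generator 5'-truncates 70% of molecules (mimicking
mRNA degradation), and conservative isoforms are called on those only. The
event mix is dominated by TSS and cassette events because the generator's
configured isoform variants are an alternative TSS and a cassette exclusion
per gene.

Artifacts land under `demo/`: the simulated FASTQ/BED12/GTF truth set,
extracted reads, transcript BED12, per-level isoform tables, offset tables,
a markdown report with the offset histograms, and `manifest.json` with the
per-stage accounting shown above. The same stages are available separately
(`isoscope simulate / extract / assemble / isoforms / stats`) over files.

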