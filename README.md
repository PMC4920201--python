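# bruwave

Transcription dynamics from pulse-labeled nascent-RNA coverage.

`bruwave` implements, as a tested and reusable pipeline, the analysis of
time-resolved nascent-RNA sequencing of a stimulus response (a starved
baseline plus consecutive 30-minute labeling windows after stimulation):

* **`bruwave.sim`** — a kinetic simulator of pulse-labeled nascent
  transcription. Point polymerases initiate at a piecewise-constant,
  time-dependent rate, move deterministically through a position-dependent
  elongation-rate field, and a position is labeled in a window iff a
  polymerase transcribes it while label is present. Expected per-bin
  coverage has a closed form; optional Poisson read sampling produces
  stranded bedGraph tracks together with a ground-truth manifest
  (response labels, wave-front positions, displacements).
* **`bruwave.quant`** — TSS-proximal windowed quantification: genes are
  quantified over the whole body when shorter than 30 kb and over the
  first 30 kb downstream of the TSS otherwise, giving a gene × window
  RPKM matrix that reflects productive initiation; genes with RPKM > 0.5
  in any window count as expressed.
* **`bruwave.classify`** — log2 fold changes of each stimulated window
  versus the starved baseline (with a pseudocount), strict twofold
  thresholding, and assignment of each expressed gene to a direction
  (induced / repressed / reversal) and temporal pattern (sustained /
  transient / delayed / reversal) with its onset window, plus
  deterministic heat-map ordering and responder count summaries.
* **`bruwave.wavefront`** — algorithmic detection of transcription
  wave fronts in genes longer than 200 kb (advancing wedges after
  induction, retreating 5' clearings after repression), per-interval
  displacements and elongation rates (displacement / 30 min), and cohort
  statistics with paired Wilcoxon signed-rank comparisons between
  labeling intervals.
* **`bruwave.pipeline` / `bruwave.cli`** — orchestration, config
  validation, deterministic TSV/JSON outputs with a provenance block.

## Command line

```sh
# simulate a shipped scenario (default | patterns | waves) or a YAML config
bruwave simulate --preset default --seed 1 --out simdir
bruwave simulate --config scenario.yaml --out simdir [--no-noise]

# individual stages
bruwave quantify  --genes simdir/genes.bed --samples simdir/samples.tsv --out matrix.tsv
bruwave classify  --matrix matrix.tsv --out clsdir
bruwave wavefront --coverage-dir simdir --genes simdir/genes.bed \
                  --calls clsdir/calls.tsv --out wfdir

# or the full pipeline from a config
bruwave run --config run.yaml
```

A minimal `run.yaml`:

```yaml
genes: simdir/genes.bed
samples: simdir/samples.tsv
out: outdir
```

All tabular outputs are TSV with a single `#`-prefixed header line.
Coverage is exchanged as 0-based half-open bedGraph per strand per
labeling window; the fourth column is the read count in the interval. A
sample sheet TSV (`window`, `plus`, `minus`, optional `library_size`)
maps windows to files; its first row is the starved baseline window.
Exit codes: 0 success, 2 validation failure, 3 stage failure.

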