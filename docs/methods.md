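# Methods

## The model

The predictor is a fixed linear calibration between the pooled
amino-acid composition of coding sequence and temperature:

```
T [°C] = 937 · F_IVYWREL − 335
```

where *F*<sub>IVYWREL</sub> is the fraction of Ile, Val, Tyr, Trp, Arg,
Glu and Leu among all counted residues. For a single genome the counted
residues are its whole coding proteome and the output is an optimal
growth temperature (OGT); for a metagenome they are the pooled
translated coding fragments of every read and the output is a
metagenomic predicted temperature (MPT). The calibration's two golden
points — −335 °C at *F* = 0 and a span of 937 °C over the full
composition range — are asserted exactly in the test suite.

Two modelling commitments matter:

- **Pooling, not averaging.** Residue counts are pooled across all
  fragments before the fraction is taken (length-weighted), so
  `["IV", "GGGGGG"]` gives *F* = 2/8, not (1.0 + 0.0)/2. This treats the
  sample as one community proteome, mirrors the per-genome definition,
  and makes the result invariant to how proteins are chunked.
- **No clamping.** The line is applied as-is even where it extrapolates;
  results outside roughly 0–110 °C raise a warning, never a correction,
  because masking extrapolation would hide upstream QC problems. Symbols
  outside the 20 standard residues (X, B, Z, U, `*`, gaps) are excluded
  from numerator and denominator alike.

## Read quality control

Two filters are applied, both inclusive at the boundary: minimum read
length 50 bp, and at most 1 ambiguous base (N) per read. Non-ACGTN IUPAC
codes are normalized to N on input so a single ambiguity currency feeds
the N filter. A read failing both filters is tallied under the length
failure only, so the three tallies partition the input count. Adapter
and quality-score trimming are assumed done upstream; qualities are
carried through but never interpreted numerically. Host or contaminant
depletion is consumed as a plain id list (`exclude_by_id`): the mapping
step that produces it is out of scope.

## Coding-fragment extraction on short reads

Shotgun reads (default geometry 181 bp) rarely span complete genes, so
genes are not "called" in the usual sense. Instead every read is scanned
in all six frames and each maximal stop-free stretch of ≥ `min_aa`
(default 20) residues is a candidate fragment; flags record whether the
stretch happens to begin at a bacterial start codon (ATG/GTG/TTG, first
residue then rendered M) or end at a stop. `complete` mode, for inputs
that do contain whole genes, keeps only start-to-stop stretches. The
scanner is deterministic and model-free — it is **not** a reimplementation
of a trained metagenomic gene predictor, and this is the package's
largest fidelity gap versus annotation-based pipelines. Its output is
verified against a brute-force enumeration of all maximal in-frame
windows on 1,000 random sequences.

### Frame disambiguation

A model-free six-frame scan emits, besides the true coding frame,
spurious stretches from shifted and reverse frames. Measured on
synthetic communities, those spurious stretches are *not* a neutral
background: their IVYWREL fraction sits near 0.37–0.40 almost regardless
of the community's true composition, so pooling all six frames drags
warm communities tens of °C cold (≈ −47 °C at an 80 °C target) while
leaving 20 °C communities nearly untouched.

`predict_mpt` therefore defaults to `frame_policy="unique"`: a read
contributes only when exactly one of its six frames is plausible, where
a frame is plausible if it contains no stop codon other than as its
final codon (a terminal stop is consistent with a read spanning a gene
end). Inside real coding sequence the true frame is always plausible,
while each shuffled frame accumulates internal stops at roughly one per
twenty codons; demanding uniqueness drops frame-ambiguous reads (about a
quarter of coding reads at 181 bp) instead of guessing. The cost is a
small conditioning bias: reads whose alternate frames happen to be
stop-free are discarded, and stop codons in shifted frames arise
preferentially from the codons of certain residues, so the kept reads
are slightly IVYWREL-enriched (+1.7 to +2.4 °C on the synthetic
communities below, stable across the 20–80 °C range). `frame_policy="all"`
restores the pool-everything behaviour for diagnostic use.

## Synthetic communities

The simulator inverts the calibration: a target temperature fixes a
target fraction *f* = (T + 335)/937, a proteome of `n_genes` ×
`gene_len_aa` residues is drawn with exactly `round(f · total)` IVYWREL
residues (positions shuffled; the seven IVYWREL and thirteen other
residues each drawn uniformly), each protein is reverse-translated with
uniform synonymous-codon choice under the bacterial genetic code plus a
terminal TAA, and reads of fixed length are sampled at uniform positions
with per-CDS Poisson counts matching the target coverage. Ambiguous
bases can be injected at a per-base rate to exercise the N filter. All
draws derive from a single seed; runs are bit-reproducible.

Default geometry — 200 genes × 150 aa, 181 bp reads, 5× coverage, no N
injection — emulates a small warm-environment community sequenced at the
read length of the data the method targets. Deliberate non-features:
no codon-usage bias (composition, the quantity under test, is unaffected),
no species-abundance structure, no sequencing-error model, no intergenic
sequence by default. Passing recovery tests therefore demonstrates the
compositional arithmetic and the frame logic, not robustness to real
sequencer noise or non-coding DNA.

### Recovery accuracy and its error budget

For targets {20, 37, 50, 60, 80} °C at the default geometry over ten
seeds each, the mean prediction error per temperature stays within
±3 °C with no trend across the range (slope ≈ −0.01 °C/°C); the
acceptance test asserts exactly this. Individual runs scatter around the
mean with sd ≈ 2–2.5 °C and occasional excursions to ≈ ±7 °C. The
decomposition, measured by translating every read in its known true
frame:

- **Input sampling noise** (zero-mean, sd ≈ 1.5–2.2 °C): a finite
  proteome of 30,000 residues resampled with uneven coverage weights
  simply does not carry the target fraction to better than a few parts
  per thousand, and 1 unit of *F* spans 937 °C. This bound lives in the
  reads themselves, before any prediction.
- **Frame-selection conditioning** (+1.7 to +2.4 °C mean, sd ≈ 1.3 °C):
  the unique-frame policy's kept-read enrichment described above.

Per-run tolerances in unit tests (±8 °C) reflect this budget.

## Seasonal cycle fitting

Monthly series are summarized by
`y(x) = A · sin(2π(x + φ)/P) + C` with the period fixed at P = 12
months, never fitted: the model is then linear in
(A cos 2πφ/P, A sin 2πφ/P, C) and solved in closed form by ordinary
least squares — deterministic, no iteration, no starting values. The
(−A, φ + P/2) ambiguity is resolved canonically to A ≥ 0, φ ∈ [0, P);
amplitudes below 10⁻⁹ of the data scale report phase 0 by convention. A
design matrix of rank < 3 (all samples at the same phase point) is an
error. The phase lag between two fits of common period is the wrapped
difference φ_b − φ_a in (−P/2, P/2], positive when the first series
peaks after the second; on the published community/water seasonal
curves (amplitude 1.9 vs 7 °C, phases 4.2 vs 6.1 months) this yields
+1.9 months — the community trails the water by about two months.

## Numerical and interface choices

- Gzip is detected from magic bytes, not file extension.
- FASTA/FASTQ parsing is delegated to Biopython's low-level iterators;
  malformed records raise errors carrying the record index.
- Temperatures are printed to 0.01 °C in logs; machine reports carry
  full precision.
- Fragment calls are sorted by (start, strand, frame); coordinates are
  always reported on the forward strand of the read, half-open, with a
  trailing stop codon included in the span but not the translation.
- `predict_ogt_proteome` refuses an empty proteome; `predict_mpt`
  reports `insufficient coding signal` instead, because an empty *sample*
  is a legitimate measurement outcome while an empty *genome* is a user
  error.

## Known limitations

- Six-frame scanning with frame disambiguation is a heuristic stand-in
  for a trained gene predictor; on real metagenomes containing
  intergenic DNA, a fraction of non-coding reads (~20–25 % at 181 bp)
  will present exactly one stop-free frame and contribute background
  composition.
- The calibration is prokaryotic; eukaryotic and viral reads are neither
  detected nor screened out here.
- Cold environments over-predict: cold adaptation has no specific
  IVYWREL signature, so the line flattens below ~15 °C in practice.
- Paired-end mates are treated as independent reads; no mate-pairing
  logic is applied.
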