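# metathermo

Predict the temperature of an environment from its shotgun metagenome.

Every prokaryote has an optimal growth temperature (OGT), and OGT leaves a
compositional fingerprint on the proteome: the fraction of the seven
residues Ile, Val, Tyr, Trp, Arg, Glu and Leu among all encoded amino
acids — written *F*<sub>IVYWREL</sub> — rises with growth temperature.
A single linear calibration turns composition into temperature:

```
OGT [°C] = 937 · F_IVYWREL − 335
```

Applied not to one genome but to the pooled coding fragments of a whole
metagenomic sample, the same line yields a **metagenomic predicted
temperature (MPT)**: communities dominated by thermophiles carry a higher
pooled IVYWREL fraction, and the predicted temperature tracks the habitat
temperature of warm, stable environments (hot springs, heated canals, the
human gut). The package is aimed at microbial ecologists who want a
taxonomy-free, annotation-free temperature readout from raw reads.

## What it does

- **`metathermo mpt`** — end-to-end prediction from FASTA/FASTQ reads
  (gzip transparent): quality filtering (length ≥ 50 bp, ≤ 1 ambiguous
  base per read), six-frame coding-fragment extraction with
  frame disambiguation, pooled composition, linear calibration.
- **`metathermo ogt`** — per-species OGT from a coding-sequence
  amino-acid FASTA.
- **`metathermo sinefit`** — fixed-period (12-month) sinusoidal
  least-squares fit for seasonal series, plus phase-lag estimation
  between two cycles (`metathermo.timeseries.phase_lag`) to quantify how
  long a community takes to respond to temperature change.
- **`metathermo simulate`** — truth-carrying synthetic communities:
  proteomes of prescribed *F*<sub>IVYWREL</sub>, reverse-translated to
  coding sequences, shredded into 181-bp reads at chosen coverage and
  N-injection rate.

Everything is also available as a library (`import metathermo`).

## Worked example

Simulate a 50 °C community and read its temperature back:

```
$ metathermo simulate --target-temp 50 --seed 0 --reads-out reads.fasta
INFO metathermo: wrote 2499 reads to reads.fasta (achieved temperature 50.01 degC)

$ metathermo mpt --input reads.fasta --out report.json
INFO metathermo: reads.fasta: MPT = 49.66 degC (F_IVYWREL = 0.41052 over 94100 residues)
```

`report.json` then contains (abridged):

```json
{
  "n_reads_in": 2499,
  "n_reads_pass": 2499,
  "n_orfs": 1577,
  "n_residues": 94100,
  "f_ivywrel": 0.4105207,
  "mpt_celsius": 49.6579,
  "status": "ok"
}
```

All 2499 simulated reads pass quality control; 1577 coding fragments are
pooled into 94,100 residues whose IVYWREL fraction of 0.4105 maps to
49.7 °C — within sampling noise of the 50 °C target. A sample yielding no
coding fragments reports `"status": "insufficient coding signal"` instead
of a fabricated temperature.

For a single genome (here a simulated mesophile proteome):

```
$ metathermo ogt --input proteome.faa
INFO metathermo: OGT = 36.99 degC
```

## Caveats

- Coding fragments come from deterministic six-frame scanning, not a
  trained gene model; see `docs/methods.md` for the frame-disambiguation
  policy and its measured accuracy.
- The calibration is linear and unclamped; predictions outside roughly
  0–110 °C trigger a warning rather than a correction. Cold environments
  are systematically over-predicted — cold adaptation lacks a specific
  amino-acid signature.
- Input reads are assumed adapter-trimmed; only the length and
  ambiguous-base filters are applied here.
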