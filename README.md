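# pttquant

Absolute quantification of premature transcription termination (PTT) from
droplet digital PCR, with an RT-qPCR comparison arm and a simulator of the
full reverse-transcription / site-directed-cleavage / droplet workflow.

## Background

Riboswitch-controlled genes produce a mixture of full-length and prematurely
terminated transcripts. The assay measures each transcript with three
amplicons: **P1** upstream of the termination site (detects all transcripts),
**P2** flanking an RNase-H cleavage site directed by a DNA oligomer (reports
cleavage efficiency), and **P3** downstream of the cleavage site (detects
full-length transcripts only). From absolute ddPCR concentrations:

- terminated concentration `T = P1 − P3`, full-length `FL = P3`;
- induction ratio `IR = (FL/T)₋ / (FL/T)₊` between a ligand-starved (Met−)
  and a ligand-replete (Met+) condition;
- the alternative `IR* = (P3/P1)₋ / (P3/P1)₊`, which is also computable from
  relative qPCR quantities (`RQ = 2^(−ΔΔCt)`).

Random-hexamer reverse transcription covers regions far from a transcript's
3′ end with more cDNA copies than regions close to it. Cutting the
full-length transcript at a directed site — so that P1 and P3 sit at the same
~200 nt distance from their respective 3′ ends — cancels this bias; the
simulator reproduces it and the analysis quantifies its effect (uncleaved
controls systematically underestimate IR).

## Layout

| module | contents |
| --- | --- |
| `pttquant.ddpcr` | droplet counts → copies/µl via the Poisson transform, confidence intervals, replicate pooling |
| `pttquant.ptt` | assay geometry validation, `T = P1 − P3` decomposition, cleavage efficiency, IR, IR*, with/without-cleavage comparison |
| `pttquant.qpcr` | ΔΔCt relative quantities, primer-efficiency QC (90–110 %, R² > 0.985), IR* from Cts |
| `pttquant.sim` | generative model: transcript pools, cleavage, 3′-distance-biased RT, droplet partitioning, end-to-end datasets |
| `pttquant.pipeline` | joins droplet data to sample sheets and produces tidy result tables |
| `pttquant.io` / `pttquant.cli` | CSV/YAML formats and the `pttquant` command |
| `pttquant.examples` | bundled published IR comparison table used as a worked example |

## CLI

```sh
# simulate a demo panel (5 genes × 2 conditions × 4 time points × 2 arms)
pttquant simulate -o sim/ --seed 1

# droplet counts → absolute concentrations
pttquant quantify sim/droplets.csv -o estimates.csv

# full PTT analysis: FL/T tables, IR, IR*, cleavage efficiency + comparison
pttquant ptt sim/droplets.csv sim/sample_sheet.csv -o results/ --control-gene gyrA

# qPCR arm: IR* from a Ct table, optional primer-efficiency QC
pttquant qpcr ct.csv -o irstar.csv --dilution-series dilutions.csv
```

Exit codes: 0 success, 1 data error, 2 configuration error. Input formats
are plain CSV with documented headers (see module docstrings in
`pttquant/io.py`); a QuantaSoft-style droplet export
(`Well, Sample, Positives, AcceptedDroplets`) is also accepted.

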