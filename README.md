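# flexiquantlf

Label-free identification of differentially modified peptides and
quantification of their modification extent from peptide-level intensity
tables (e.g. DIA/SWATH peptide reports), without any knowledge of the
modification types involved.

## Who this is for

Quantitative proteomics groups running time-series or case/control
label-free experiments who want to know, per peptide, *how much* of a
protein's pool became modified relative to a reference sample — without
heavy isotope-labelled standards, PTM enrichment, or specifying the
modifications up front.

## The method

The total copy number of a protein is shared by all of its proteolytic
peptides, so any covalent modification removes intensity from the
*unmodified* species of the affected peptide. For each protein and each
sample, the unmodified peptide intensities *y<sub>i</sub>* are regressed
against the reference sample intensities *x<sub>i</sub>* through the
origin:

> *y<sub>i</sub>* = *β x<sub>i</sub>* + *ε<sub>i</sub>*

The slope *β* absorbs protein-abundance differences between sample and
reference. The line is fitted robustly by RANSAC (default: 1000 trials per
run, subsets of ⌈*n*/2⌉ peptides, inlier rule (*y* − *βx*)² ≤ MAD(*y*)²,
where MAD is the unscaled median absolute deviation), executed 30 times per
sample with the best model selected by *r*². Then, per peptide:

1. **raw score** *s<sub>i</sub>* = 1 − (*βx<sub>i</sub>* − *y<sub>i</sub>*)/(*βx<sub>i</sub>*)
   = *y<sub>i</sub>*/(*βx<sub>i</sub>*) — 1 on the line, 0 at complete
   signal loss;
2. **outlier gate**: raw scores strictly above median + 3·MAD of all raw
   scores are excluded (high side only — low scores *are* the signal) and
   reported in `*_removed_peptides.csv`;
3. **RM score** (*Relative Modification* score): surviving raw scores are
   divided by the median of the three highest, so that unmodified peptides
   sit at ≈1. RM = 1 − modification extent;
4. **call**: RM < 0.5 → *likely* differentially modified, 0.5 ≤ RM < 0.6 →
   *possibly*, RM ≥ 0.6 → *likely not*.

Proteins need at least five complete peptides; smaller proteins can be
rescued by pooling user-asserted co-stoichiometric proteins into a
"superprotein" (regression and raw scores on the pooled peptides, outlier
gating and RM scaling per protein — the slope cancels in RM scores, so
pooling is exactly equivalent for proteins analysable on their own).

## Worked example

Reference intensities `[10, 20, 30, 40, 50, 60]`, one sample identical
except the last peptide dropped to half:

```python
import pandas as pd
import flexiquantlf as fq

data = pd.DataFrame(
    [[10, 20, 30, 40, 50, 60], [10, 20, 30, 40, 50, 30]],
    index=["t0", "t1"],
    columns=pd.MultiIndex.from_product([["CDCX"], [f"pep{i}" for i in range(1, 7)]]),
)
table = fq.IntensityTable(data, reference_samples=["t0"])
result = fq.analyze_protein(table, "CDCX", seed=0)

print("slope:", result.fits["t1"].slope)
print(result.rm_frame().round(3).to_string())
print(result.calls("t1")[["peptide", "rm_score", "category"]].to_string(index=False))
```

prints

```
slope: 1.0
        pep1  pep2  pep3  pep4  pep5  pep6
sample
t0       1.0   1.0   1.0   1.0   1.0   1.0
t1       1.0   1.0   1.0   1.0   1.0   0.5
peptide  rm_score   category
   pep1       1.0 likely_not
   pep2       1.0 likely_not
   pep3       1.0 likely_not
   pep4       1.0 likely_not
   pep5       1.0 likely_not
   pep6       0.5   possibly
```

The regression pins the five consistent peptides (slope 1: no abundance
change), pep6's unmodified intensity is at 50% of expectation — an RM score
of 0.5, i.e. half of the protein molecules appear modified at that peptide
relative to t0 — and the 0.5/0.6 cutoffs call it *possibly* differentially
modified.

## Command line

```bash
flexiquant-lf run --input peptides.csv --output-dir out/ --reference S_phase \
    [--layout wide|wide-flat|long] [--replicate-map reps.csv] \
    [--superprotein groups.csv] [--call-sample 10hr] [--seed 7]
```

writes `<base>_RM_scores.csv`, `<base>_raw_scores.csv`,
`<base>_removed_peptides.csv`, `<base>_diagnostics.csv` (slope, *r*²,
inlier count, thresholds, scaling factor per protein/sample) and
`<base>_calls.csv`. Input layouts are described in the docstring of
`flexiquantlf.io` (wide: two header rows protein/peptide; long: tidy
sample/protein/peptide/intensity rows).

Two validation harnesses are also exposed:

```bash
flexiquant-lf benchmark --n-proteins 100 --cv 0.05 --k 4 --seed 1 --output-dir bench/
flexiquant-lf reproducibility --input peptides.csv --reference S_phase \
    --protein CDC27 --runs 1000 --ladder 1,10,20,30 --output-dir rep/
```

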