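# twopan

Differential analysis of **two-arm phage-display selections** from
multi-round amplicon sequencing.

When an SH2-domain variant library is panned in parallel against two nearly
identical ligands — a sulfotyrosine (sTyr) peptide and its phosphotyrosine
(pTyr) counterpart — pool-level binding assays cannot tell which clones are
*specific* for the intended target: dual binders and background-sticky
clones enrich in both arms.  `twopan` answers that question computationally.
It takes per-round paired-end amplicon FASTQ for both selection arms
(R0 = naive library, R1..R4 = panning rounds), extracts and translates the
11 evolvable pocket residues of each read, and scores variants by how
differently they behave between the arms.

The pipeline implements:

* **Library design math** — soft randomization synthesizes each evolvable
  codon from doped nucleotide mixtures (template base kept with fraction
  *p*, the other three bases at (1−*p*)/3 each).  `solve_base_retention`
  calibrates *p* for a requested per-position mutation rate at the codon or
  amino-acid level by genetic-code enumeration and root finding, predicts
  the expected residue distribution per position, and emits degenerate
  primer specifications with explicit mixture tables.
* **Read tallying** — anchor-based orientation and overlap-consensus merge
  of mate pairs, fixed-frame extraction of the three doped regions between
  constant anchors (substitutions tolerated, indels rejected), translation,
  and per-round variant counts with full QC accounting.
* **Enrichment classification** — per-position residue proportions in
  percent of QC-passing reads; the proportion change Δ from the naive
  library to the final round classifies each (position, residue) as
  enriched (Δ > 5), depleted (Δ < −5), or neutral.
* **Enrichment index (EI) scoring** — for a variant *v* with residues
  *v₁..v₁₁* and a classification map *C*,

  EI(v) = Σₚ C[p, vₚ] ∈ [−11, +11],

  computed against each arm; the **EI difference** EI_sTyr − EI_pTyr, the
  0.1% abundance filter over the last two target-arm rounds, and the
  per-arm trajectory trends rank candidate sTyr-specific binders.
* **A ground-truthed simulator** — naive-library sampling from the doped
  mixtures, multinomial capture/log-normal amplification selection rounds
  with planted specific / dual / sticky variants, and paired-end FASTQ
  emission with configurable depth and base-error rate, so the whole
  pipeline is testable without the deposited raw data.

## Worked example

`examples/03_classify_and_score.py` simulates a reduced-scale two-arm
selection (5 000 naive clones, 20 000 read pairs per round, seed 7) with
three planted sTyr-specific variants, three dual binders and one
background-sticky clone, then runs the full analysis:

```
enriched in both arms: R@P1 C@P2 S@P3 E@P4 H@P7 V@P8 H@P9 Y@P10 L@P11
opposite sign between arms: G@P5 R@P5 L@P6 Y@P7

rank variant      EI(sTyr) EI(pTyr) EI_diff  sTyr trajectory (%)
   1 KCSEGLYVHYL       11        4       7  0.14 1.58 11.24 15.19 20.80
   2 RCSEGLYVHYL       11        5       6  0.11 1.89 14.33 21.47 24.12
   3 RCSEGVYVHYL       10        7       3  0.12 2.25 19.12 26.65 29.63

planted sTyr-specific truth: ['KCSEGLYVHYL', 'RCSEGLYVHYL', 'RCSEGVYVHYL']
```

Reading the numbers: the EI columns say how many of a variant's 11 pocket
residues were enriched (+1) or depleted (−1) in each arm's round-4 vs naive
comparison; a large sTyr EI with a smaller pTyr EI (positive EI difference)
plus a rising sTyr trajectory and a falling/flat pTyr trajectory is the
signature of a target-specific binder.  The three top-ranked variants are
exactly the planted ground truth; the dual binders score high EI in *both*
arms and are excluded by the trajectory filter.

The other example scripts cover the library-design math
(`01_library_design.py`), tallying and QC (`02_simulate_and_tally.py`), and
the background-stickiness diagnostic via residue prevalence and Pearson
correlation (`04_background_diagnostic.py`).

## Command line

The same stages are available as a thin CLI for shell pipelines:

```bash
twopan simulate --seed 7 --out-dir sim/
twopan run-all --samples sim/samples.tsv --out-dir run/
twopan report --run-dir run/
```

`tally`, `classify` and `score` run the stages individually; all thresholds
(classification cutoff 5, abundance cutoff 0.1%, reference round 0 vs the
last round, trend folds) are exposed as flags.  Stage outputs are plain TSV
plus one JSON summary per stage; exit codes are 0 (ok), 2 (usage),
3 (input error), 4 (internal).

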