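# Methods

## Problem setting

A soft-randomized SH2-domain library (11 evolvable pocket residues,
P1–P11; template pocket sequence `RQLARVYAHYL`) is panned in parallel
against a sulfotyrosine (sTyr) peptide and its phosphotyrosine (pTyr)
counterpart.  Amplicon sequencing of every round in both arms gives, per
(arm, round), a set of reads covering the three doped regions of the
amplicon.  The analysis asks which variants are *specific* for sTyr — i.e.
enrich in the sTyr arm while depleting or stagnating in the pTyr arm — and
ranks them for experimental follow-up.

## Library design model

Each evolvable codon is synthesized from three doped nucleotide mixtures:
the template base is retained with fraction *p* and each non-template base
appears with (1−*p*)/3.  The per-position mutation rate as a function of
*p* is computed exactly by enumerating all 64 codons weighted by the
product of per-base mixture fractions.  Two calibration levels exist:

* **codon** — any nucleotide change counts; closed form *p* = (1−rate)^⅓;
* **amino_acid** (default) — only a changed residue counts, with stop
  codons counted as mutations.  Synonymous codons raise residue retention,
  so the required *p* is strictly smaller for codons with synonyms; it is
  found by bisection (`brentq` on [0.25, 1], tolerance 1e−12).

The default calibrates every position to a 50% amino-acid-level mutation
rate, the doping strength used to build the study library.  Rates above the
uniform-mixture limit (e.g. ≳ 90% for leucine's six codons) are rejected
with the achievable range in the error message.

Expected naive-library profiles renormalize away the stop-codon mass,
because clones with a stop in the variable region do not display on phage
and are never observed in panning reads.  Template-residue proportions
therefore sit slightly above 50% (e.g. 55.3% for tyrosine positions, whose
doped distribution has relatively high stop mass).

Primer specifications are emitted as plain text with mixture-class labels
(N1, N2, …) plus an explicit fraction table, since IUPAC degeneracy codes
cannot express unequal fractions; the text round-trips through a parser.
Designs carry a primer grouping so that two doped regions sharing a short
internal constant (`AAAGGTGCG`) are written as one mutagenic oligo, while
the third region, separated by a long template segment, is its own oligo.

## Amplicon layout and read processing

The default amplicon is fixed-length (112 nt): forward constant flank
`GAGGTACCTTTCTTATC`, 18 nt doped (P1–P6), `AAAGGTGCG`, 6 nt doped (P7–P8),
a 36 nt internal template segment, 9 nt doped (P9–P11), reverse flank
`ATTCGCAAACTTGACAA`.  Template codons for the 11 residues are
config-supplied (the analysis depends only on translated 11-mers);
coordinates are 0-based, half-open throughout.

Mate pairs are oriented by trying both strands of both mates: the forward
candidate must begin with the forward flank and the opposing mate must end
with the reverse flank, each within 3 substitutions.  Overlapping bases are
merged by consensus; a disagreement **inside a doped region** fails the
fragment (`ambiguous_base`), while a disagreement in a constant segment
keeps the forward mate's base and is absorbed by the per-anchor mismatch
tolerance (default 1 substitution per anchor, no indels anywhere — an indel
would corrupt the codon frame, so fixed-frame extraction rejects
length-changed fragments instead of realigning them).  Extraction then
checks every constant segment at its expected offset (flank failures →
`anchor_fail`, internal failures → `unexpected_constant`), requires clean
ACGT codons (`ambiguous_base` otherwise) and no stop (`stop_codon`), and
translates with the standard genetic code.  Every fragment contributes
exactly one QC status; only `designed` fragments contribute variant counts.
Base qualities are not used for filtering by default; an optional
minimum-mean-quality flag exists.

## Enrichment statistics

Proportions are carried in **percent of designed reads** so the published
thresholds apply literally.  For each arm, the proportion change
Δ(position, residue) between the naive round (reference, default R0) and
the comparison round (default: last round; R3 gives similar results) feeds
the classification: enriched iff Δ > 5, depleted iff Δ < −5 — strict
inequalities, no pseudo-counts (absent residues have proportion exactly 0;
the absolute cutoff is robust to zeros).  Frequency rows sum to 100 and
delta rows to 0 by construction, and raising the cutoff can only zero
cells, never flip a sign.

The enrichment index of a variant against a classification map is the sum
of the map values at its 11 residues, bounded by ±11; the EI difference is
the sTyr EI minus the pTyr EI.  Candidate prioritization applies, in order:

1. **abundance** — proportion strictly above 0.1% in each of the final two
   sTyr rounds ("last few rounds" is read minimally as two, configurable);
2. **trend** — sTyr trajectory increasing, pTyr trajectory decreasing or
   flat.  A trajectory is *increasing* when the final proportion is at
   least `fold_up` (2×) times max(first detected proportion, 0.01%) and the
   last two transitions are non-decreasing up to a relative slack of 15%
   (`tail_slack`); *decreasing* is symmetric with `fold_down` (0.5×).  The
   slack exists because once a handful of winners jointly dominate the pool
   (~80% combined share) their individual shares jitter round-to-round even
   though selection is still operating; a strictly monotone rule would
   miscall genuinely enriching clones.  All trend parameters are
   configurable;
3. **ranking** — EI difference desc, then sTyr EI desc, then final sTyr
   proportion desc, ties broken lexicographically by variant string so the
   output is byte-reproducible.

Diagnostics include per-round residue prevalence (percent of designed reads
carrying a residue at a position — the cysteine-at-P10 background
diagnostic) and a Pearson correlation helper that raises on zero-variance
input rather than returning 0.

## Synthetic data generator

The simulator provides ground truth for validation; its defaults are the
study conditions at desk scale:

| parameter | default | meaning |
|---|---|---|
| `n_clones` | 10⁴ | naive clones sampled from the doped mixtures (the real library's ~10⁹ capacity, emulated) |
| `rounds` | 4 | panning rounds per arm, from a shared naive library |
| `depth` | 5×10⁴ | read pairs per (arm, round) (vs ~1.6 M in the study) |
| `capture_size` | 10⁴ | multinomial capture per round |
| `amp_sigma` | 0.2 | per-clone log-normal amplification dispersion |
| `baseline_sigma` | 0.3 | log-normal spread of unplanted variants' affinity (one draw per variant, shared by both arms) |
| `background_weight` | 0.2 | baseline background-capture weight |
| `error_rate` | 7.5×10⁻⁴ | per-base substitution rate in emitted reads |

One selection round is: capture `capture_size` phage by multinomial
sampling with probability ∝ clone abundance × (arm weight + background
weight), multiply each captured clone by an independent log-normal factor
(mean 1), rescale to the population size.  This is the simplest update that
yields round-over-round exponential enrichment; it does not model display
valency, growth competition, or elution chemistry.  Negative selection
against streptavidin is represented only through the background weight
term.  Clones carry explicit codons, so synonymous diversity and stop-codon
loss (non-displaying clones are discarded at sampling) are representable.

The default planted truth is 3 sTyr-specific variants (arm weights 30 / 1),
3 dual binders (20 / 20) and 1 background-sticky clone marked by C@P10
(weights 1 / 1, background 8), each at 0.1% naive abundance (sticky: 0.5%).
The base error rate was set analytically: with 33 doped bases read twice,
mate disagreement discards ≈ 2·e·33 of pairs, so e = 7.5×10⁻⁴ puts the
designed-read fraction near 0.95, matching the study's QC pass rate.  All
randomness flows from a single scenario seed through named `SeedSequence`
children; FASTQ output is byte-identical per seed (gzip mtime pinned to 0).

What the simulator does **not** emulate: Illumina error profiles beyond
uniform substitutions (no quality-correlated or indel errors), PCR
amplification bias and chimeras, round-specific stringency changes (unless
configured via `background_scale`), and the real library's scale.  Passing
tests therefore demonstrate the pipeline's correctness and the scoring
scheme's discriminative power under this generative model, not performance
on the deposited sequencing data — which can still be processed by pointing
a sample sheet at the downloaded FASTQ files.

## Numerical and design choices

* Proportion denominators are designed (QC-passing) reads, not total
  reads: the distributions describe library variants, not artifacts.
* The study's exact high-quality-read filter is specified only by citation;
  it is not reproduced, and the QC report documents its own statuses
  instead.
* Region→position mapping defaults to amplicon order (region 1 → P1–P6,
  region 2 → P7–P8, region 3 → P9–P11) and is configurable, as is the true
  orientation of the mutagenic oligos (handled by both-strand search).
* EI values default to the round-4-vs-naive classification; a round-3
  comparison is available via `comparison_round`.
* Variants absent from a round have proportion exactly 0 (no imputation);
  a variant missing one arm entirely is flagged and excluded from ranking.
* Analysis scale in tests (reduced clone counts/depths for shared
  fixtures) was chosen so sampling noise stays well inside the assertion
  tolerances derived from binomial standard errors.

## Known limitations

* With only ~10⁴ naive clones, most theoretical variant diversity is
  unsampled; recovery statistics speak to planted-variant scenarios, not to
  rare-variant sensitivity at production scale.
* The 5-point classification cutoff is an absolute threshold, not a
  significance test; at very low sequencing depth it conflates sampling
  noise with selection (the null-control tests quantify the margin at the
  default depth).
* Anchor matching tolerates substitutions only; reads with indels in
  constant regions are dropped rather than rescued by alignment.
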