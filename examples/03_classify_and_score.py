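"""From round tallies to a ranked list of target-specific candidates.

Classification compares each arm's round-4 residue proportions against the
shared naive library (round 0): a residue moving by more than 5 percentage
points at a position is enriched (+1) or depleted (-1).  Each variant's
enrichment index (EI) sums those values over its 11 pocket residues, and the
EI difference (sTyr minus pTyr) plus the per-arm proportion trajectories
separate sTyr-specific binders from dual binders and sticky background
clones.
"""

import tempfile
from pathlib import Path

import twopan as tp

workdir = Path(tempfile.mkdtemp(prefix="twopan_example_"))
result = tp.run_scenario(tp.ScenarioConfig(n_clones=5000, depth=20_000, seed=7), workdir)
analysis = tp.analyze_run(result.sample_sheet, result.design)

summary = tp.classification_concordance(
    analysis.classifications["sTyr"], analysis.classifications["pTyr"]
)
print("enriched in both arms:", " ".join(summary.shared_enriched))
print("opposite sign between arms:", " ".join(summary.opposite) or "-")
print()

print("rank variant      EI(sTyr) EI(pTyr) EI_diff  sTyr trajectory (%)")
for rec in analysis.ranked()[:5]:
    trj = analysis.trajectories["sTyr"][rec.variant]
    series = " ".join(f"{p:.2f}" for p in trj.proportions)
    print(
        f"{rec.rank:>4} {rec.variant} {rec.ei_sTyr:>8} {rec.ei_pTyr:>8} "
        f"{rec.ei_difference:>7}  {series}"
    )
print()
print("planted sTyr-specific truth:", sorted(result.truth.planted_specific))
print("the top ranks are the planted specifics: they rise only in the sTyr")
print("arm and carry the sTyr-enriched pocket residues, so their EI")
print("difference dominates dual binders (high EI in BOTH arms) and the")
print("sticky background clone (no arm preference).")
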