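"""Simulate a two-arm selection and tally the sequencing reads.

A ground-truthed scenario plants sTyr-specific, dual-binding, and
background-sticky variants into a soft-randomized naive library, runs four
rounds of panning per arm, and writes paired-end FASTQ per round.  The tally
stage then recovers per-variant counts and QC statistics from those reads.
Run time is a couple of minutes at this reduced scale.
"""

import tempfile
from pathlib import Path

import twopan as tp

workdir = Path(tempfile.mkdtemp(prefix="twopan_example_"))
config = tp.ScenarioConfig(n_clones=5000, depth=20_000, seed=7)
result = tp.run_scenario(config, workdir)
print(f"simulated dataset in {workdir}")
print(f"planted sTyr-specific variants: {sorted(result.truth.planted_specific)}\n")

rows = tp.sequencing_io.read_sample_sheet(result.sample_sheet)
rounds = tp.tally_samples(rows, result.design)
qc = tp.qc_report([rc for rcs in rounds.values() for rc in rcs])
print(qc.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\ndesigned_fraction sits near 0.95: read pairs disagreeing inside a")
print("variable codon (sequencing error) are excluded, like the study's")
print("'unexpected mutations' bucket; the rest of the QC columns break the")
print("failures down by cause.")
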