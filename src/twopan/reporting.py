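"""Consolidated run reports.

Everything in the report is recomputed or re-read from the stage outputs in
the run directory (tally/, classify/, score/) — no hidden state — so
regenerating the report from the same directory is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .enrichment import classification_concordance, read_matrix

__all__ = ["consolidated_report"]

STAGES = ("tally", "classify", "score")


def consolidated_report(run_dir) -> tuple[str, dict]:
    """Build the consolidated summary for a completed ``run-all`` directory.

    Returns ``(text, payload)``: a human-readable report and the equivalent
    machine-readable document.  An incomplete run raises a ValueError that
    lists the missing stages.
    """
    run = Path(run_dir)
    missing = [s for s in STAGES if not (run / s).is_dir()]
    if missing:
        raise ValueError(
            f"incomplete run in {run}: missing stage directories {missing}"
        )

    qc = pd.read_csv(run / "tally" / "qc_summary.tsv", sep="\t")
    with open(run / "classify" / "classify_summary.json") as fh:
        classify_summary = json.load(fh)
    with open(run / "score" / "score_summary.json") as fh:
        score_summary = json.load(fh)
    candidates = pd.read_csv(run / "score" / "candidates.tsv", sep="\t")

    cmaps = {
        arm: read_matrix(run / "classify" / f"classification_{arm}.tsv")
        for arm in ("sTyr", "pTyr")
    }
    concordance = classification_concordance(cmaps["sTyr"], cmaps["pTyr"])

    for rec in score_summary["top"]:
        if rec["ei_difference"] != rec["ei_sTyr"] - rec["ei_pTyr"]:
            raise ValueError(
                f"inconsistent EI difference for {rec['variant']} in score summary"
            )

    lines = ["# twopan consolidated report", "", "## QC per (arm, round)", ""]
    lines.append(qc.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    lines += ["", "## Enriched / depleted residues (residue@position)", ""]
    for arm in ("sTyr", "pTyr"):
        tokens = classify_summary["tokens"][arm]
        lines.append(f"{arm} enriched: {' '.join(tokens['enriched']) or '-'}")
        lines.append(f"{arm} depleted: {' '.join(tokens['depleted']) or '-'}")
    lines += [
        "",
        "## Two-arm concordance",
        "",
        f"enriched in both arms: {' '.join(concordance.shared_enriched) or '-'}",
        f"depleted in both arms: {' '.join(concordance.shared_depleted) or '-'}",
        f"opposite sign: {' '.join(concordance.opposite) or '-'}",
        "",
        "## Top candidates (EI columns: sTyr, pTyr, difference)",
        "",
    ]
    if score_summary["top"]:
        lines.append("rank variant      EI(sTyr) EI(pTyr) EI_diff")
        for rec in score_summary["top"]:
            lines.append(
                f"{rec['rank']:>4} {rec['variant']} {rec['ei_sTyr']:>8} "
                f"{rec['ei_pTyr']:>8} {rec['ei_difference']:>7}"
            )
    else:
        lines.append("(no variant passed the filters)")

    lines += ["", "## Candidate trajectories (percent of designed reads)", ""]
    traj_cols = [c for c in candidates.columns if "_R" in c]
    ranked = candidates[candidates["rank"].notna() & (candidates["rank"] != "")]
    payload_traj = {}
    for _, row in ranked.iterrows():
        series = {c: float(row[c]) for c in traj_cols if pd.notna(row[c])}
        payload_traj[row["variant"]] = series
        pretty = " ".join(f"{c.split('_', 1)[1]}={v:.3f}" for c, v in series.items())
        lines.append(f"{row['variant']} sTyr:{row['trend_sTyr']} pTyr:{row['trend_pTyr']}")
        lines.append(f"    {pretty}")

    payload = {
        "qc": qc.to_dict(orient="records"),
        "classification": classify_summary,
        "concordance": {
            "shared_enriched": concordance.shared_enriched,
            "shared_depleted": concordance.shared_depleted,
            "opposite": concordance.opposite,
        },
        "candidates": score_summary["top"],
        "trajectories": payload_traj,
        "params": score_summary["params"],
    }
    return "\n".join(lines) + "\n", payload
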