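"""End-to-end orchestration: tally all rounds from a sample sheet, classify
both arms against the naive round, and score/rank candidate variants."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .enrichment import (
    DEFAULT_CUTOFF,
    classify,
    position_frequencies,
    proportion_change,
)
from .library_design import LibraryDesign
from .scoring import ScoringParams, score_variants, variant_trajectory
from .sequencing_io import RoundCounts, TallyParams, read_sample_sheet, tally_round

__all__ = ["AnalysisParams", "AnalysisResult", "tally_samples", "analyze_rounds", "analyze_run"]


@dataclass(frozen=True)
class AnalysisParams:
    cutoff: float = DEFAULT_CUTOFF  # classification cutoff, percentage points
    reference_round: int = 0
    comparison_round: Optional[int] = None  # default: last tallied round
    scoring: ScoringParams = ScoringParams()
    tally: TallyParams = TallyParams()


@dataclass
class AnalysisResult:
    rounds: dict  # arm -> [RoundCounts sorted by round]
    frequencies: dict  # (arm, round) -> FrequencyTable
    deltas: dict  # arm -> DeltaTable
    classifications: dict  # arm -> ClassificationMap
    records: list  # ranked EIRecords
    trajectories: dict  # arm -> {variant -> Trajectory}

    def ranked(self) -> list:
        return [r for r in self.records if r.rank is not None]


def tally_samples(
    sheet_rows: Sequence[dict],
    design: LibraryDesign,
    params: TallyParams = TallyParams(),
) -> dict:
    """Tally every (arm, round) in a sample sheet; multiple rows for the same
    (arm, round) are pooled."""
    grouped: dict[tuple, list] = {}
    for row in sheet_rows:
        key = (row["arm"], row["round"])
        entry = (row["r1"], row["r2"]) if row.get("r2") else row["r1"]
        grouped.setdefault(key, []).append(entry)
    out: dict[str, list[RoundCounts]] = {}
    for (arm, rnd), files in sorted(grouped.items()):
        out.setdefault(arm, []).append(tally_round(files, arm, rnd, design, params))
    for arm in out:
        out[arm].sort(key=lambda rc: rc.round)
    return out


def analyze_rounds(
    rounds_by_arm: dict,
    design: LibraryDesign,
    params: AnalysisParams = AnalysisParams(),
) -> AnalysisResult:
    """Classification and scoring from already-tallied rounds (two arms)."""
    n_positions = design.n_positions
    frequencies: dict = {}
    deltas: dict = {}
    classifications: dict = {}
    for arm, rounds in rounds_by_arm.items():
        for rc in rounds:
            frequencies[(arm, rc.round)] = position_frequencies(rc, n_positions)
        comparison = params.comparison_round
        if comparison is None:
            comparison = max(rc.round for rc in rounds)
        delta = proportion_change(
            frequencies[(arm, comparison)],
            frequencies[(arm, params.reference_round)],
        )
        deltas[arm] = delta
        classifications[arm] = classify(delta, params.cutoff)

    arms = sorted(rounds_by_arm)
    if set(arms) != {"sTyr", "pTyr"}:
        raise ValueError(f"need both sTyr and pTyr arms, got {arms}")
    records = score_variants(
        rounds_by_arm["sTyr"],
        rounds_by_arm["pTyr"],
        classifications["sTyr"],
        classifications["pTyr"],
        params.scoring,
    )
    trajectories = {
        arm: {
            rec.variant: variant_trajectory(
                rec.variant, rounds_by_arm[arm], params.scoring
            )
            for rec in records
        }
        for arm in ("sTyr", "pTyr")
    }
    return AnalysisResult(
        rounds=rounds_by_arm,
        frequencies=frequencies,
        deltas=deltas,
        classifications=classifications,
        records=records,
        trajectories=trajectories,
    )


def analyze_run(
    sample_sheet_path,
    design: LibraryDesign,
    params: AnalysisParams = AnalysisParams(),
) -> AnalysisResult:
    """Full pipeline from a sample sheet: tally -> classify -> score."""
    rows = read_sample_sheet(sample_sheet_path)
    rounds = tally_samples(rows, design, params.tally)
    return analyze_rounds(rounds, design, params)
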