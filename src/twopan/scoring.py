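"""Per-variant enrichment indices, round trajectories, and prioritization of
target-specific binders from a two-arm selection.

The enrichment index (EI) of a variant against one arm's classification map
is the sum over evolvable positions of +1 for an enriched residue, -1 for a
depleted residue and 0 otherwise, so it lies in [-n, +n] for n positions.
The EI difference (sTyr EI minus pTyr EI) together with the per-arm
proportion trajectories separates target-specific binders from variants that
rise in both arms or bind the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .enrichment import ClassificationMap
from .sequencing_io import RoundCounts

__all__ = [
    "Trajectory",
    "EIRecord",
    "ScoringParams",
    "enrichment_index",
    "ei_difference",
    "variant_trajectory",
    "prioritize",
    "residue_prevalence",
    "pearson_correlation",
    "score_variants",
    "candidate_table",
]


@dataclass(frozen=True)
class ScoringParams:
    """Filter/trend thresholds for candidate prioritization.

    ``abundance_cutoff``: percent of designed reads a candidate must exceed
    (strictly) in each of the final ``last_rounds`` rounds of the target arm.
    ``fold_up``/``fold_down``: final/first proportion fold changes that call
    a trajectory increasing/decreasing; ``floor`` (percent) guards the fold
    test against near-zero starting proportions.
    """

    abundance_cutoff: float = 0.1
    last_rounds: int = 2
    fold_up: float = 2.0
    fold_down: float = 0.5
    floor: float = 0.01
    top_k: int = 10
    ei_cutoff: Optional[int] = None  # optional minimum EI difference to rank
    # Relative slack for the tail-monotonicity test: once winners jointly
    # saturate the pool their individual shares jitter, so an "increasing"
    # tail tolerates transitions down to (1 - tail_slack) x previous round.
    tail_slack: float = 0.15


@dataclass
class Trajectory:
    variant: str
    arm: str
    rounds: list[int]
    proportions: list[float]  # percent of designed reads, per round
    trend: str  # {increasing, decreasing, flat}


@dataclass
class EIRecord:
    variant: str
    ei_sTyr: int
    ei_pTyr: int
    ei_difference: int
    detected_rounds: dict = field(default_factory=dict)  # arm -> [round, ...]
    passes_abundance: bool = False
    passes_trend: bool = False
    rank: Optional[int] = None


def enrichment_index(variant: str, cmap: ClassificationMap) -> int:
    """Sum of the classification values of the variant's residues across the
    evolvable positions."""
    positions = list(cmap.matrix.index)
    if len(variant) != len(positions):
        raise ValueError(
            f"variant {variant!r} has {len(variant)} residues; map has "
            f"{len(positions)} positions"
        )
    total = 0
    for pos, aa in zip(positions, variant):
        if aa not in cmap.matrix.columns:
            raise ValueError(f"invalid residue {aa!r} at position {pos}")
        total += int(cmap.matrix.at[pos, aa])
    return total


def ei_difference(ei_styr: int, ei_ptyr: int) -> int:
    """Target-arm EI minus counter-target EI (sTyr EI - pTyr EI)."""
    for v in (ei_styr, ei_ptyr):
        if not -11 <= v <= 11:
            raise ValueError(f"EI value {v} outside [-11, 11]")
    return ei_styr - ei_ptyr


def variant_trajectory(
    variant: str,
    rounds: Sequence[RoundCounts],
    params: ScoringParams = ScoringParams(),
) -> Trajectory:
    """Proportion of one variant across the rounds of one arm, with a trend
    label.

    Increasing: final proportion >= fold_up x max(first detected proportion,
    floor) and non-decreasing over the last two transitions.  Decreasing is
    symmetric with fold_down and non-increasing transitions.  Everything
    else — including a never-observed variant — is flat.
    """
    ordered = sorted(rounds, key=lambda r: r.round)
    if len({r.arm for r in ordered}) > 1:
        raise ValueError("trajectory rounds must come from a single arm")
    props = [r.proportion_percent(variant) for r in ordered]
    trend = _trend(props, params)
    return Trajectory(
        variant=variant,
        arm=ordered[0].arm,
        rounds=[r.round for r in ordered],
        proportions=props,
        trend=trend,
    )


def _trend(props: Sequence[float], params: ScoringParams) -> str:
    nonzero = [p for p in props if p > 0]
    if not nonzero or len(props) < 2:
        return "flat"
    first = max(nonzero[0], params.floor)
    final = props[-1]
    tail = props[-3:]  # last two transitions (or one, for 2-round series)
    slack = params.tail_slack
    if final >= params.fold_up * first and all(
        b >= a * (1 - slack) for a, b in zip(tail, tail[1:])
    ):
        return "increasing"
    if final <= params.fold_down * first and all(
        b <= a * (1 + slack) for a, b in zip(tail, tail[1:])
    ):
        return "decreasing"
    return "flat"


def score_variants(
    rounds_styr: Sequence[RoundCounts],
    rounds_ptyr: Sequence[RoundCounts],
    cmap_styr: ClassificationMap,
    cmap_ptyr: ClassificationMap,
    params: ScoringParams = ScoringParams(),
    variants: Optional[Sequence[str]] = None,
) -> list[EIRecord]:
    """Build EI records with trajectories and filter flags for every variant
    observed in either arm (or the given subset), then rank candidates."""
    rounds_styr = sorted(rounds_styr, key=lambda r: r.round)
    rounds_ptyr = sorted(rounds_ptyr, key=lambda r: r.round)
    if variants is None:
        seen: set[str] = set()
        for rc in (*rounds_styr, *rounds_ptyr):
            seen.update(rc.counts)
        variants = sorted(seen)
    records, trj_s, trj_p = [], {}, {}
    for v in variants:
        ts = variant_trajectory(v, rounds_styr, params)
        tp = variant_trajectory(v, rounds_ptyr, params)
        trj_s[v], trj_p[v] = ts, tp
        ei_s = enrichment_index(v, cmap_styr)
        ei_p = enrichment_index(v, cmap_ptyr)
        records.append(
            EIRecord(
                variant=v,
                ei_sTyr=ei_s,
                ei_pTyr=ei_p,
                ei_difference=ei_difference(ei_s, ei_p),
                detected_rounds={
                    "sTyr": [r for r, p in zip(ts.rounds, ts.proportions) if p > 0],
                    "pTyr": [r for r, p in zip(tp.rounds, tp.proportions) if p > 0],
                },
            )
        )
    return prioritize(records, trj_s, trj_p, params)


def prioritize(
    ei_records: Sequence[EIRecord],
    trajectories_styr: dict,
    trajectories_ptyr: dict,
    params: ScoringParams = ScoringParams(),
) -> list[EIRecord]:
    """Filter and rank candidate target-specific binders.

    Filters: proportion strictly above ``abundance_cutoff`` percent in each
    of the final ``last_rounds`` target-arm rounds; target-arm trend
    increasing; counter-arm trend decreasing or flat.  Survivors are ranked
    by (EI difference desc, target EI desc, final target proportion desc),
    ties broken lexicographically by variant.  Every record gets pass/fail
    flags; variants missing either arm's trajectory are flagged and excluded.
    """
    ranked: list[tuple] = []
    out = list(ei_records)
    for rec in out:
        rec.rank = None
        ts = trajectories_styr.get(rec.variant)
        tp = trajectories_ptyr.get(rec.variant)
        if ts is None or tp is None:
            rec.passes_abundance = False
            rec.passes_trend = False
            continue
        tail = ts.proportions[-params.last_rounds :]
        rec.passes_abundance = len(tail) == params.last_rounds and all(
            p > params.abundance_cutoff for p in tail
        )
        rec.passes_trend = ts.trend == "increasing" and tp.trend in (
            "decreasing",
            "flat",
        )
        if params.ei_cutoff is not None and rec.ei_difference < params.ei_cutoff:
            continue
        if rec.passes_abundance and rec.passes_trend:
            ranked.append(
                (
                    -rec.ei_difference,
                    -rec.ei_sTyr,
                    -ts.proportions[-1],
                    rec.variant,
                    rec,
                )
            )
    ranked.sort(key=lambda t: t[:4])
    for i, (*_, rec) in enumerate(ranked, start=1):
        rec.rank = i
    out.sort(
        key=lambda r: (r.rank is None, r.rank if r.rank is not None else 0, r.variant)
    )
    return out


def residue_prevalence(
    residue: str, position: int, rounds: Sequence[RoundCounts]
) -> list[float]:
    """Percent of designed reads whose variant carries ``residue`` at the
    1-based evolvable ``position``, per round (sorted by round index)."""
    if position < 1:
        raise ValueError("position is 1-based")
    out = []
    for rc in sorted(rounds, key=lambda r: r.round):
        designed = rc.designed_reads
        if designed == 0:
            out.append(0.0)
            continue
        hits = sum(
            n for v, n in rc.counts.items() if v[position - 1] == residue
        )
        out.append(100.0 * hits / designed)
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; errors (rather than returning 0)
    on fewer than 3 points or zero variance."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal lengths")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    xs, ys = pd.Series(x, dtype=float), pd.Series(y, dtype=float)
    if xs.var() == 0 or ys.var() == 0:
        raise ValueError("Pearson correlation undefined for zero variance")
    return float(stats.pearsonr(xs, ys).statistic)


def candidate_table(
    records: Sequence[EIRecord],
    trajectories_styr: dict,
    trajectories_ptyr: dict,
) -> pd.DataFrame:
    """Flat candidate table: EI columns, per-round proportions for both arms,
    trend labels, filter flags, and rank (NaN for unranked)."""
    rows = []
    for rec in records:
        row = {
            "variant": rec.variant,
            "ei_sTyr": rec.ei_sTyr,
            "ei_pTyr": rec.ei_pTyr,
            "ei_difference": rec.ei_difference,
            "passes_abundance": rec.passes_abundance,
            "passes_trend": rec.passes_trend,
            "rank": rec.rank if rec.rank is not None else "",
        }
        for arm, trjs in (("sTyr", trajectories_styr), ("pTyr", trajectories_ptyr)):
            t = trjs.get(rec.variant)
            if t is not None:
                row[f"trend_{arm}"] = t.trend
                for r, p in zip(t.rounds, t.proportions):
                    row[f"{arm}_R{r}_percent"] = p
        rows.append(row)
    return pd.DataFrame(rows)
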