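"""Per-position residue proportions, round-over-round proportion changes,
and the enriched/depleted classification.

Proportions are carried in percent of designed (QC-passing) reads, so the
classification cutoff is expressed directly in percentage points.  A residue
type is enriched at a position when its proportion change from the reference
(naive) round exceeds the cutoff, depleted when it falls below the negative
cutoff — strict inequalities in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import AMINO_ACIDS
from .sequencing_io import RoundCounts

__all__ = [
    "FrequencyTable",
    "DeltaTable",
    "ClassificationMap",
    "position_frequencies",
    "proportion_change",
    "classify",
    "classification_concordance",
    "ConcordanceSummary",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 5.0  # percentage points


def _position_index(n: int) -> list[str]:
    return [f"P{i + 1}" for i in range(n)]


@dataclass
class FrequencyTable:
    """position x residue proportions (percent of designed reads)."""

    arm: str
    round: int
    matrix: pd.DataFrame  # index P1..Pn, columns 20 residues, percent

    def validate(self) -> None:
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValueError(f"frequency rows must sum to 100, got {sums.values}")


@dataclass
class DeltaTable:
    """position x residue proportion changes (percentage points)."""

    arm: str
    round_pair: tuple[int, int]  # (reference round, comparison round)
    matrix: pd.DataFrame

    def validate(self) -> None:
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 0.0, atol=1e-6):
            raise ValueError(f"delta rows must sum to 0, got {sums.values}")


@dataclass
class ClassificationMap:
    """position x residue in {+1 enriched, -1 depleted, 0 neutral}."""

    arm: str
    cutoff: float
    matrix: pd.DataFrame  # int8 values in {-1, 0, +1}

    def value(self, position: str, residue: str) -> int:
        return int(self.matrix.at[position, residue])

    def tokens(self, sign: int) -> list[str]:
        """Residue@position labels with the given sign, e.g. ["R@P1", ...]."""
        out = []
        for pos in self.matrix.index:
            for aa in self.matrix.columns:
                if int(self.matrix.at[pos, aa]) == sign:
                    out.append(f"{aa}@{pos}")
        return out


def position_frequencies(counts: RoundCounts, n_positions: int = 11) -> FrequencyTable:
    """Residue proportions per evolvable position from one round's tally.

    proportion(position, residue) = 100 x designed reads whose variant has
    that residue at that position / designed reads.
    """
    designed = counts.designed_reads
    if designed == 0:
        raise ValueError(
            f"no designed reads in {counts.arm} round {counts.round}; "
            "cannot compute proportions"
        )
    mat = np.zeros((n_positions, len(AMINO_ACIDS)))
    col = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    for variant, n in counts.counts.items():
        if len(variant) != n_positions:
            raise ValueError(
                f"variant {variant!r} length {len(variant)} != {n_positions}"
            )
        for i, aa in enumerate(variant):
            mat[i, col[aa]] += n
    matrix = pd.DataFrame(
        100.0 * mat / designed,
        index=_position_index(n_positions),
        columns=list(AMINO_ACIDS),
    )
    table = FrequencyTable(counts.arm, counts.round, matrix)
    table.validate()
    return table


def proportion_change(
    comparison: FrequencyTable, reference: FrequencyTable
) -> DeltaTable:
    """Elementwise proportion change (comparison - reference), in points."""
    if not comparison.matrix.index.equals(reference.matrix.index) or not (
        comparison.matrix.columns.equals(reference.matrix.columns)
    ):
        raise ValueError("frequency tables have mismatched positions/residues")
    delta = DeltaTable(
        arm=comparison.arm,
        round_pair=(reference.round, comparison.round),
        matrix=comparison.matrix - reference.matrix,
    )
    delta.validate()
    return delta


def classify(delta: DeltaTable, cutoff: float = DEFAULT_CUTOFF) -> ClassificationMap:
    """Enriched (+1) where change > cutoff, depleted (-1) where < -cutoff,
    neutral (0) otherwise; the inequalities are strict."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    values = np.where(
        delta.matrix.values > cutoff, 1, np.where(delta.matrix.values < -cutoff, -1, 0)
    ).astype(np.int8)
    return ClassificationMap(
        arm=delta.arm,
        cutoff=cutoff,
        matrix=pd.DataFrame(
            values, index=delta.matrix.index, columns=delta.matrix.columns
        ),
    )


@dataclass
class ConcordanceSummary:
    shared_enriched: list[str]
    shared_depleted: list[str]
    opposite: list[str]  # +1 in one map, -1 in the other
    only_a: list[str]  # non-neutral in a, neutral in b
    only_b: list[str]


def classification_concordance(
    a: ClassificationMap, b: ClassificationMap
) -> ConcordanceSummary:
    """Compare two arms' classifications cell by cell (the two-arm
    enriched/depleted agreement view)."""
    if not a.matrix.index.equals(b.matrix.index) or not a.matrix.columns.equals(
        b.matrix.columns
    ):
        raise ValueError("classification maps have mismatched dimensions")
    summary = ConcordanceSummary([], [], [], [], [])
    for pos in a.matrix.index:
        for aa in a.matrix.columns:
            va, vb = int(a.matrix.at[pos, aa]), int(b.matrix.at[pos, aa])
            token = f"{aa}@{pos}"
            if va == vb == 1:
                summary.shared_enriched.append(token)
            elif va == vb == -1:
                summary.shared_depleted.append(token)
            elif va * vb == -1:
                summary.opposite.append(token)
            elif va != 0 and vb == 0:
                summary.only_a.append(token)
            elif vb != 0 and va == 0:
                summary.only_b.append(token)
    return summary


def read_matrix(path):
    """Read back a matrix written by :func:`write_matrix`, reconstructing the
    table type from its metadata header."""
    import io as _io

    meta: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
            else:
                body.append(line)
    matrix = pd.read_csv(_io.StringIO("".join(body)), sep="\t", index_col=0)
    kind = meta.get("kind")
    if kind == "frequency":
        return FrequencyTable(meta["arm"], int(meta["round"]), matrix)
    if kind == "delta":
        return DeltaTable(
            meta["arm"],
            (int(meta["reference_round"]), int(meta["comparison_round"])),
            matrix,
        )
    if kind == "classification":
        return ClassificationMap(
            meta["arm"], float(meta["cutoff"]), matrix.astype(np.int8)
        )
    raise ValueError(f"{path}: unknown matrix kind {kind!r}")


def write_matrix(table, path, kind: str) -> None:
    """Write a frequency/delta/classification matrix as TSV with metadata
    header lines (arm, rounds, cutoff as applicable)."""
    with open(path, "w") as fh:
        fh.write(f"# kind={kind}\n# arm={table.arm}\n")
        if isinstance(table, FrequencyTable):
            fh.write(f"# round={table.round}\n")
        elif isinstance(table, DeltaTable):
            fh.write(
                f"# reference_round={table.round_pair[0]}\n"
                f"# comparison_round={table.round_pair[1]}\n"
            )
        elif isinstance(table, ClassificationMap):
            fh.write(f"# cutoff={table.cutoff}\n")
        table.matrix.to_csv(fh, sep="\t")
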