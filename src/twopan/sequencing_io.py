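"""Amplicon FASTQ ingestion: orient paired reads, extract and translate the
evolvable codons between constant anchors, and tally variant counts per
selection round.

The amplicon layout is fixed-length (no indels are tolerated: an indel would
corrupt the codon frame), so anchors are located by position with a small
per-anchor substitution tolerance rather than by alignment.  All coordinates
are 0-based, half-open.
"""

from __future__ import annotations

import functools
import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genetics import reverse_complement, CODON_TO_AA, STOP
from .library_design import LibraryDesign

__all__ = [
    "ReadRecord",
    "ExtractionResult",
    "RoundCounts",
    "TallyParams",
    "FastqFormatError",
    "read_fastq",
    "orient_and_merge",
    "extract_variant",
    "tally_round",
    "qc_report",
    "read_sample_sheet",
    "write_round_counts",
    "read_round_counts",
    "write_qc_report",
]

# extraction statuses, in reporting order
STATUSES = (
    "designed",
    "anchor_fail",
    "length_fail",
    "ambiguous_base",
    "stop_codon",
    "unexpected_constant",
    "quality_fail",
)


class FastqFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    qualities: Optional[str] = None
    mate: str = "single"  # {single, R1, R2}

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FastqFormatError(
                f"read {self.id}: sequence and quality lengths differ"
            )

    def mean_quality(self) -> Optional[float]:
        if not self.qualities:
            return None
        return float(np.mean([ord(c) - 33 for c in self.qualities]))


@dataclass(frozen=True)
class ExtractionResult:
    status: str
    variant: Optional[str] = None
    region_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if (self.status == "designed") != (self.variant is not None):
            raise ValueError("variant must be present iff status == designed")


@dataclass
class RoundCounts:
    """Per (arm, round) variant read counts plus QC tallies."""

    arm: str
    round: int
    counts: Counter = field(default_factory=Counter)
    qc: Counter = field(default_factory=Counter)
    total_reads: int = 0

    @property
    def designed_reads(self) -> int:
        return self.qc.get("designed", 0)

    def proportion_percent(self, variant: str) -> float:
        """Percent of designed reads carrying ``variant`` (0 if absent)."""
        designed = self.designed_reads
        if designed == 0:
            return 0.0
        return 100.0 * self.counts.get(variant, 0) / designed

    def validate(self) -> None:
        if sum(self.counts.values()) != self.qc.get("designed", 0):
            raise ValueError("sum(counts) != qc[designed]")
        if sum(self.qc.values()) != self.total_reads:
            raise ValueError("sum(qc) != total_reads")


def _open_text(path):
    """Open plain or gzipped text transparently (sniffs the gzip magic)."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path, mate: str = "single") -> Iterator[ReadRecord]:
    """Stream FASTQ records in file order; malformed 4-line blocks raise a
    :class:`FastqFormatError` naming the 0-based record index."""
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        n = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(f"{path}: record {n}: {exc}") from None
            yield ReadRecord(title.split()[0], seq.upper(), qual, mate)
            n += 1


def _mismatches(observed: str, expected: str, limit: int) -> int:
    """Substitution count with early exit past ``limit``; missing bases and
    Ns count as mismatches."""
    n = abs(len(observed) - len(expected))
    if n > limit:
        return n
    for x, y in zip(observed, expected):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


@functools.lru_cache(maxsize=8)
def _variable_mask(design: LibraryDesign) -> tuple[bool, ...]:
    mask = [False] * design.amplicon_length
    for start, end in design.variable_spans():
        for i in range(start, end):
            mask[i] = True
    return tuple(mask)


def orient_and_merge(
    r1: ReadRecord,
    r2: ReadRecord,
    design: LibraryDesign,
    orient_mismatch: int = 3,
) -> tuple[Optional[str], Optional[str]]:
    """Orient a mate pair against the design and merge by overlap consensus.

    Returns ``(fragment, None)`` on success or ``(None, status)`` on failure.
    Both strands of both mates are tried: the forward candidate must start
    with the forward flank and the (reverse-complemented) mate must end with
    the reverse flank, each within ``orient_mismatch`` substitutions.  Where
    both mates cover the same base they must agree inside a variable region
    (disagreement fails the fragment with ``ambiguous_base``); in constant
    segments the forward mate's base is kept and the per-anchor mismatch
    tolerance absorbs the error.
    """
    fwd, rev = design.forward_flank, design.reverse_flank
    s1, s2 = r1.sequence, r2.sequence
    candidates = (
        (s1, lambda: reverse_complement(s2)),
        (s2, lambda: reverse_complement(s1)),
        (reverse_complement(s1), lambda: s2),
        (reverse_complement(s2), lambda: s1),
    )
    f = m = None
    for cand_f, cand_m in candidates:
        if _mismatches(cand_f[: len(fwd)], fwd, orient_mismatch) <= orient_mismatch:
            cm = cand_m()
            if (
                _mismatches(cm[-len(rev) :], rev, orient_mismatch)
                <= orient_mismatch
            ):
                f, m = cand_f, cm
                break
    if f is None:
        return None, "anchor_fail"

    L = design.amplicon_length
    if len(f) == L and f == m:  # identical full-length mates: nothing to merge
        return f, None
    off = L - len(m)
    if len(f) > L or off < 0:
        return None, "length_fail"

    mask = _variable_mask(design)
    merged = [None] * L
    merged[: len(f)] = list(f)
    for j, ch in enumerate(m):
        i = off + j
        prev = merged[i]
        if prev is None:
            merged[i] = ch
        elif prev != ch:
            if mask[i]:
                return None, "ambiguous_base"
            # constant segment: keep the forward mate's base
    if any(b is None for b in merged):
        merged = [b if b is not None else "N" for b in merged]
    return "".join(merged), None


def extract_variant(
    fragment: str, design: LibraryDesign, max_anchor_mismatch: int = 1
) -> ExtractionResult:
    """Extract and translate the evolvable codons from an oriented fragment.

    The fragment must have the design's exact amplicon length (substitutions
    only; indels are rejected as ``length_fail``).  Flanking anchors off by
    more than ``max_anchor_mismatch`` give ``anchor_fail``; internal constant
    segments give ``unexpected_constant``.  Ns inside variable codons give
    ``ambiguous_base`` and stop codons ``stop_codon``.
    """
    L = design.amplicon_length
    offsets = tuple(start for start, _ in design.variable_spans())
    if len(fragment) != L:
        return ExtractionResult("length_fail")
    for kind, start, end, payload in design.segment_layout():
        if kind != "anchor":
            continue
        mism = _mismatches(fragment[start:end], payload, max_anchor_mismatch)
        if mism > max_anchor_mismatch:
            status = (
                "anchor_fail" if start == 0 or end == L else "unexpected_constant"
            )
            return ExtractionResult(status, region_offsets=offsets)
    residues = []
    for (start, end), region in zip(design.variable_spans(), design.regions):
        run = fragment[start:end]
        for k in range(0, len(run), 3):
            codon = run[k : k + 3]
            aa = CODON_TO_AA.get(codon)
            if aa is None:  # non-ACGT base inside a variable codon
                return ExtractionResult("ambiguous_base", region_offsets=offsets)
            if aa == STOP:
                return ExtractionResult("stop_codon", region_offsets=offsets)
            residues.append(aa)
    return ExtractionResult("designed", "".join(residues), offsets)


@dataclass(frozen=True)
class TallyParams:
    max_anchor_mismatch: int = 1
    orient_mismatch: int = 3
    min_mean_quality: Optional[float] = None


def tally_round(
    files: Iterable,
    arm: str,
    round_index: int,
    design: LibraryDesign,
    params: TallyParams = TallyParams(),
) -> RoundCounts:
    """Tally variant counts for one (arm, round) from FASTQ file(s).

    ``files`` is a list of single-end paths or of ``(r1, r2)`` path pairs.
    Each fragment contributes exactly one QC status; designed fragments also
    contribute one variant count.
    """
    rc = RoundCounts(arm=arm, round=round_index)
    for entry in files:
        paired = isinstance(entry, (tuple, list))
        try:
            if paired:
                r1_path, r2_path = entry
                stream = zip(
                    read_fastq(r1_path, "R1"), read_fastq(r2_path, "R2"),
                    strict=True,
                )
            else:
                stream = ((r, None) for r in read_fastq(entry, "single"))
            for r1, r2 in stream:
                rc.total_reads += 1
                if params.min_mean_quality is not None:
                    quals = [
                        q
                        for q in (r1.mean_quality(), r2.mean_quality() if r2 else None)
                        if q is not None
                    ]
                    if quals and min(quals) < params.min_mean_quality:
                        rc.qc["quality_fail"] += 1
                        continue
                if r2 is not None:
                    fragment, fail = orient_and_merge(
                        r1, r2, design, params.orient_mismatch
                    )
                else:
                    fragment, fail = _orient_single(
                        r1, design, params.orient_mismatch
                    )
                if fail is not None:
                    rc.qc[fail] += 1
                    continue
                result = extract_variant(
                    fragment, design, params.max_anchor_mismatch
                )
                rc.qc[result.status] += 1
                if result.status == "designed":
                    rc.counts[result.variant] += 1
        except (OSError, ValueError) as exc:
            raise type(exc)(f"while tallying {entry} ({arm} R{round_index}): {exc}")
    rc.validate()
    return rc


def _orient_single(
    read: ReadRecord, design: LibraryDesign, orient_mismatch: int
) -> tuple[Optional[str], Optional[str]]:
    fwd = design.forward_flank
    for seq in (read.sequence, reverse_complement(read.sequence)):
        if _mismatches(seq[: len(fwd)], fwd, orient_mismatch) <= orient_mismatch:
            return seq, None
    return None, "anchor_fail"


def qc_report(rounds: list[RoundCounts]) -> pd.DataFrame:
    """Per-(arm, round) QC summary: totals, designed fraction (NaN when the
    round has no reads, never 0), status breakdown, unique variant count."""
    if not rounds:
        raise ValueError("qc_report needs at least one round")
    rows = []
    for rc in sorted(rounds, key=lambda r: (r.arm, r.round)):
        row = {
            "arm": rc.arm,
            "round": rc.round,
            "total_reads": rc.total_reads,
            "designed_fraction": (
                rc.designed_reads / rc.total_reads if rc.total_reads else np.nan
            ),
            "unique_variants": len(rc.counts),
        }
        for status in STATUSES:
            row[status] = rc.qc.get(status, 0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text interfaces
# ---------------------------------------------------------------------------


def read_sample_sheet(path) -> list[dict]:
    """Read a tab-separated sample sheet mapping files to (arm, round).

    Columns: ``arm``, ``round``, ``r1`` and optionally ``r2``.  File paths
    are resolved relative to the sheet's directory.
    """
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("arm", "round", "r1"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample sheet missing column {col!r}")
    rows = []
    for _, rec in df.iterrows():
        r2 = rec.get("r2")
        rows.append(
            {
                "arm": rec["arm"],
                "round": int(rec["round"]),
                "r1": str(base / rec["r1"]),
                "r2": str(base / r2) if isinstance(r2, str) and r2 else None,
            }
        )
    return rows


def write_round_counts(rc: RoundCounts, path) -> None:
    """Write a variant count table (TSV) with arm/round/QC metadata headers."""
    with open(path, "w") as fh:
        fh.write(f"# arm={rc.arm}\n# round={rc.round}\n")
        fh.write(f"# total_reads={rc.total_reads}\n")
        for status in STATUSES:
            if rc.qc.get(status):
                fh.write(f"# qc_{status}={rc.qc[status]}\n")
        fh.write("variant\tcount\tproportion_percent\n")
        designed = rc.designed_reads
        for variant, count in sorted(
            rc.counts.items(), key=lambda kv: (-kv[1], kv[0])
        ):
            fh.write(f"{variant}\t{count}\t{100.0 * count / designed:.6f}\n")


def read_round_counts(path) -> RoundCounts:
    meta: dict[str, str] = {}
    counts: Counter = Counter()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
            elif line and not line.startswith("variant\t"):
                variant, count, _ = line.split("\t")
                counts[variant] = int(count)
    qc = Counter(
        {k[3:]: int(v) for k, v in meta.items() if k.startswith("qc_")}
    )
    rc = RoundCounts(
        arm=meta["arm"],
        round=int(meta["round"]),
        counts=counts,
        qc=qc,
        total_reads=int(meta["total_reads"]),
    )
    rc.validate()
    return rc


def write_qc_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
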