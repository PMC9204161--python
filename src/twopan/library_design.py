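"""Soft-randomization (doped oligonucleotide) library design.

A soft-randomized library is built from a template protein by synthesizing
each evolvable codon from "doped" nucleotide mixtures: at every codon base
the template nucleotide is kept with fraction ``p`` and each of the three
other nucleotides appears with fraction ``(1 - p) / 3``.  Choosing ``p``
tunes the per-position mutation rate.  This module calibrates ``p`` for a
requested mutation rate (at the codon or amino-acid level), predicts the
resulting residue distribution at each position by genetic-code
enumeration, and emits/parses degenerate primer specifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .genetics import (
    ALL_CODONS,
    AMINO_ACIDS,
    BASES,
    STOP,
    CODON_TO_AA,
    codons_for,
    is_sense_codon,
    translate_codon,
)

__all__ = [
    "NucleotideMixture",
    "DopedCodon",
    "LibraryDesign",
    "solve_base_retention",
    "expected_residue_distribution",
    "expected_library_profile",
    "emit_degenerate_primers",
    "parse_degenerate_primers",
    "default_design",
    "load_design",
    "save_design",
    "DesignError",
]

#: Default evolvable-pocket template: the 11-residue wild pocket sequence
#: of the sTyr-binding SH2 template clone used as mutagenesis start point.
DEFAULT_TEMPLATE_RESIDUES = "RQLARVYAHYL"
#: Arbitrary sense codons for the default template residues (downstream
#: analysis depends only on translated 11-mers; real codons are config-supplied).
DEFAULT_TEMPLATE_CODONS = (
    "CGT", "CAA", "CTG", "GCT", "CGT", "GTT", "TAT", "GCT", "CAT", "TAT", "CTG",
)
#: Amplicon constant segments flanking/separating the three doped runs.
#: Forward flank is the amplicon-seq forward primer; the 9-mer separates the
#: first two runs; the long middle segment spans the template between the
#: two mutagenic oligos; the reverse flank is the reverse-complemented
#: amplicon-seq reverse primer.
DEFAULT_ANCHORS = (
    "GAGGTACCTTTCTTATC",
    "AAAGGTGCG",
    "CTTTCTATCCGTGATTGGAAAGGAGACCATGTCAAA",
    "ATTCGCAAACTTGACAA",
)
DEFAULT_REGIONS = ((0, 1, 2, 3, 4, 5), (6, 7), (8, 9, 10))
DEFAULT_PRIMER_GROUPS = ((0, 1), (2,))
DEFAULT_MUTATION_RATE = 0.5
DEFAULT_RATE_LEVEL = "amino_acid"


class DesignError(ValueError):
    """Invalid library-design value or configuration."""


@dataclass(frozen=True)
class NucleotideMixture:
    """Fractions of A/C/G/T at one synthesized base position."""

    proportions: tuple[float, float, float, float]  # order A, C, G, T

    def __post_init__(self) -> None:
        if len(self.proportions) != 4:
            raise DesignError("mixture needs exactly 4 fractions (A, C, G, T)")
        if any(f < 0 for f in self.proportions):
            raise DesignError(f"negative mixture fraction in {self.proportions}")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise DesignError(
                f"mixture fractions sum to {sum(self.proportions)!r}, not 1"
            )

    def fraction(self, base: str) -> float:
        return self.proportions[BASES.index(base)]

    @classmethod
    def doped(cls, template_base: str, retention: float) -> "NucleotideMixture":
        """Template base kept with fraction ``retention``; others equal."""
        if template_base not in BASES:
            raise DesignError(f"invalid template base {template_base!r}")
        off = (1.0 - retention) / 3.0
        return cls(tuple(retention if b == template_base else off for b in BASES))

    @classmethod
    def point(cls, base: str) -> "NucleotideMixture":
        return cls.doped(base, 1.0)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(BASES, self.proportions))


def _codon_mutation_rate(template_codon: str, p: float, level: str) -> float:
    """Probability that a codon sampled with retention ``p`` differs from the
    template at the requested level (stops count as mutations at residue level)."""
    if level == "codon":
        return 1.0 - p**3
    template_aa = translate_codon(template_codon)
    off = (1.0 - p) / 3.0
    retained = 0.0
    for codon in codons_for(template_aa):
        w = 1.0
        for tb, cb in zip(template_codon, codon):
            w *= p if cb == tb else off
        retained += w
    return 1.0 - retained


def solve_base_retention(
    target_rate: float, template_codon: str, level: str = "amino_acid"
) -> float:
    """Solve the per-base template retention fraction ``p`` so a codon sampled
    from the doped mixtures mutates at ``target_rate``.

    ``level="codon"``: mutation = any nucleotide change, closed form
    ``p = (1 - rate)^(1/3)``.  ``level="amino_acid"``: mutation = translated
    residue differs from the template residue (stop codons count as
    mutations); solved by bisection against full genetic-code enumeration.
    Synonymous codons raise residue retention, so the amino-acid-level ``p``
    is at most the codon-level one.
    """
    template_codon = template_codon.upper()
    if level not in ("codon", "amino_acid"):
        raise DesignError(f"unknown rate level {level!r}")
    if not (0.0 <= target_rate < 1.0):
        raise DesignError(f"target_rate {target_rate} outside [0, 1)")
    if len(template_codon) != 3 or any(b not in BASES for b in template_codon):
        raise DesignError(f"invalid template codon {template_codon!r}")
    if not is_sense_codon(template_codon):
        raise DesignError(f"template codon {template_codon} is a stop codon")
    if target_rate == 0.0:
        return 1.0
    max_rate = _codon_mutation_rate(template_codon, 0.25, level)
    if target_rate > max_rate + 1e-12:
        raise DesignError(
            f"target_rate {target_rate} unachievable for {template_codon} at "
            f"{level} level; achievable range is [0, {max_rate:.6f}]"
        )
    if level == "codon":
        return (1.0 - target_rate) ** (1.0 / 3.0)
    return brentq(
        lambda p: _codon_mutation_rate(template_codon, p, level) - target_rate,
        0.25,
        1.0,
        xtol=1e-12,
    )


@dataclass(frozen=True)
class DopedCodon:
    """A template codon with one nucleotide mixture per codon base."""

    template_codon: str
    mixtures: tuple[NucleotideMixture, NucleotideMixture, NucleotideMixture]

    def __post_init__(self) -> None:
        if len(self.template_codon) != 3 or any(
            b not in BASES for b in self.template_codon
        ):
            raise DesignError(f"invalid template codon {self.template_codon!r}")
        if not is_sense_codon(self.template_codon):
            raise DesignError(
                f"template codon {self.template_codon} translates to a stop"
            )
        if len(self.mixtures) != 3:
            raise DesignError("a doped codon needs exactly 3 mixtures")

    @property
    def template_residue(self) -> str:
        return translate_codon(self.template_codon)

    @classmethod
    def from_mutation_rate(
        cls, template_codon: str, rate: float, level: str = "amino_acid"
    ) -> "DopedCodon":
        p = solve_base_retention(rate, template_codon, level)
        template_codon = template_codon.upper()
        return cls(
            template_codon,
            tuple(NucleotideMixture.doped(b, p) for b in template_codon),
        )

    def codon_probability(self, codon: str) -> float:
        w = 1.0
        for mix, base in zip(self.mixtures, codon):
            w *= mix.fraction(base)
        return w


def expected_residue_distribution(doped: DopedCodon) -> dict[str, float]:
    """Distribution over the 20 residues plus stop ("*") at one position,
    from enumerating all 64 codons weighted by the mixture fractions."""
    dist = {aa: 0.0 for aa in AMINO_ACIDS}
    dist[STOP] = 0.0
    for codon in ALL_CODONS:
        dist[CODON_TO_AA[codon]] += doped.codon_probability(codon)
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"distribution sums to {total}")
    return dist


@dataclass(frozen=True)
class LibraryDesign:
    """Layout of the soft-randomized amplicon.

    ``positions`` are the evolvable doped codons P1..Pn in amplicon order.
    ``regions`` partitions them into consecutive runs; ``anchors`` holds the
    n_regions+1 constant DNA segments around/between the runs, so the
    amplicon reads ``anchors[0] + run1 + anchors[1] + run2 + ...``.
    ``primer_groups`` records which consecutive regions were synthesized on
    one mutagenic oligo (for primer emission only).
    """

    positions: tuple[DopedCodon, ...]
    regions: tuple[tuple[int, ...], ...] = DEFAULT_REGIONS
    anchors: tuple[str, ...] = DEFAULT_ANCHORS
    primer_groups: tuple[tuple[int, ...], ...] = DEFAULT_PRIMER_GROUPS

    def __post_init__(self) -> None:
        flat = [i for region in self.regions for i in region]
        if flat != list(range(len(self.positions))):
            raise DesignError(
                "regions must partition positions in order; got runs "
                f"{self.regions} for {len(self.positions)} positions"
            )
        for region in self.regions:
            if list(region) != list(range(region[0], region[-1] + 1)):
                raise DesignError(f"region {region} is not a consecutive run")
        if len(self.anchors) != len(self.regions) + 1:
            raise DesignError(
                f"need {len(self.regions) + 1} anchors for "
                f"{len(self.regions)} regions, got {len(self.anchors)}"
            )
        for a in self.anchors:
            if not a or any(b not in BASES for b in a):
                raise DesignError(f"invalid or empty anchor {a!r}")
        gflat = [r for g in self.primer_groups for r in g]
        if sorted(gflat) != list(range(len(self.regions))):
            raise DesignError(
                f"primer_groups {self.primer_groups} must partition regions"
            )

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def position_names(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1}" for i in range(self.n_positions))

    @property
    def template_residues(self) -> str:
        return "".join(p.template_residue for p in self.positions)

    @property
    def template_codons(self) -> tuple[str, ...]:
        return tuple(p.template_codon for p in self.positions)

    @property
    def forward_flank(self) -> str:
        return self.anchors[0]

    @property
    def reverse_flank(self) -> str:
        return self.anchors[-1]

    @property
    def amplicon_length(self) -> int:
        return sum(len(a) for a in self.anchors) + 3 * self.n_positions

    def segment_layout(self) -> list[tuple[str, int, int, object]]:
        """Amplicon segments as (kind, start, end, payload): kind "anchor"
        (payload: anchor DNA) or "region" (payload: region index).
        Coordinates are 0-based, half-open."""
        out: list[tuple[str, int, int, object]] = []
        pos = 0
        for i, region in enumerate(self.regions):
            a = self.anchors[i]
            out.append(("anchor", pos, pos + len(a), a))
            pos += len(a)
            rlen = 3 * len(region)
            out.append(("region", pos, pos + rlen, i))
            pos += rlen
        a = self.anchors[-1]
        out.append(("anchor", pos, pos + len(a), a))
        return out

    def variable_spans(self) -> list[tuple[int, int]]:
        """(start, end) of each doped region in amplicon coordinates."""
        return [
            (start, end)
            for kind, start, end, _ in self.segment_layout()
            if kind == "region"
        ]

    def build_amplicon(self, codons: "list[str] | tuple[str, ...] | str") -> str:
        """Assemble the amplicon DNA for one clone's variable codons."""
        if isinstance(codons, str):
            codons = [codons[i : i + 3] for i in range(0, len(codons), 3)]
        if len(codons) != self.n_positions:
            raise DesignError(
                f"expected {self.n_positions} codons, got {len(codons)}"
            )
        parts = []
        for i, region in enumerate(self.regions):
            parts.append(self.anchors[i])
            parts.extend(codons[j] for j in region)
        parts.append(self.anchors[-1])
        return "".join(parts)


def expected_library_profile(design: LibraryDesign) -> pd.DataFrame:
    """Expected displayed-library residue proportions per position.

    Stop-codon mass is removed and the remaining residue probabilities are
    renormalized, because clones with a stop in the variable region do not
    display and are never observed in panning reads.  Rows are positions
    P1..Pn, columns the 20 residues; each row sums to 1.
    """
    rows = []
    for doped in design.positions:
        dist = expected_residue_distribution(doped)
        stop_mass = dist.pop(STOP)
        keep = 1.0 - stop_mass
        rows.append({aa: v / keep for aa, v in dist.items()})
    return pd.DataFrame(rows, index=list(design.position_names))[
        list(AMINO_ACIDS)
    ]


# ---------------------------------------------------------------------------
# degenerate primer specifications
# ---------------------------------------------------------------------------


def _mixture_key(mix: NucleotideMixture) -> tuple[float, ...]:
    return tuple(round(f, 12) for f in mix.proportions)


def emit_degenerate_primers(design: LibraryDesign) -> str:
    """Render the design as plain-text primer specifications.

    One primer per primer group: 5' constant anchor, the doped bases written
    as mixture-class labels (N1, N2, ...), internal constants, 3' constant
    anchor.  A mixture table gives the exact A/C/G/T fractions per label,
    since IUPAC degeneracy codes cannot encode unequal fractions.  The text
    round-trips through :func:`parse_degenerate_primers`.
    """
    labels: dict[tuple[float, ...], str] = {}
    mix_by_label: dict[str, NucleotideMixture] = {}

    def label(mix: NucleotideMixture) -> str:
        key = _mixture_key(mix)
        if key not in labels:
            name = f"N{len(labels) + 1}"
            labels[key] = name
            mix_by_label[name] = mix
        return labels[key]

    primer_lines: list[str] = []
    for gi, group in enumerate(design.primer_groups):
        primer_lines.append(f"[primer {gi + 1}]")
        primer_lines.append(f"anchor\t{design.anchors[group[0]]}")
        for ri in group:
            doped_labels = [
                label(mix)
                for pi in design.regions[ri]
                for mix in design.positions[pi].mixtures
            ]
            primer_lines.append("doped\t" + " ".join(doped_labels))
            primer_lines.append(f"anchor\t{design.anchors[ri + 1]}")

    header = ["[mixtures]"]
    for name, mix in mix_by_label.items():
        fracs = "\t".join(
            f"{b}={f:.17g}" for b, f in zip(BASES, mix.proportions)
        )
        header.append(f"{name}\t{fracs}")
    return "\n".join(header + primer_lines) + "\n"


def parse_degenerate_primers(text: str) -> LibraryDesign:
    """Parse :func:`emit_degenerate_primers` output back into a design.

    The template codon at each position is recovered as the modal base of
    each mixture (soft randomization always favors the template base).
    Consecutive primers whose abutting anchors are identical are merged into
    one amplicon layout.
    """
    mixtures: dict[str, NucleotideMixture] = {}
    primers: list[list[tuple[str, object]]] = []
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line == "[mixtures]":
            section = "mixtures"
            continue
        if line.startswith("[primer"):
            section = "primer"
            primers.append([])
            continue
        fields = line.split("\t")
        if section == "mixtures":
            name = fields[0]
            fracs = {"A": None, "C": None, "G": None, "T": None}
            for item in fields[1:]:
                base, _, value = item.partition("=")
                if base not in BASES:
                    raise DesignError(f"line {lineno}: unknown base {base!r}")
                fracs[base] = float(value)
            if any(v is None for v in fracs.values()):
                raise DesignError(f"line {lineno}: mixture {name} incomplete")
            mixtures[name] = NucleotideMixture(tuple(fracs[b] for b in BASES))
        elif section == "primer":
            kind = fields[0]
            if kind == "anchor":
                primers[-1].append(("anchor", fields[1]))
            elif kind == "doped":
                primers[-1].append(("doped", fields[1].split()))
            else:
                raise DesignError(f"line {lineno}: unknown primer row {kind!r}")
        else:
            raise DesignError(f"line {lineno}: content before any section header")

    if not primers:
        raise DesignError("no primer sections found")

    anchors: list[str] = []
    positions: list[DopedCodon] = []
    regions: list[tuple[int, ...]] = []
    primer_groups: list[tuple[int, ...]] = []
    positions_pending = False
    for primer in primers:
        group: list[int] = []
        for kind, payload in primer:
            if kind == "anchor":
                if anchors and not positions_pending and anchors[-1] == payload:
                    continue  # shared junction anchor between primers
                anchors.append(payload)
                positions_pending = False
            else:
                labels = payload
                if len(labels) % 3:
                    raise DesignError(
                        f"doped run of {len(labels)} bases is not whole codons"
                    )
                start = len(positions)
                for i in range(0, len(labels), 3):
                    mixes = tuple(mixtures[l] for l in labels[i : i + 3])
                    template = "".join(
                        BASES[int(np.argmax(m.proportions))] for m in mixes
                    )
                    positions.append(DopedCodon(template, mixes))
                regions.append(tuple(range(start, len(positions))))
                group.append(len(regions) - 1)
                positions_pending = True
        primer_groups.append(tuple(group))
    return LibraryDesign(
        tuple(positions), tuple(regions), tuple(anchors), tuple(primer_groups)
    )


# ---------------------------------------------------------------------------
# design configuration files
# ---------------------------------------------------------------------------


def default_design(
    rate: float = DEFAULT_MUTATION_RATE, level: str = DEFAULT_RATE_LEVEL
) -> LibraryDesign:
    """The 11-position pocket design with calibrated doped mixtures."""
    return LibraryDesign(
        tuple(
            DopedCodon.from_mutation_rate(c, rate, level)
            for c in DEFAULT_TEMPLATE_CODONS
        )
    )


def _require(cfg: dict, key: str, typ: type) -> object:
    if key not in cfg:
        raise DesignError(f"design config: missing required key {key!r}")
    val = cfg[key]
    if not isinstance(val, typ):
        raise DesignError(
            f"design config key {key!r}: expected {typ.__name__}, "
            f"got {type(val).__name__}"
        )
    return val


def design_from_dict(cfg: dict) -> LibraryDesign:
    codons = _require(cfg, "template_codons", list)
    rate = float(cfg.get("mutation_rate", DEFAULT_MUTATION_RATE))
    level = cfg.get("rate_level", DEFAULT_RATE_LEVEL)
    positions = tuple(
        DopedCodon.from_mutation_rate(str(c).upper(), rate, level) for c in codons
    )
    if "template_residues" in cfg:
        want = str(cfg["template_residues"])
        got = "".join(p.template_residue for p in positions)
        if got != want:
            raise DesignError(
                f"design config: template_codons translate to {got}, but "
                f"template_residues says {want}"
            )
    regions_cfg = _require(cfg, "regions", list)
    regions = []
    for i, r in enumerate(regions_cfg):
        if not (isinstance(r, list) and len(r) == 2):
            raise DesignError(
                f"design config regions[{i}]: expected [first, last] "
                f"1-based position pair"
            )
        regions.append(tuple(range(int(r[0]) - 1, int(r[1]))))
    anchors = tuple(str(a).upper() for a in _require(cfg, "anchors", list))
    groups_cfg = cfg.get("primer_groups")
    if groups_cfg is None:
        groups = tuple((i,) for i in range(len(regions)))
    else:
        groups = tuple(tuple(int(r) - 1 for r in g) for g in groups_cfg)
    return LibraryDesign(positions, tuple(regions), anchors, groups)


def design_to_dict(design: LibraryDesign, rate=None, level=None) -> dict:
    d = {
        "template_codons": list(design.template_codons),
        "template_residues": design.template_residues,
        "regions": [[r[0] + 1, r[-1] + 1] for r in design.regions],
        "anchors": list(design.anchors),
        "primer_groups": [[r + 1 for r in g] for g in design.primer_groups],
    }
    if rate is not None:
        d["mutation_rate"] = rate
    if level is not None:
        d["rate_level"] = level
    return d


def load_design(path) -> LibraryDesign:
    """Load a design config (YAML key/value + tables) with strict validation."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DesignError(f"{path}: design config must be a mapping")
    try:
        return design_from_dict(cfg)
    except DesignError as exc:
        raise DesignError(f"{path}: {exc}") from None


def save_design(design: LibraryDesign, path, rate=None, level=None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design, rate, level), fh, sort_keys=False)
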