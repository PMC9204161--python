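"""Ground-truthed synthetic selection experiments.

Generates everything the analysis consumes: a soft-randomized naive library
sampled clone by clone from the doped mixtures, multi-round two-arm
selection with planted target-specific / dual-binding / background-sticky
variants, and paired-end FASTQ emission with uniform substitution error.

The selection model is intentionally minimal: each round captures a
multinomial sample of phage with probability proportional to clone abundance
times (arm affinity weight + background weight), then amplifies each
captured clone by an independent log-normal factor and rescales the pool —
the simplest update that produces round-over-round exponential enrichment.
Negative selection against the streptavidin background is represented only
through the background weight term.  Clones carry explicit codons so
synonymous diversity and stop-codon loss are representable.

All randomness flows from a single scenario seed; outputs are reproducible
byte for byte.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .genetics import ALL_CODONS, CODON_TO_AA, STOP, codons_for, reverse_complement
from .library_design import LibraryDesign, default_design
from .sequencing_io import RoundCounts

__all__ = [
    "VariantFitness",
    "SimulationTruth",
    "PlantSpec",
    "ScenarioConfig",
    "ScenarioResult",
    "sample_naive_library",
    "plant_variants",
    "simulate_round",
    "sample_round_counts",
    "emit_fastq",
    "run_scenario",
    "DEFAULT_PLANT",
]

READ_LENGTH = 150
ARMS = ("sTyr", "pTyr")

# uint8 base codes 0..3 = A,C,G,T; 64-entry codon -> residue code lookup
_AA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODON_AA = np.array(
    [255 if CODON_TO_AA[c] == STOP else ord(CODON_TO_AA[c]) for c in ALL_CODONS],
    dtype=np.uint8,
)
_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class VariantFitness:
    """Per-variant capture weights: arm-specific affinities plus a
    target-independent background (plastic/streptavidin stickiness) term."""

    variant: str
    weight_sTyr: float
    weight_pTyr: float
    weight_background: float

    def __post_init__(self) -> None:
        if min(self.weight_sTyr, self.weight_pTyr, self.weight_background) <= 0:
            raise ValueError(f"weights must be positive: {self}")

    def arm_weight(self, arm: str) -> float:
        return self.weight_sTyr if arm == "sTyr" else self.weight_pTyr


@dataclass(frozen=True)
class PlantSpec:
    """One variant planted into the naive library at a known abundance."""

    variant: str
    kind: str  # {specific, dual, sticky}
    naive_fraction: float
    weight_sTyr: float
    weight_pTyr: float
    weight_background: float


@dataclass
class SimulationTruth:
    fitness: dict  # variant -> VariantFitness
    planted_specific: set
    planted_dual: set
    planted_sticky: set
    seed: int
    specificity_ratio: float = 10.0

    def __post_init__(self) -> None:
        sets = (self.planted_specific, self.planted_dual, self.planted_sticky)
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("planted variant sets must be disjoint")

    def is_specific(self, variant: str) -> bool:
        f = self.fitness[variant]
        return f.weight_sTyr / f.weight_pTyr >= self.specificity_ratio


# Default planted variants: three sTyr-specific clones sharing a pocket
# signature (C@P2 S@P3 E@P4 G@P5 ... V@P8), three dual binders that rise in
# both arms, and one background-sticky clone marked by C@P10.
DEFAULT_PLANT = (
    PlantSpec("RCSEGLYVHYL", "specific", 0.001, 30.0, 1.0, 0.2),
    PlantSpec("RCSEGVYVHYL", "specific", 0.001, 30.0, 1.0, 0.2),
    PlantSpec("KCSEGLYVHYL", "specific", 0.001, 30.0, 1.0, 0.2),
    PlantSpec("RCSERVHVHYL", "dual", 0.001, 20.0, 20.0, 0.2),
    PlantSpec("RCSARVHVHYL", "dual", 0.001, 20.0, 20.0, 0.2),
    PlantSpec("RQSARVFVHYL", "dual", 0.001, 20.0, 20.0, 0.2),
    PlantSpec("RLLARVYAHCL", "sticky", 0.005, 1.0, 1.0, 8.0),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated two-arm selection.

    Scale emulates the real experiment (1e9-clone library, 1.6M reads) at
    desk size: 1e4 naive clones, 4 rounds per arm, 5e4 reads per round.  The
    base error rate 7.5e-4 puts the designed-read fraction near 0.95, the
    QC pass rate observed in the study's sequencing.
    """

    n_clones: int = 10_000
    rounds: int = 4
    depth: int = 50_000
    error_rate: float = 7.5e-4
    capture_size: int = 10_000
    population_size: float = 10_000.0
    amp_sigma: float = 0.2
    baseline_sigma: float = 0.3
    background_weight: float = 0.2
    specificity_ratio: float = 10.0
    mutation_rate: float = 0.5
    rate_level: str = "amino_acid"
    seed: int = 0
    plant: tuple = DEFAULT_PLANT
    background_scale: tuple = ()  # optional per-round background multiplier


def sample_naive_library(
    design: LibraryDesign, n_clones: int, seed: int
) -> Counter:
    """Sample a naive population: per-clone codons drawn from the doped
    mixtures; clones carrying any stop codon are discarded (the population
    shrinks, mirroring non-displaying clones).  Returns codon-string counts."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    n_pos = design.n_positions
    codes = np.empty((n_clones, 3 * n_pos), dtype=np.uint8)
    for pos, doped in enumerate(design.positions):
        for k, mix in enumerate(doped.mixtures):
            codes[:, 3 * pos + k] = rng.choice(
                4, size=n_clones, p=np.asarray(mix.proportions)
            )
    codon_idx = (
        codes[:, 0::3].astype(np.int32) * 16
        + codes[:, 1::3].astype(np.int32) * 4
        + codes[:, 2::3]
    )
    aa = _CODON_AA[codon_idx]
    keep = ~(aa == 255).any(axis=1)
    ascii_rows = _AA_BYTES[codes[keep]]
    population: Counter = Counter()
    for row in ascii_rows:
        population[row.tobytes().decode()] += 1
    return population


def variant_of(codon_string: str) -> str:
    return "".join(
        CODON_TO_AA[codon_string[i : i + 3]] for i in range(0, len(codon_string), 3)
    )


def codons_for_variant(variant: str, design: LibraryDesign) -> str:
    """A concrete codon string for a residue 11-mer: the template codon where
    the residue matches the template, else the lexicographically first codon."""
    out = []
    for aa, template in zip(variant, design.template_codons):
        if CODON_TO_AA[template] == aa:
            out.append(template)
        else:
            out.append(codons_for(aa)[0])
    return "".join(out)


def plant_variants(
    population: Counter,
    plant: tuple,
    design: LibraryDesign,
    config: ScenarioConfig,
) -> tuple[Counter, SimulationTruth]:
    """Insert planted variants at configured naive abundances and assign
    fitness weights: planted clones get their spec's weights; every other
    variant draws one baseline affinity (shared by both arms) from a
    log-normal with mean 1 and the configured background weight."""
    population = Counter(population)
    pop_total = sum(population.values())
    sets: dict[str, set] = {"specific": set(), "dual": set(), "sticky": set()}
    fitness: dict[str, VariantFitness] = {}
    for spec in plant:
        if not 0 < spec.naive_fraction < 1:
            raise ValueError(
                f"planted fraction {spec.naive_fraction} for {spec.variant} "
                "must be in (0, 1)"
            )
        count = max(1, round(spec.naive_fraction * pop_total))
        population[codons_for_variant(spec.variant, design)] += count
        sets[spec.kind].add(spec.variant)
        fitness[spec.variant] = VariantFitness(
            spec.variant, spec.weight_sTyr, spec.weight_pTyr, spec.weight_background
        )
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2**20)))
    variants = sorted({variant_of(k) for k in population})
    sigma = config.baseline_sigma
    for v in variants:
        if v in fitness:
            continue
        w = (
            float(rng.lognormal(-0.5 * sigma**2, sigma))
            if sigma > 0
            else 1.0
        )
        fitness[v] = VariantFitness(v, w, w, config.background_weight)
    truth = SimulationTruth(
        fitness=fitness,
        planted_specific=sets["specific"],
        planted_dual=sets["dual"],
        planted_sticky=sets["sticky"],
        seed=config.seed,
        specificity_ratio=config.specificity_ratio,
    )
    return population, truth


def simulate_round(
    population: dict,
    arm: str,
    truth: SimulationTruth,
    config: ScenarioConfig,
    seed: int,
    background_scale: float = 1.0,
) -> dict:
    """One panning round: multinomial capture with probability proportional
    to abundance x (arm weight + scaled background weight), then per-clone
    log-normal amplification rescaled to the configured population size."""
    if config.capture_size <= 0:
        raise ValueError("capture_size must be positive")
    if not population:
        raise ValueError("population is empty")
    rng = np.random.default_rng(seed)
    keys = sorted(population)
    counts = np.array([population[k] for k in keys], dtype=float)
    weights = np.array(
        [
            truth.fitness[variant_of(k)].arm_weight(arm)
            + background_scale * truth.fitness[variant_of(k)].weight_background
            for k in keys
        ]
    )
    probs = counts * weights
    probs /= probs.sum()
    captured = rng.multinomial(config.capture_size, probs)
    keep = captured > 0
    amp = rng.lognormal(
        -0.5 * config.amp_sigma**2, config.amp_sigma, size=int(keep.sum())
    )
    new = captured[keep] * amp
    new *= config.population_size / new.sum()
    return dict(zip((k for k, m in zip(keys, keep) if m), new.tolist()))


def sample_round_counts(
    population: dict,
    arm: str,
    round_index: int,
    depth: int,
    seed: int,
) -> RoundCounts:
    """Sequencing-free observation of a population: multinomial read sample
    at the given depth, aggregated to residue variants (every read passes
    QC).  Used for analyses where base-call errors are irrelevant."""
    rng = np.random.default_rng(seed)
    keys = sorted(population)
    probs = np.array([population[k] for k in keys], dtype=float)
    probs /= probs.sum()
    reads = rng.multinomial(depth, probs)
    counts: Counter = Counter()
    for k, n in zip(keys, reads):
        if n:
            counts[variant_of(k)] += int(n)
    return RoundCounts(
        arm=arm,
        round=round_index,
        counts=counts,
        qc=Counter({"designed": depth}),
        total_reads=depth,
    )


def _write_gzip_text(path, text: str) -> None:
    # mtime=0 keeps same-seed output byte-identical across runs
    with open(path, "wb") as raw:
        raw.write(gzip.compress(text.encode("ascii"), mtime=0))


def emit_fastq(
    population: dict,
    design: LibraryDesign,
    depth: int,
    error_rate: float,
    seed: int,
    r1_path,
    r2_path,
    tag: str = "sim",
) -> None:
    """Emit a paired-end FASTQ pair for one population.

    ``depth`` clones are sampled with replacement proportionally to their
    abundances; each amplicon is read from both ends (R1 forward, R2 reverse
    complement, up to 150 bp) and independent per-base substitution errors
    are applied at ``error_rate``.  Read ids encode the source variant for
    debugging.  Output is byte-identical for a fixed seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    keys = sorted(population)
    probs = np.array([population[k] for k in keys], dtype=float)
    probs /= probs.sum()
    idx = rng.choice(len(keys), size=depth, p=probs)

    amplicons = [design.build_amplicon(k) for k in keys]
    variants = [variant_of(k) for k in keys]
    r1_tpl = np.array(
        [
            np.frombuffer(a[:READ_LENGTH].encode(), dtype=np.uint8)
            for a in amplicons
        ]
    )
    r2_tpl = np.array(
        [
            np.frombuffer(
                reverse_complement(a)[:READ_LENGTH].encode(), dtype=np.uint8
            )
            for a in amplicons
        ]
    )
    code_of = np.full(256, 255, dtype=np.uint8)
    for b, i in _BASE_CODE.items():
        code_of[ord(b)] = i

    out = []
    for tpl in (r1_tpl, r2_tpl):
        reads = tpl[idx].copy()
        if error_rate > 0:
            err = rng.random(reads.shape) < error_rate
            n_err = int(err.sum())
            if n_err:
                orig = code_of[reads[err]]
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                reads[err] = _AA_BYTES[(orig + shift) % 4]
        out.append(reads)

    qual = "I" * out[0].shape[1]
    for path, reads, mate in ((r1_path, out[0], 1), (r2_path, out[1], 2)):
        chunks = []
        for i in range(depth):
            name = f"{tag}:{i}:{variants[idx[i]]}"
            chunks.append(
                f"@{name}/{mate}\n{reads[i].tobytes().decode()}\n+\n{qual}\n"
            )
        _write_gzip_text(path, "".join(chunks))


@dataclass
class ScenarioResult:
    design: LibraryDesign
    truth: SimulationTruth
    config: ScenarioConfig
    outdir: Path
    sample_sheet: Path
    truth_manifest: Path
    populations: dict  # arm -> [population per round, index 0 = naive]


def run_scenario(
    config: ScenarioConfig = ScenarioConfig(),
    outdir=None,
    design: LibraryDesign | None = None,
    emit_reads: bool = True,
) -> ScenarioResult:
    """Run a full two-arm scenario: naive sampling, planting, ``rounds``
    selection rounds per arm from the shared naive library, and per-round
    FASTQ emission plus a sample sheet and machine-readable truth manifest.

    With ``emit_reads=False`` only the populations are produced (no files);
    ``outdir`` may then be omitted.
    """
    if design is None:
        design = default_design(config.mutation_rate, config.rate_level)
    ss = np.random.SeedSequence(config.seed)
    # deterministic per-purpose child seeds
    seeds = {
        "naive": int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
    }
    naive = sample_naive_library(design, config.n_clones, seeds["naive"])
    population, truth = plant_variants(naive, config.plant, design, config)

    populations: dict[str, list] = {}
    for ai, arm in enumerate(ARMS):
        pops = [dict(population)]
        for r in range(1, config.rounds + 1):
            scale = (
                config.background_scale[r - 1]
                if len(config.background_scale) >= r
                else 1.0
            )
            seed_r = int(
                np.random.SeedSequence((config.seed, 1000 + ai, r))
                .generate_state(1)[0]
                % 2**31
            )
            pops.append(
                simulate_round(pops[-1], arm, truth, config, seed_r, scale)
            )
        populations[arm] = pops

    if not emit_reads:
        return ScenarioResult(
            design, truth, config, Path("."), Path("."), Path("."), populations
        )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    # shared naive library: emit R0 once, reference it from both arms
    r0 = (outdir / "naive_R0_1.fastq.gz", outdir / "naive_R0_2.fastq.gz")
    seed_emit = int(
        np.random.SeedSequence((config.seed, 3000)).generate_state(1)[0] % 2**31
    )
    emit_fastq(
        population, design, config.depth, config.error_rate, seed_emit,
        *r0, tag="sim:R0",
    )
    for arm in ARMS:
        rows.append((arm, 0, r0[0].name, r0[1].name))
    for ai, arm in enumerate(ARMS):
        for r in range(1, config.rounds + 1):
            p1 = outdir / f"{arm}_R{r}_1.fastq.gz"
            p2 = outdir / f"{arm}_R{r}_2.fastq.gz"
            seed_r = int(
                np.random.SeedSequence((config.seed, 4000 + ai, r))
                .generate_state(1)[0]
                % 2**31
            )
            emit_fastq(
                populations[arm][r], design, config.depth, config.error_rate,
                seed_r, p1, p2, tag=f"sim:{arm}:R{r}",
            )
            rows.append((arm, r, p1.name, p2.name))

    sheet = outdir / "samples.tsv"
    with open(sheet, "w") as fh:
        fh.write("arm\tround\tr1\tr2\n")
        for arm, r, p1, p2 in sorted(rows):
            fh.write(f"{arm}\t{r}\t{p1}\t{p2}\n")

    manifest = outdir / "truth.json"
    with open(manifest, "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(config).items()
                    if k != "plant"
                },
                "planted": [asdict(s) for s in config.plant],
                "planted_specific": sorted(truth.planted_specific),
                "planted_dual": sorted(truth.planted_dual),
                "planted_sticky": sorted(truth.planted_sticky),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return ScenarioResult(
        design, truth, config, outdir, sheet, manifest, populations
    )
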