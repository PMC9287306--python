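"""Genetic algorithm for synonymous codon optimization.

Starting from a validated coding sequence, each iteration proposes N
daughter sequences by mutating a proportion p of the eligible codon
positions (interior positions whose amino acid has at least two codons;
the start and stop codons are never touched), drawing replacement codons
from the direction-specific softmax-over-rank distributions.  Elitist
selection keeps the fittest of {parent} + daughters, fitness being the
predicted stability (maximized when optimizing, minimized when
deoptimizing).  The walk stops after m iterations, or early once the
fittest score crosses the threshold t (above +t when optimizing, below
-t when deoptimizing), and the per-iteration parents form the
optimization path: a gradient of synonymous variants ordered by
predicted stability.

All randomness flows through one seeded ``numpy`` Generator per call,
consumed in a fixed order (daughter by daughter: positions first, then
one codon draw per position), so identical inputs give byte-identical
outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .codon_core import (
    AA_TO_CODONS,
    CODON_TO_AA,
    STOP_CODONS,
    CodingSequence,
    DiffCount,
    count_differences,
    translate,
)
from .stability import (
    SamplingDistribution,
    StabilityScore,
    WeightTable,
    mutation_distribution,
    predict_stability,
)

DIRECTIONS = ("optimize", "deoptimize")


@dataclass(frozen=True)
class OptimizerConfig:
    """Parameters of the evolutionary search.

    t : stability threshold for early stopping (default 1, in the
        predictor's arbitrary decay-rate units; the deoptimization stop
        is symmetric at -t).
    N : daughters proposed per iteration (default 10).
    p : proportion of eligible codon positions mutated per daughter
        (default 0.05; at least one position is always mutated).
    m : maximum iterations (default 10).
    """

    t: float = 1.0
    N: int = 10
    p: float = 0.05
    m: int = 10
    seed: int = 0
    direction: str = "optimize"

    def __post_init__(self) -> None:
        if not np.isfinite(self.t):
            raise ValueError("threshold t must be finite")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0 < self.p <= 1):
            raise ValueError("p must be in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


@dataclass(frozen=True)
class PathStep:
    """One iteration's selected parent along an optimization path."""

    iteration: int
    sequence: CodingSequence
    score: StabilityScore
    diff: DiffCount


@dataclass(frozen=True)
class OptimizationPath:
    """Per-iteration fittest sequences; step 0 is the input."""

    steps: tuple[PathStep, ...]
    terminated_early: bool
    direction: str

    @property
    def final(self) -> PathStep:
        return self.steps[-1]

    def scores(self) -> list[float]:
        return [s.score.value for s in self.steps]


def eligible_positions(seq: CodingSequence) -> list[int]:
    """Codon indices open to synonymous mutation.

    The first and last codons are excluded (start and stop are fixed), as
    is any position whose amino acid admits a single codon (Met, Trp).
    """
    codons = seq.codons
    out = []
    for i in range(1, len(codons) - 1):
        codon = codons[i]
        if codon in STOP_CODONS:
            continue
        if len(AA_TO_CODONS[CODON_TO_AA[codon]]) >= 2:
            out.append(i)
    return out


def _family_distributions(
    table: WeightTable, direction: str
) -> dict[str, SamplingDistribution]:
    return {aa: mutation_distribution(aa, direction, table) for aa in AA_TO_CODONS}


def propose_daughters(
    seq: CodingSequence,
    config: OptimizerConfig,
    table: WeightTable,
    rng: np.random.Generator,
    _dists: dict[str, SamplingDistribution] | None = None,
) -> list[CodingSequence]:
    """Propose N synonymous daughter sequences.

    Each daughter mutates k = max(1, round(p * E)) positions drawn
    uniformly without replacement from the E eligible positions; at each,
    a synonymous codon different from the current one is drawn from the
    direction's sampling distribution (current codon excluded, remaining
    probabilities renormalized).
    """
    dists = _dists if _dists is not None else _family_distributions(table, config.direction)
    elig = eligible_positions(seq)
    if not elig:
        warnings.warn(
            f"sequence {seq.id!r} has no synonymously mutable position; "
            "daughters are copies of the input",
            stacklevel=2,
        )
        return [seq] * config.N
    k = min(len(elig), max(1, round(config.p * len(elig))))
    codons = list(seq.codons)
    daughters = []
    for _ in range(config.N):
        picked = rng.choice(len(elig), size=k, replace=False)
        new_codons = list(codons)
        for j in sorted(int(x) for x in picked):
            pos = elig[j]
            current = codons[pos]
            aa = CODON_TO_AA[current]
            new_codons[pos] = dists[aa].sample(rng, exclude=current)
        daughters.append(seq.with_codons(new_codons))
    return daughters


def evolve(
    seq: CodingSequence, config: OptimizerConfig, table: WeightTable
) -> OptimizationPath:
    """Run the evolutionary search, returning the optimization path.

    Selection is elitist over {parent} + daughters, so the path score is
    non-decreasing when optimizing and non-increasing when deoptimizing.
    Early stop: fittest score > t (optimize) or < -t (deoptimize); the
    threshold is checked on the input too, so an already-past-threshold
    sequence yields a single-step path.
    """
    rng = np.random.default_rng(config.seed)
    sign = 1.0 if config.direction == "optimize" else -1.0
    dists = _family_distributions(table, config.direction)

    parent = seq
    parent_score = predict_stability(parent, table)
    steps = [PathStep(0, parent, parent_score, DiffCount(0, 0))]
    terminated_early = False
    if sign * parent_score.value > config.t:
        return OptimizationPath(tuple(steps), terminated_early=True,
                                direction=config.direction)

    for iteration in range(1, config.m + 1):
        daughters = propose_daughters(parent, config, table, rng, _dists=dists)
        best, best_score = parent, parent_score
        for d in daughters:
            s = predict_stability(d, table)
            if sign * s.value > sign * best_score.value:
                best, best_score = d, s
        parent, parent_score = best, best_score
        steps.append(
            PathStep(iteration, parent, parent_score, count_differences(seq, parent))
        )
        if sign * parent_score.value > config.t:
            terminated_early = True
            break
    return OptimizationPath(tuple(steps), terminated_early=terminated_early,
                            direction=config.direction)


@dataclass(frozen=True)
class Variant:
    """A designed synonymous variant with its annotations."""

    id: str
    direction: str
    sequence: CodingSequence
    score: StabilityScore
    diff: DiffCount


def design_variants(
    seq: CodingSequence,
    table: WeightTable,
    n_each: int = 9,
    seed: int = 0,
    config: OptimizerConfig | None = None,
) -> dict[str, list[Variant]]:
    """Design up to ``n_each`` optimized and deoptimized variants.

    Runs the evolutionary search in both directions (with at least
    ``n_each`` iterations so the path can supply that many points) and
    returns the distinct path sequences per direction, annotated with
    predicted stability and nucleotide/codon changes versus the input and
    ordered by predicted stability.  Fewer than ``n_each`` come back when
    the path stops early or revisits sequences.
    """
    base = config if config is not None else OptimizerConfig()
    out: dict[str, list[Variant]] = {}
    for direction in DIRECTIONS:
        cfg = replace(base, direction=direction, m=max(base.m, n_each), seed=seed)
        path = evolve(seq, cfg, table)
        seen = {seq.nucleotides}
        variants = []
        for step in path.steps[1:]:
            if step.sequence.nucleotides in seen:
                continue
            seen.add(step.sequence.nucleotides)
            variants.append(
                Variant(
                    id=f"{seq.id}_{direction}_{len(variants) + 1}",
                    direction=direction,
                    sequence=step.sequence,
                    score=step.score,
                    diff=step.diff,
                )
            )
        variants.sort(key=lambda v: v.score.value)
        # keep the most-advanced path points in each direction
        kept = variants[-n_each:] if direction == "optimize" else variants[:n_each]
        out[direction + "d"] = kept
    return {"optimized": out["optimized"], "deoptimized": out["deoptimized"]}


@dataclass(frozen=True)
class TargetResult:
    """Closest-achieved sequence for a target predicted stability."""

    sequence: CodingSequence
    achieved: StabilityScore
    target: float
    gap: float
    within_tolerance: bool
    path: OptimizationPath


def optimize_to_target(
    seq: CodingSequence,
    target: float,
    table: WeightTable,
    tolerance: float = 0.05,
    seed: int = 0,
    config: OptimizerConfig | None = None,
) -> TargetResult:
    """Evolve toward a target predicted stability and return the closest hit.

    The search runs in the direction of the target (optimize if the target
    exceeds the input's prediction, deoptimize otherwise) with the stop
    threshold replaced by the target, then returns the path sequence whose
    prediction is nearest the target.  A sequence always comes back — the
    closest achieved — with ``within_tolerance`` false when the residual
    gap exceeds ``tolerance``.
    """
    if not np.isfinite(target):
        raise ValueError("target must be finite")
    base = config if config is not None else OptimizerConfig()
    current = predict_stability(seq, table).value
    direction = "optimize" if target > current else "deoptimize"
    # evolve() stops once sign*score crosses sign*t; aiming t at the target
    # halts the walk as soon as the target side is reached
    t = target if direction == "optimize" else -target
    cfg = replace(base, direction=direction, t=t, seed=seed)
    path = evolve(seq, cfg, table)
    best = min(path.steps, key=lambda s: abs(s.score.value - target))
    gap = abs(best.score.value - target)
    return TargetResult(
        sequence=best.sequence,
        achieved=best.score,
        target=float(target),
        gap=gap,
        within_tolerance=gap <= tolerance,
        path=path,
    )
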