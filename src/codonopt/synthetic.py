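"""Deterministic synthetic data: sequences, weight tables, reporter reads.

Everything the other modules consume can be generated here from a seed,
so the whole pipeline is testable without any experimental download.
``simulate_reporter_reads`` is the inverse of the decay pipeline: given a
designed library and per-reporter true decay rates it emits amplicon
reads whose per-sample counts follow first-order decay plus multinomial
sequencing noise at fixed depth, with optional substitution/indel
injection to populate the imperfect set.  The ground truth comes back
alongside the reads so recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_core import SENSE_CODONS, STOP_CODONS, CodingSequence
from .library_design import DesignedLibrary
from .reporter_decay import (
    DEFAULT_TIMEPOINTS,
    FIVE_PRIME_CONSTANT,
    THREE_PRIME_CONSTANT,
    ReadRecord,
    SampleKey,
)
from .stability import WeightTable

_SENSE = tuple(SENSE_CODONS)


def random_cds(n_codons: int, rng: np.random.Generator, id: str = "seq") -> CodingSequence:
    """Random clean ORF: ATG, n_codons - 1 random sense codons, TAA.

    Total length is (n_codons + 1) codons counting the stop; always
    passes validation.
    """
    if n_codons < 2:
        raise ValueError("need at least 2 codons (start + one sense codon)")
    body = [str(_SENSE[i]) for i in rng.integers(0, len(_SENSE), size=n_codons - 1)]
    return CodingSequence("ATG" + "".join(body) + "TAA", id=id)


def synthetic_weight_table(
    spread: float, seed: int, species: str = "custom"
) -> WeightTable:
    """Weight table with 61 uniform(-spread/2, +spread/2) weights."""
    if spread <= 0:
        raise ValueError("spread must be positive")
    rng = np.random.default_rng(seed)
    w = rng.uniform(-spread / 2, spread / 2, size=len(SENSE_CODONS))
    return WeightTable(
        weights={c: float(x) for c, x in zip(SENSE_CODONS, w)},
        intercept=0.0,
        species=species,
        provenance=f"synthetic uniform(+/-{spread / 2}), seed={seed}",
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of a simulated reporter time course.

    Defaults mirror the experimental design the pipeline targets: three
    timepoints at 2, 5 and 8 hours post-injection, three replicates, and
    a fixed per-sample sequencing depth.  ``rates`` are true first-order
    decay slopes per hour (typically negative); ``initial_abundances``
    are relative time-zero amounts (default equal).
    """

    rates: tuple[float, ...]
    initial_abundances: tuple[float, ...] | None = None
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    replicates: int = 3
    depth: int = 100_000
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rates or not all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite and non-empty")
        if self.initial_abundances is not None:
            if len(self.initial_abundances) != len(self.rates):
                raise ValueError("initial_abundances must match rates in length")
            if any(a <= 0 for a in self.initial_abundances):
                raise ValueError("initial abundances must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.replicates < 1 or not self.timepoints:
            raise ValueError("need >= 1 replicate and >= 1 timepoint")
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r <= 1:
                raise ValueError("error rates must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedReads:
    """Reads plus the ground truth that generated them.

    ``input_rates`` are the absolute first-order rates the simulation was
    driven with.  ``true_rates`` are the rates the TPM pipeline estimates:
    abundance is quantified per-sample as a fixed-sum composition, so every
    log-TPM trajectory carries a common term - the log of the library-wide
    total - whose least-squares slope over the design timepoints shifts all
    fitted slopes equally.  ``true_rates`` subtracts that common slope from
    the input rates (exact, because least squares is linear in the
    response), giving the decay rates relative to the library average that
    a compositional read-out can actually measure.
    """

    reads: tuple[ReadRecord, ...]
    true_rates: dict[str, float]  # variant id -> relative decay rate per hour
    input_rates: dict[str, float]  # variant id -> absolute simulated rate
    true_counts: dict[tuple[float, int], dict[str, int]]  # sample -> id -> count


def _corrupt(seq: str, spec: SimulationSpec, rng: np.random.Generator) -> str:
    """Apply at most one error event per read, per error channel."""
    s = seq
    if spec.substitution_rate and rng.random() < spec.substitution_rate:
        i = int(rng.integers(len(s)))
        alt = "ACGT".replace(s[i], "")
        s = s[:i] + alt[int(rng.integers(3))] + s[i + 1 :]
    if spec.insertion_rate and rng.random() < spec.insertion_rate:
        i = int(rng.integers(len(s) + 1))
        s = s[:i] + "ACGT"[int(rng.integers(4))] + s[i:]
    if spec.deletion_rate and rng.random() < spec.deletion_rate and len(s) > 1:
        i = int(rng.integers(len(s)))
        s = s[:i] + s[i + 1 :]
    return s


def simulate_reporter_reads(
    library: DesignedLibrary, spec: SimulationSpec
) -> SimulatedReads:
    """Simulate the reporter time-course experiment.

    Per sample, the expected share of reporter i is proportional to
    N0_i * exp(rate_i * t); actual counts are one multinomial draw at the
    spec's depth (fixed sequencing depth, exact TPM denominators).  Each
    read is 5' constant + variable region + 3' constant, corrupted at the
    spec's error rates.  Identical error-free reads are collapsed into
    counted records; corrupted reads are emitted individually.
    """
    variants = library.variants
    if len(spec.rates) != len(variants):
        raise ValueError(
            f"spec provides {len(spec.rates)} rates for {len(variants)} variants"
        )
    n0 = (np.ones(len(variants)) if spec.initial_abundances is None
          else np.array(spec.initial_abundances, dtype=float))
    rates = np.array(spec.rates, dtype=float)
    rng = np.random.default_rng(spec.seed)
    any_errors = (spec.substitution_rate or spec.insertion_rate
                  or spec.deletion_rate)

    amplicons = [FIVE_PRIME_CONSTANT + v.variable_region + THREE_PRIME_CONSTANT
                 for v in variants]
    input_rates = {v.id: float(r) for v, r in zip(variants, rates)}
    # common slope induced by fixed-sum normalization: least-squares slope
    # of the log total abundance over the design timepoints
    times = np.array(spec.timepoints, dtype=float)
    log_totals = np.array(
        [np.log(np.sum(n0 * np.exp(rates * t))) for t in times]
    )
    tc = times - times.mean()
    common_slope = float(tc @ (log_totals - log_totals.mean()) / (tc @ tc)) \
        if len(times) > 1 else 0.0
    true_rates = {v.id: float(r) - common_slope
                  for v, r in zip(variants, rates)}
    true_counts: dict[tuple[float, int], dict[str, int]] = {}
    reads: list[ReadRecord] = []
    for t in spec.timepoints:
        weights = n0 * np.exp(rates * t)
        probs = weights / weights.sum()
        for rep in range(1, spec.replicates + 1):
            sample = SampleKey(float(t), rep)
            counts = rng.multinomial(spec.depth, probs)
            true_counts[(float(t), rep)] = {
                v.id: int(c) for v, c in zip(variants, counts) if c
            }
            for amplicon, c in zip(amplicons, counts):
                if not c:
                    continue
                if not any_errors:
                    reads.append(ReadRecord(amplicon, sample, count=int(c)))
                    continue
                clean = 0
                for _ in range(int(c)):
                    corrupted = _corrupt(amplicon, spec, rng)
                    if corrupted == amplicon:
                        clean += 1
                    else:
                        reads.append(ReadRecord(corrupted, sample))
                if clean:
                    reads.append(ReadRecord(amplicon, sample, count=clean))
    return SimulatedReads(tuple(reads), true_rates, input_rates, true_counts)


def write_reads_text(
    reads: tuple[ReadRecord, ...], directory: str | Path,
) -> Path:
    """Write reads as per-sample text files plus a sample-manifest CSV.

    Expands counted records to one line per read; returns the manifest
    path (columns file,timepoint_hours,replicate) in the dialect the
    decay pipeline reads.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_sample: dict[tuple[float, int], list[str]] = {}
    for r in reads:
        key = (r.sample.timepoint, r.sample.replicate)
        by_sample.setdefault(key, []).extend([r.sequence] * r.count)
    manifest = directory / "samples.csv"
    with open(manifest, "w") as fh:
        fh.write("file,timepoint_hours,replicate\n")
        for (t, rep), seqs in sorted(by_sample.items()):
            name = f"t{t:g}_r{rep}.txt"
            (directory / name).write_text("\n".join(seqs) + "\n")
            fh.write(f"{name},{t:g},{rep}\n")
    return manifest


def synonymous_variant_with_diffs(
    seq: CodingSequence,
    n_codon_changes: int,
    n_nt_changes: int,
    rng: np.random.Generator,
    id: str = "variant",
) -> CodingSequence:
    """Construct a synonymous variant with exact difference counts.

    Picks ``n_codon_changes`` interior codon positions and swaps each for
    a synonymous codon, choosing replacements so the nucleotide
    differences total exactly ``n_nt_changes``.  Used to build synthetic
    stand-ins for published variant pairs whose printed nucleotide/codon
    change counts are known but whose sequences are not shipped here.
    Raises if the requested combination is infeasible for the sequence.
    """
    from .codon_core import AA_TO_CODONS, CODON_TO_AA

    if not n_codon_changes <= n_nt_changes <= 3 * n_codon_changes:
        raise ValueError("need codon_changes <= nt_changes <= 3*codon_changes")
    codons = list(seq.codons)
    interior = [i for i in range(1, len(codons) - 1)
                if codons[i] not in STOP_CODONS]
    # per position: map nt-distance -> available synonymous codons
    options: list[tuple[int, dict[int, list[str]]]] = []
    for i in interior:
        fam = AA_TO_CODONS[CODON_TO_AA[codons[i]]]
        by_dist: dict[int, list[str]] = {}
        for alt in fam:
            if alt == codons[i]:
                continue
            d = sum(a != b for a, b in zip(alt, codons[i]))
            by_dist.setdefault(d, []).append(alt)
        if by_dist:
            options.append((i, by_dist))
    if len(options) < n_codon_changes:
        raise ValueError("not enough mutable positions")
    order = list(rng.permutation(len(options)))
    chosen: list[tuple[int, dict[int, list[str]]]] = [options[j] for j in order]

    # start every change at nucleotide distance 1 (each synonymous family
    # has a single-base alternative), then upgrade changes one step at a
    # time until the nucleotide total is met
    selected = [
        (idx, min(chosen[idx][1])) for idx in range(n_codon_changes)
    ]
    budget = n_nt_changes - sum(d for _, d in selected)
    if budget < 0:
        raise ValueError("cannot place the requested codon changes")
    progressed = True
    while budget > 0 and progressed:
        progressed = False
        for k, (idx, d) in enumerate(selected):
            if budget == 0:
                break
            by_dist = chosen[idx][1]
            for d2 in (d + 1, d + 2):
                if d2 in by_dist and (d2 - d) <= budget:
                    selected[k] = (idx, d2)
                    budget -= d2 - d
                    progressed = True
                    break
    if budget != 0:
        raise ValueError("cannot reach the requested nucleotide changes")
    out = list(codons)
    for idx, d in selected:
        pos, by_dist = chosen[idx]
        out[pos] = str(by_dist[d][int(rng.integers(len(by_dist[d])))])
    return seq.with_codons(out, id=id)
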