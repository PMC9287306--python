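"""Reporter-library design: random proteins, permutations, targeted variants.

The design emulates a massive synonymous-reporter experiment: sample a
small set of base proteins from average proteome amino-acid usage, expand
each into random permutations (same residues, shuffled order), reverse-
translate each protein into a starting coding sequence, and evolve that
sequence toward each of several target predicted stabilities in
independent runs.  With the defaults (10 bases x 10 permutations x 5
targets x 2 runs) this yields exactly 1000 variants over 100 proteins,
spanning five bins of increasing predicted stability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_core import AA_TO_CODONS, CodingSequence, write_fasta
from .evolution import OptimizerConfig, TargetResult, optimize_to_target
from .stability import StabilityScore, WeightTable

#: Average vertebrate proteome amino-acid usage (proportions), a documented
#: approximation of zebrafish proteome composition; configurable input.
DEFAULT_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.069, "R": 0.056, "N": 0.039, "D": 0.049, "C": 0.022,
    "Q": 0.046, "E": 0.070, "G": 0.063, "H": 0.025, "I": 0.046,
    "L": 0.099, "K": 0.057, "M": 0.022, "F": 0.037, "P": 0.061,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.029, "V": 0.061,
}

#: The five default target predicted stabilities (arbitrary decay-rate
#: units), spanning unstable to stable bins.
DEFAULT_TARGETS = (-0.99, -0.16, 0.08, 0.31, 0.77)


@dataclass(frozen=True)
class LibraryDesignSpec:
    """Parameters of the library design procedure."""

    n_base_proteins: int = 10
    protein_length: int = 100
    n_permutations: int = 10
    targets: tuple[float, ...] = DEFAULT_TARGETS
    runs_per_target: int = 2
    aa_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_base_proteins < 1 or self.n_permutations < 1:
            raise ValueError("need at least one base protein and one permutation")
        if self.protein_length < 2:
            raise ValueError("protein_length must be >= 2")
        if self.runs_per_target < 1 or not self.targets:
            raise ValueError("need at least one target and one run per target")
        total = sum(self.aa_frequencies.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"amino-acid frequencies sum to {total}, not 1")
        if set(self.aa_frequencies) - set(AA_TO_CODONS):
            raise ValueError("frequencies contain non-standard amino acids")


@dataclass(frozen=True)
class LibraryProtein:
    id: str
    base_id: str
    sequence: str  # amino acids


@dataclass(frozen=True)
class LibraryVariant:
    id: str
    protein_id: str
    base_id: str
    target: float
    run: int
    cds: CodingSequence
    achieved: StabilityScore

    @property
    def variable_region(self) -> str:
        """Amplicon variable region: the CDS minus its first codon and
        terminal stop.  The cloning context supplies the fixed
        translation start and an in-frame stop, so for a 100-aa protein
        this is 3*(100-1) = 297 nt."""
        return self.cds.nucleotides[3:-3]


@dataclass(frozen=True)
class DesignedLibrary:
    proteins: tuple[LibraryProtein, ...]
    variants: tuple[LibraryVariant, ...]
    spec: LibraryDesignSpec

    def variable_regions(self) -> dict[str, str]:
        """variant id -> amplicon variable region."""
        return {v.id: v.variable_region for v in self.variants}


def sample_protein(
    length: int, aa_frequencies: dict[str, float], rng: np.random.Generator
) -> str:
    """Draw an i.i.d. random protein from amino-acid usage frequencies.

    No start methionine is forced: the reporter cloning context supplies
    the fixed initiation codons.
    """
    aas = sorted(aa_frequencies)
    probs = np.array([aa_frequencies[a] for a in aas], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {probs.sum()}, not 1")
    probs = probs / probs.sum()
    return "".join(rng.choice(aas, size=length, p=probs))


def permute_protein(
    protein: str, n_permutations: int, rng: np.random.Generator
) -> list[str]:
    """Uniform random shuffles of a protein (same residues, new order).

    If a shuffle reproduces the input exactly it is re-drawn once, so
    permutations are almost surely distinct from the original.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    out = []
    residues = list(protein)
    for _ in range(n_permutations):
        perm = list(rng.permutation(residues))
        if "".join(perm) == protein:
            perm = list(rng.permutation(residues))
        out.append("".join(perm))
    return out


def reverse_translate(
    protein: str, rng: np.random.Generator, id: str = "seq"
) -> CodingSequence:
    """Encode a protein with uniformly drawn synonymous codons + TAA stop."""
    codons = []
    for aa in protein:
        family = AA_TO_CODONS.get(aa)
        if family is None:
            raise ValueError(f"non-standard residue {aa!r}")
        codons.append(str(rng.choice(family)))
    codons.append("TAA")
    return CodingSequence("".join(codons), id=id)


def design_library(
    spec: LibraryDesignSpec,
    table: WeightTable,
    optimizer: OptimizerConfig | None = None,
) -> DesignedLibrary:
    """Run the full library design procedure.

    Emits exactly n_base_proteins * n_permutations proteins and one
    variant per (protein, target, run) — unreachable targets yield the
    closest-achieved sequence, so the variant count is deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    proteins: list[LibraryProtein] = []
    for b in range(spec.n_base_proteins):
        base_id = f"base{b + 1:02d}"
        base = sample_protein(spec.protein_length, spec.aa_frequencies, rng)
        for k, perm in enumerate(permute_protein(base, spec.n_permutations, rng)):
            proteins.append(
                LibraryProtein(id=f"{base_id}_p{k + 1:02d}", base_id=base_id,
                               sequence=perm)
            )

    variants: list[LibraryVariant] = []
    # per-call seeds derived from one spawned stream, kept below 2**31
    seed_rng = np.random.default_rng(spec.seed + 1)
    for prot in proteins:
        start = reverse_translate(prot.sequence, rng, id=prot.id)
        for ti, target in enumerate(spec.targets):
            for run in range(spec.runs_per_target):
                run_seed = int(seed_rng.integers(0, 2**31 - 1))
                result: TargetResult = optimize_to_target(
                    start, target, table, seed=run_seed, config=optimizer
                )
                vid = f"{prot.id}_t{ti + 1}_r{run + 1}"
                variants.append(
                    LibraryVariant(
                        id=vid,
                        protein_id=prot.id,
                        base_id=prot.base_id,
                        target=float(target),
                        run=run + 1,
                        cds=CodingSequence(result.sequence.nucleotides, id=vid),
                        achieved=result.achieved,
                    )
                )
    return DesignedLibrary(tuple(proteins), tuple(variants), spec)


def write_manifest(library: DesignedLibrary, path: str | Path) -> None:
    """Design-manifest CSV: one row per variant."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["variant_id", "protein_id", "base_id", "target", "run",
                    "achieved_stability", "sequence"])
        for v in library.variants:
            w.writerow([v.id, v.protein_id, v.base_id, v.target, v.run,
                        f"{v.achieved.value:.6f}", v.cds.nucleotides])


def write_library_fasta(library: DesignedLibrary, path: str | Path) -> None:
    write_fasta((v.cds for v in library.variants), path)
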