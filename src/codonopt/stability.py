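"""Linear codon-composition model of mRNA stability.

The predictor is a deterministic map from codon composition to a stability
score in arbitrary decay-rate units (positive = more stable):

    score = intercept + sum_c weight(c) * proportion(c)

with one weight per sense codon (a CSC-style stabilization weight: higher
weight = more stabilizing codon) and proportions taken over the coding
sequence excluding the terminal stop.  The same weights, ranked within
each synonymous family and pushed through a softmax, define the codon
sampling distributions the evolutionary optimizer mutates with.

Built-in species tables shipped under ``data/`` are synthetic CSC-style
stand-ins (seeded uniform draws, one table per species name); they give the
model realistic spread and distinct per-species behaviour but are not the
published regression coefficients, which users can supply as a TSV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .codon_core import AA_TO_CODONS, CODON_TO_AA, SENSE_CODONS, CodingSequence, codon_composition

BUILTIN_SPECIES = ("human", "mouse", "zebrafish", "xenopus")


@dataclass(frozen=True)
class StabilityScore:
    """Predicted mRNA stability in arbitrary decay-rate units."""

    value: float
    species: str = "custom"

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite stability score: {self.value}")


@dataclass(frozen=True)
class WeightTable:
    """Per-codon stability weights plus an intercept.

    Exactly the 61 sense codons must be present.  A synonymous family of
    size >= 2 whose weights are all identical makes rank-based sampling
    uninformative for that amino acid; this is allowed but warned about.
    """

    weights: dict[str, float]
    intercept: float = 0.0
    species: str = "custom"
    provenance: str = ""

    def __post_init__(self) -> None:
        got = set(self.weights)
        expected = set(SENSE_CODONS)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"weight table must cover the 61 sense codons exactly; "
                f"missing={missing} extra={extra}"
            )
        for c, w in self.weights.items():
            if not math.isfinite(float(w)):
                raise ValueError(f"non-finite weight for codon {c}")
        degenerate = [
            aa
            for aa, codons in AA_TO_CODONS.items()
            if len(codons) >= 2
            and len({self.weights[c] for c in codons}) < 2
        ]
        if degenerate:
            warnings.warn(
                "synonymous families with all-equal weights (sampling is "
                f"uniform for them): {sorted(degenerate)}",
                stacklevel=2,
            )

    @property
    def spread(self) -> float:
        vals = list(self.weights.values())
        return max(vals) - min(vals)


def load_weight_table(source: str | Path) -> WeightTable:
    """Load a weight table from a TSV path or a built-in species name.

    The TSV dialect is two columns ``codon<TAB>weight`` with optional
    comment lines ``#intercept=<float>`` and ``#species=<name>``.
    Built-in names (human, mouse, zebrafish, xenopus) resolve to synthetic
    CSC-style tables shipped with the package.
    """
    name = str(source)
    if name in BUILTIN_SPECIES:
        ref = resources.files("codonopt.data") / f"{name}_csc_synthetic.tsv"
        return _parse_weight_tsv(ref.read_text(), default_species=name)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a built-in species "
            f"{BUILTIN_SPECIES} nor an existing TSV file"
        )
    return _parse_weight_tsv(path.read_text(), default_species="custom",
                             provenance=str(path))


def _parse_weight_tsv(
    text: str, default_species: str = "custom", provenance: str = ""
) -> WeightTable:
    weights: dict[str, float] = {}
    intercept = 0.0
    species = default_species
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("intercept="):
                intercept = float(body.split("=", 1)[1])
            elif body.startswith("species="):
                species = body.split("=", 1)[1].strip()
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"line {lineno}: expected 'codon<TAB>weight', got {line!r}")
        codon = fields[0].strip().upper().replace("U", "T")
        if codon in weights:
            raise ValueError(f"line {lineno}: duplicate codon {codon}")
        try:
            weights[codon] = float(fields[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric weight {fields[1]!r}") from exc
    return WeightTable(weights=weights, intercept=intercept, species=species,
                       provenance=provenance)


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    """Write a table in the TSV dialect ``load_weight_table`` reads."""
    lines = [f"#species={table.species}", f"#intercept={table.intercept!r}"]
    lines += [f"{c}\t{table.weights[c]!r}" for c in SENSE_CODONS]
    Path(path).write_text("\n".join(lines) + "\n")


def predict_stability(seq: CodingSequence, table: WeightTable) -> StabilityScore:
    """Predict mRNA stability from codon composition.

    score = intercept + sum over codons of weight * proportion, with the
    terminal stop excluded from the composition.  Depends only on codon
    proportions, not their order.
    """
    _, props = codon_composition(seq, include_stop=False)
    bad = [c for c in props if c not in table.weights]
    if bad:
        raise ValueError(f"sequence contains stop/unknown codons internally: {bad}")
    value = table.intercept + sum(table.weights[c] * p for c, p in props.items())
    return StabilityScore(value=value, species=table.species)


@dataclass(frozen=True)
class SamplingDistribution:
    """Softmax-over-rank codon sampling distribution for one amino acid."""

    amino_acid: str
    direction: str  # "optimize" | "deoptimize"
    probabilities: dict[str, float]

    def sample(self, rng: np.random.Generator, exclude: str | None = None) -> str:
        """Draw a codon, optionally excluding (and renormalizing away) one."""
        items = [(c, p) for c, p in self.probabilities.items() if c != exclude]
        if not items:
            raise ValueError(f"no codon left to sample for {self.amino_acid}")
        codons, probs = zip(*items)
        p = np.asarray(probs, dtype=float)
        p /= p.sum()
        return str(rng.choice(codons, p=p))


def _average_ranks(values: list[float]) -> list[float]:
    """Ascending 1-based ranks with ties sharing the average rank."""
    return list(stats.rankdata(values, method="average"))


def mutation_distribution(
    amino_acid: str, direction: str, table: WeightTable
) -> SamplingDistribution:
    """Softmax-over-rank sampling distribution for one synonymous family.

    Codons are ranked by weight ascending within the family (rank 1 =
    least stabilizing; ties share averaged ranks).  ``optimize`` applies a
    softmax to the ranks themselves, so the most stabilizing codon gets
    the largest probability; ``deoptimize`` applies it to the reversed
    ranks.  Single-codon families return probability 1.
    """
    if direction not in ("optimize", "deoptimize"):
        raise ValueError(f"direction must be optimize|deoptimize, got {direction!r}")
    codons = AA_TO_CODONS.get(amino_acid)
    if not codons:
        raise ValueError(f"unknown amino acid {amino_acid!r}")
    ranks = np.array(_average_ranks([table.weights[c] for c in codons]))
    if direction == "deoptimize":
        ranks = (len(codons) + 1) - ranks
    z = np.exp(ranks - ranks.max())
    probs = z / z.sum()
    return SamplingDistribution(
        amino_acid=amino_acid,
        direction=direction,
        probabilities={c: float(p) for c, p in zip(codons, probs)},
    )


def compare_gene_sets(
    set_scores: list[StabilityScore | float],
    background_scores: list[StabilityScore | float],
) -> dict[str, float]:
    """Two-sided Welch t-test comparing predicted stabilities of gene sets.

    Used to ask whether a gene family (e.g. circadian regulators,
    ribosomal proteins) is predicted more or less stable than the
    transcriptome background.
    """
    a = np.array([s.value if isinstance(s, StabilityScore) else float(s)
                  for s in set_scores])
    b = np.array([s.value if isinstance(s, StabilityScore) else float(s)
                  for s in background_scores])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 scores")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if math.isnan(t):  # identical zero-variance groups
        t, p = 0.0, 1.0
    return {
        "t_statistic": float(t),
        "p_value": float(p),
        "mean_set": float(a.mean()),
        "mean_background": float(b.mean()),
    }
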