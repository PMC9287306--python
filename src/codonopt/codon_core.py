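"""Codon-level coding-sequence primitives.

A coding sequence (CDS) is held as an uppercase A/C/G/T string whose length
is a multiple of three, addressed codon by codon.  Everything downstream —
stability prediction, synonymous mutagenesis, reporter classification —
works on this representation.  Only the standard (NCBI table 1) genetic
code is supported: the species in scope are vertebrates and all sequences
are nuclear genes.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqIO import parse as _fasta_parse, write as _fasta_write
from Bio.SeqRecord import SeqRecord

#: Standard-code stop codons.
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

#: codon -> one-letter amino acid, sense codons only (61 entries).
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of synonymous codons, sorted alphabetically.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in sorted(set(CODON_TO_AA.values()))
}


class ValidationWarning(enum.Enum):
    """Problems a pasted coding sequence can have."""

    NOT_MULTIPLE_OF_THREE = "not_multiple_of_three"
    INTERNAL_STOP = "internal_stop"
    NO_TERMINAL_STOP = "no_terminal_stop"
    INVALID_CHARACTER = "invalid_character"


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of validating raw coding-sequence text.

    ``is_clean`` is true exactly when ``warnings`` is empty.
    ``normalized`` carries the uppercased, whitespace-stripped, U->T mapped
    sequence so callers can proceed from the same text that was checked.
    """

    warnings: frozenset[ValidationWarning]
    normalized: str

    @property
    def is_clean(self) -> bool:
        return not self.warnings


@dataclass(frozen=True)
class DiffCount:
    """Differences between two equal-length synonymous sequences."""

    nt_changes: int
    codon_changes: int

    def __post_init__(self) -> None:
        if not (0 <= self.codon_changes <= self.nt_changes <= 3 * self.codon_changes
                or self.nt_changes == self.codon_changes == 0):
            raise ValueError(
                f"inconsistent diff counts: {self.nt_changes} nt, "
                f"{self.codon_changes} codons"
            )


def _normalize(raw: str) -> str:
    """Uppercase, drop whitespace, map U (RNA input) to T."""
    return "".join(raw.split()).upper().replace("U", "T")


@dataclass(frozen=True)
class CodingSequence:
    """A validated DNA coding sequence with codon-indexed access.

    Parameters
    ----------
    nucleotides:
        A/C/G/T string (U accepted and mapped to T; case-insensitive;
        internal whitespace ignored).  Length must be a multiple of 3.
    id:
        Free-text label carried through to FASTA/CSV output.
    """

    nucleotides: str
    id: str = "seq"

    def __post_init__(self) -> None:
        norm = _normalize(self.nucleotides)
        if not norm:
            raise ValueError("empty coding sequence")
        if set(norm) - set("ACGT"):
            bad = sorted(set(norm) - set("ACGT"))
            raise ValueError(f"invalid characters in coding sequence: {bad}")
        if len(norm) % 3:
            raise ValueError(
                f"coding sequence length {len(norm)} is not a multiple of 3"
            )
        object.__setattr__(self, "nucleotides", norm)

    @property
    def codons(self) -> tuple[str, ...]:
        nt = self.nucleotides
        return tuple(nt[i : i + 3] for i in range(0, len(nt), 3))

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def __len__(self) -> int:
        return len(self.nucleotides)

    def __iter__(self) -> Iterator[str]:
        return iter(self.codons)

    def with_codons(self, codons: Iterable[str], id: str | None = None) -> "CodingSequence":
        return CodingSequence("".join(codons), id=id if id is not None else self.id)


def validate_cds(raw: str) -> ValidationReport:
    """Validate raw coding-sequence text the way the interactive tool does.

    Every applicable warning is reported, not just the first:
    characters outside A/C/G/T/U, a length that is not a multiple of
    three, a stop codon before the final position, and a missing terminal
    stop (TAA/TAG/TGA).

    Raises
    ------
    ValueError
        If the input is empty after stripping whitespace.
    """
    norm = _normalize(raw)
    if not norm:
        raise ValueError("empty input sequence")
    warnings: set[ValidationWarning] = set()
    invalid = set(norm) - set("ACGT")
    if invalid:
        warnings.add(ValidationWarning.INVALID_CHARACTER)
        # check frame/stop structure on the valid-character subsequence is
        # meaningless; keep whatever structural warnings still apply below
        norm_checked = "".join(c for c in norm if c in "ACGT")
    else:
        norm_checked = norm
    if len(norm) % 3:
        warnings.add(ValidationWarning.NOT_MULTIPLE_OF_THREE)
    codons = [norm_checked[i : i + 3] for i in range(0, len(norm_checked) - 2, 3)]
    if codons:
        if codons[-1] not in STOP_CODONS or len(norm_checked) % 3:
            warnings.add(ValidationWarning.NO_TERMINAL_STOP)
        internal = codons[:-1] if len(norm_checked) % 3 == 0 else codons
        if any(c in STOP_CODONS for c in internal):
            warnings.add(ValidationWarning.INTERNAL_STOP)
    else:
        warnings.add(ValidationWarning.NO_TERMINAL_STOP)
    return ValidationReport(warnings=frozenset(warnings), normalized=norm)


def translate(seq: CodingSequence) -> str:
    """Translate with the standard genetic code.

    A terminal stop is rendered ``*``; a stop codon anywhere else is an
    error (the sequence is not a single ORF).
    """
    out = []
    codons = seq.codons
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if i != len(codons) - 1:
                raise ValueError(f"internal stop codon {codon} at codon {i}")
            out.append("*")
        else:
            out.append(CODON_TO_AA[codon])
    return "".join(out)


def codon_composition(
    seq: CodingSequence, include_stop: bool = False
) -> tuple[dict[str, int], dict[str, float]]:
    """Count codons and their proportions.

    The terminal stop codon is excluded by default: stop codons carry no
    synonymous choice under the optimizer and do not enter the stability
    model.  Proportions sum to 1 over the counted codons.

    Returns
    -------
    (counts, proportions) : pair of dicts keyed by codon.
    """
    codons = list(seq.codons)
    if not include_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise ValueError("no codons to count (stop-only sequence)")
    counts = dict(Counter(codons))
    total = len(codons)
    proportions = {c: n / total for c, n in counts.items()}
    return counts, proportions


def count_differences(a: CodingSequence, b: CodingSequence) -> DiffCount:
    """Count nucleotide and codon differences between two variants.

    The pair is expected to be synonymous (equal translation); a differing
    translation is tolerated with a warning, since users may compare
    arbitrary same-length sequences.  Unequal lengths are an error.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    nt = sum(x != y for x, y in zip(a.nucleotides, b.nucleotides))
    cod = sum(x != y for x, y in zip(a.codons, b.codons))
    if nt:
        try:
            same_protein = translate(a) == translate(b)
        except ValueError:
            same_protein = False
        if not same_protein:
            import warnings as _w

            _w.warn(
                f"sequences {a.id!r} and {b.id!r} are not synonymous",
                stacklevel=2,
            )
    return DiffCount(nt_changes=nt, codon_changes=cod)


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read coding sequences from a FASTA file."""
    return [
        CodingSequence(str(rec.seq), id=rec.id) for rec in _fasta_parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    """Write coding sequences to a FASTA file."""
    records = [SeqRecord(Seq(s.nucleotides), id=s.id, description="") for s in seqs]
    _fasta_write(records, str(path), "fasta")
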