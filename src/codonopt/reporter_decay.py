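"""Reporter-library decay analysis.

Merged amplicon reads from a time-course injection experiment are trimmed
of their constant regions, classified against the designed library
(perfect = exact match to a designed variable region at the expected
length; everything else joins the imperfect set keyed by its re-parsed
ORF), quantified as transcripts per million within each
(timepoint, replicate) sample, filtered for consistent detection, and
fitted with a first-order decay model: ordinary least squares of
log abundance against time, whose slope is the decay rate (higher =
more stable).  A bootstrap over proteins then compares design tools by
the probability that a focal tool produced the most stable variant.
"""

from __future__ import annotations

import csv
import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import STOP_CODONS

#: Constant regions flanking the amplicon variable region (the 5' one is
#: the 11 fixed translation-initiation codons; the 3' one carries the
#: cloning site and an in-frame TAG stop).
FIVE_PRIME_CONSTANT = "ATGGTGAGCAAGGGCGAGGAGCTGTCCCTCGAG"
THREE_PRIME_CONSTANT = "TCTAGATAG"

#: Expected variable-region length from the library design (99 codons).
EXPECTED_LENGTH = 297

DEFAULT_TIMEPOINTS = (2.0, 5.0, 8.0)


@dataclass(frozen=True)
class SampleKey:
    """(timepoint in hours, replicate index) identifying one sample."""

    timepoint: float
    replicate: int


@dataclass(frozen=True)
class ReadRecord:
    """One merged amplicon read with its sample label."""

    sequence: str
    sample: SampleKey
    count: int = 1  # collapsed multiplicity of identical reads


# classification statuses
PERFECT = "perfect"
IMPERFECT = "imperfect"
DISCARDED = "discarded"


@dataclass(frozen=True)
class ClassifiedRead:
    status: str
    reporter_id: str | None  # variant id (perfect) or ORF key (imperfect)
    variable_region: str | None
    reason: str | None = None  # set when discarded


def trim_constant_regions(
    sequence: str,
    five_prime: str = FIVE_PRIME_CONSTANT,
    three_prime: str = THREE_PRIME_CONSTANT,
) -> tuple[str | None, str | None]:
    """Cut out the variable region between the two constant motifs.

    Both motifs must be present (exact match; 5' motif located at its
    first occurrence, 3' motif at its last occurrence downstream).
    Returns (variable_region, None) on success or (None, reason) when the
    read is discarded: ``NO_CONSTANT`` if either motif is absent,
    ``EMPTY`` if nothing lies between them.
    """
    start = sequence.find(five_prime)
    if start < 0:
        return None, "NO_CONSTANT"
    inner_start = start + len(five_prime)
    end = sequence.rfind(three_prime)
    if end < inner_start:
        return None, "NO_CONSTANT"
    region = sequence[inner_start:end]
    if not region:
        return None, "EMPTY"
    return region, None


def _orf_codons(cds: str) -> str | None:
    """Codon string of the ORF starting at the first ATG, up to (and
    excluding) the first stop codon; None without a start or stop."""
    start = cds.find("ATG")
    if start < 0:
        return None
    for i in range(start, len(cds) - 2, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return cds[start:i]
    return None


def classify_reads(
    reads: Iterable[ReadRecord],
    designed_regions: Mapping[str, str],
    expected_length: int = EXPECTED_LENGTH,
    five_prime: str = FIVE_PRIME_CONSTANT,
    three_prime: str = THREE_PRIME_CONSTANT,
) -> list[tuple[ReadRecord, ClassifiedRead]]:
    """Classify reads against the designed library.

    ``designed_regions`` maps variant id -> variable region.  A trimmed
    read at the expected length that exactly matches a designed region is
    PERFECT; any other read that still yields an ORF (constant regions
    re-attached, coding sequence read from the first ATG in consecutive
    triplets until a stop codon) becomes an IMPERFECT reporter keyed by
    that ORF codon string; reads without constant regions or without a
    parseable ORF are DISCARDED.
    """
    region_to_id = {r: vid for vid, r in designed_regions.items()}
    if len(region_to_id) != len(designed_regions):
        warnings.warn("designed variable regions are not unique; duplicate "
                      "regions resolve to one variant id", stacklevel=2)
    out = []
    cache: dict[str, ClassifiedRead] = {}
    for read in reads:
        hit = cache.get(read.sequence)
        if hit is None:
            hit = _classify_one(read.sequence, region_to_id, expected_length,
                                five_prime, three_prime)
            cache[read.sequence] = hit
        out.append((read, hit))
    return out


def _classify_one(
    sequence: str,
    region_to_id: Mapping[str, str],
    expected_length: int,
    five_prime: str,
    three_prime: str,
) -> ClassifiedRead:
    region, reason = trim_constant_regions(sequence, five_prime, three_prime)
    if region is None:
        return ClassifiedRead(DISCARDED, None, None, reason=reason)
    if len(region) == expected_length:
        vid = region_to_id.get(region)
        if vid is not None:
            return ClassifiedRead(PERFECT, vid, region)
    orf = _orf_codons(five_prime + region + three_prime)
    if not orf:
        return ClassifiedRead(DISCARDED, None, region, reason="NO_ORF")
    return ClassifiedRead(IMPERFECT, f"imperfect:{orf}", region)


@dataclass(frozen=True)
class AbundanceMatrix:
    """Reporter x sample abundance: raw counts and TPM side by side.

    Rows are reporter ids (perfect variant ids and imperfect ORF keys);
    columns are (timepoint, replicate) samples.  TPM columns each sum to
    1e6 over the quantified rows.
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    reporter_sets: dict[str, str]  # reporter id -> "perfect" | "imperfect"

    @property
    def samples(self) -> list[SampleKey]:
        return [SampleKey(float(t), int(r)) for t, r in self.counts.columns]


def quantify(
    classified: Iterable[tuple[ReadRecord, ClassifiedRead]],
) -> AbundanceMatrix:
    """Count classified reads per sample and normalize to TPM.

    Perfect and imperfect reporters share the same per-sample denominator
    (discarded reads are excluded).  Every sample must contribute at
    least one quantifiable read.
    """
    tallies: dict[tuple[float, int], Counter] = defaultdict(Counter)
    sets: dict[str, str] = {}
    empty_samples: set[tuple[float, int]] = set()
    for read, cls in classified:
        key = (read.sample.timepoint, read.sample.replicate)
        if cls.status == DISCARDED:
            empty_samples.add(key)
            continue
        tallies[key][cls.reporter_id] += read.count
        sets[cls.reporter_id] = cls.status
    missing = sorted(empty_samples - set(tallies))
    if missing:
        raise ValueError(f"samples with no quantifiable read: {missing}")
    if not tallies:
        raise ValueError("no quantifiable reads in any sample")
    cols = sorted(tallies, key=lambda k: (k[0], k[1]))
    counts = pd.DataFrame(
        {c: pd.Series(tallies[c], dtype=float) for c in cols}
    ).fillna(0.0)
    counts.columns = pd.MultiIndex.from_tuples(cols, names=["timepoint", "replicate"])
    tpm = counts / counts.sum(axis=0) * 1e6
    return AbundanceMatrix(counts=counts, tpm=tpm, reporter_sets=sets)


def filter_detected(
    matrix: AbundanceMatrix,
    mode: str,
    min_reads: int = 20,
    min_replicates: int = 2,
) -> list[str]:
    """Reporter ids that survive the detection filter.

    ``perfect`` mode: nonzero raw count in every sample (all timepoints,
    all replicates).  ``imperfect`` mode: every sample where the reporter
    is detected at all must have at least ``min_reads`` reads, and at
    every timepoint it must be detected in at least ``min_replicates``
    replicates (with the defaults and a 3x3 design: >= 6 data points).
    """
    if mode not in (PERFECT, IMPERFECT):
        raise ValueError(f"mode must be perfect|imperfect, got {mode!r}")
    counts = matrix.counts
    ids = [r for r, s in matrix.reporter_sets.items()
           if s == mode and r in counts.index]
    timepoints = sorted({t for t, _ in counts.columns})
    survivors = []
    for rid in ids:
        row = counts.loc[rid]
        if mode == PERFECT:
            if (row > 0).all():
                survivors.append(rid)
            continue
        detected = row > 0
        if detected.any() and (row[detected] < min_reads).any():
            continue
        ok = all(
            sum(1 for (t, _), d in detected.items() if t == tp and d) >= min_replicates
            for tp in timepoints
        )
        if ok:
            survivors.append(rid)
    return survivors


def filter_orf_length(
    reporter_ids: Iterable[str], min_codons: int = 70
) -> list[str]:
    """Drop imperfect reporters whose parsed ORF is ``min_codons`` codons
    or shorter (applied after detection filtering; perfect ids pass
    through untouched)."""
    out = []
    for rid in reporter_ids:
        if rid.startswith("imperfect:"):
            orf = rid.split(":", 1)[1]
            if len(orf) // 3 <= min_codons:
                continue
        out.append(rid)
    return out


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit for one reporter.

    ``decay_rate`` is the OLS slope of ln(TPM) against time in hours;
    higher (less negative) = more stable.
    """

    reporter_id: str
    decay_rate: float
    intercept: float
    r_squared: float
    n_points: int


def fit_decay(
    series: Sequence[tuple[float, float]], reporter_id: str = ""
) -> DecayFit:
    """Fit ln(abundance) ~ time by ordinary least squares.

    ``series`` is (timepoint_hours, TPM) pairs; replicates pool as
    independent points.  All abundances must be positive (the reporter
    passed detection filtering) and at least two distinct timepoints are
    required.
    """
    times = np.array([t for t, _ in series], dtype=float)
    values = np.array([v for _, v in series], dtype=float)
    if (values <= 0).any():
        raise ValueError(f"nonpositive abundance for {reporter_id!r}")
    if len(np.unique(times)) < 2:
        raise ValueError("need at least two distinct timepoints")
    res = stats.linregress(times, np.log(values))
    r2 = float(res.rvalue) ** 2 if math.isfinite(res.rvalue) else 1.0
    return DecayFit(
        reporter_id=reporter_id,
        decay_rate=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=len(series),
    )


def fit_all(
    matrix: AbundanceMatrix, reporter_ids: Iterable[str]
) -> dict[str, DecayFit]:
    """Fit decay for each surviving reporter from its TPM row.

    Samples where the reporter has zero raw count are dropped (imperfect
    reporters may be undetected in one replicate of a timepoint)."""
    fits = {}
    for rid in reporter_ids:
        row_tpm = matrix.tpm.loc[rid]
        row_n = matrix.counts.loc[rid]
        series = [(float(t), float(v))
                  for (t, _), v, n in zip(row_tpm.index, row_tpm, row_n) if n > 0]
        fits[rid] = fit_decay(series, reporter_id=rid)
    return fits


def tool_win_probability(
    fits: Mapping[str, DecayFit],
    manifest: Mapping[str, tuple[str, str]],
    focal_tool: str,
    reps: int = 300,
    seed: int = 0,
) -> dict[str, object]:
    """Bootstrap the probability that a focal design tool wins.

    ``manifest`` maps variant id -> (protein id, tool name).  Only
    proteins with at least one fitted variant from every tool enter the
    comparison.  Per repetition, one variant per (protein, tool) is drawn
    uniformly; the focal tool scores 1 for a protein iff its variant's
    decay rate strictly exceeds every counterpart's (a tie or loss scores
    0), and the per-protein scores are averaged.  Returns the
    ``reps``-length list of averages and their mean.
    """
    by_protein_tool: dict[str, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    tools: set[str] = set()
    for vid, (protein, tool) in manifest.items():
        tools.add(tool)
        if vid in fits:
            by_protein_tool[protein][tool].append(vid)
    if focal_tool not in tools:
        raise ValueError(f"focal tool {focal_tool!r} not in manifest")
    eligible = [p for p, per_tool in by_protein_tool.items()
                if set(per_tool) == tools]
    if not eligible:
        raise ValueError("no protein has surviving variants from every tool")
    eligible.sort()
    others = sorted(tools - {focal_tool})
    rng = np.random.default_rng(seed)
    averages = []
    for _ in range(reps):
        scores = []
        for protein in eligible:
            per_tool = by_protein_tool[protein]
            focal_rate = fits[per_tool[focal_tool][
                rng.integers(len(per_tool[focal_tool]))]].decay_rate
            win = all(
                focal_rate > fits[per_tool[tool][
                    rng.integers(len(per_tool[tool]))]].decay_rate
                for tool in others
            )
            scores.append(1.0 if win else 0.0)
        averages.append(float(np.mean(scores)))
    return {
        "averages": averages,
        "mean": float(np.mean(averages)),
        "n_proteins": len(eligible),
        "reps": reps,
    }


def pigment_absorbance(
    eye_intensity: float, dark_blank: float, light_blank: float
) -> float:
    """Brightfield absorbance of eye pigmentation.

    A = -log10(T) with T = (eye - dark blank) / (light blank - dark
    blank).  T above 1 (eye brighter than the light blank) is clipped to
    1 with a warning; T <= 0 is an error.
    """
    if light_blank <= dark_blank:
        raise ValueError("light blank must exceed dark blank")
    t = (eye_intensity - dark_blank) / (light_blank - dark_blank)
    if t <= 0:
        raise ValueError(f"non-positive transmittance T={t}")
    if t > 1:
        warnings.warn(f"transmittance T={t:.4f} > 1 clipped to 1", stacklevel=2)
        t = 1.0
    return -math.log10(t)


def correlate_predictions(
    fits: Mapping[str, DecayFit], predictions: Mapping[str, float]
) -> dict[str, float]:
    """Pearson and Spearman correlation of decay rates vs predictions.

    Pairing is by reporter id over the intersection of the two maps; at
    least three shared ids are required.
    """
    ids = sorted(set(fits) & set(predictions))
    if len(ids) < 3:
        raise ValueError(f"need >= 3 paired reporters, have {len(ids)}")
    x = np.array([predictions[i] for i in ids])
    y = np.array([fits[i].decay_rate for i in ids])
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_r": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
        "n": len(ids),
    }


# ---------------------------------------------------------------------------
# File-level interfaces

def read_sample_manifest(path: str | Path) -> list[tuple[Path, SampleKey]]:
    """Read a sample manifest CSV: columns file,timepoint_hours,replicate."""
    out = []
    base = Path(path).parent
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            p = Path(row["file"])
            if not p.is_absolute():
                p = base / p
            out.append((p, SampleKey(float(row["timepoint_hours"]),
                                     int(row["replicate"]))))
    return out


def read_reads_file(path: str | Path, sample: SampleKey) -> list[ReadRecord]:
    """Read merged reads from FASTQ or a headerless one-sequence-per-line
    text file (extension .fastq/.fq selects FASTQ)."""
    path = Path(path)
    reads = []
    if path.suffix.lower() in (".fastq", ".fq"):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(ReadRecord(str(rec.seq).upper(), sample))
    else:
        for line in path.read_text().splitlines():
            line = line.strip().upper()
            if line:
                reads.append(ReadRecord(line, sample))
    return reads


def write_decay_csv(
    fits: Mapping[str, DecayFit], sets: Mapping[str, str], path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Decay CSV: reporter_id,set,decay_rate,r_squared,n_points."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(["reporter_id", "set", "decay_rate", "r_squared", "n_points"])
        for rid in sorted(fits):
            f = fits[rid]
            w.writerow([rid, sets.get(rid, ""), f"{f.decay_rate:.6f}",
                        f"{f.r_squared:.4f}", f.n_points])
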