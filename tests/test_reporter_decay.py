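"""Read trimming, classification, quantification, filtering, decay fitting."""

import math

import numpy as np
import pytest

import codonopt as co
from codonopt.reporter_decay import (
    EXPECTED_LENGTH,
    FIVE_PRIME_CONSTANT,
    IMPERFECT,
    PERFECT,
    THREE_PRIME_CONSTANT,
    ReadRecord,
    SampleKey,
    fit_decay,
    trim_constant_regions,
)

SAMPLES = [SampleKey(t, r) for t in (2.0, 5.0, 8.0) for r in (1, 2, 3)]


def make_region(rng: np.random.Generator, length: int = EXPECTED_LENGTH) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def wrap(region: str) -> str:
    return FIVE_PRIME_CONSTANT + region + THREE_PRIME_CONSTANT


class TestTrim:
    def test_construction_round_trip(self, rng):
        region = make_region(rng)
        out, reason = trim_constant_regions(wrap(region))
        assert out == region and reason is None

    def test_missing_three_prime_is_discarded(self, rng):
        out, reason = trim_constant_regions(FIVE_PRIME_CONSTANT + make_region(rng))
        assert out is None and reason == "NO_CONSTANT"

    def test_missing_five_prime_is_discarded(self, rng):
        out, reason = trim_constant_regions(make_region(rng) + THREE_PRIME_CONSTANT)
        assert out is None and reason == "NO_CONSTANT"

    def test_adjacent_constants_give_empty_discard(self):
        out, reason = trim_constant_regions(FIVE_PRIME_CONSTANT + THREE_PRIME_CONSTANT)
        assert out is None and reason == "EMPTY"

    def test_extra_flanking_sequence_is_tolerated(self, rng):
        region = make_region(rng)
        read = "GGGG" + wrap(region) + "CCCC"
        out, reason = trim_constant_regions(read)
        assert out == region


class TestClassify:
    def setup_method(self):
        rng = np.random.default_rng(77)
        self.regions = {f"v{i}": make_region(rng) for i in range(3)}

    def _classify_one(self, sequence):
        read = ReadRecord(sequence, SAMPLES[0])
        [(_, cls)] = co.classify_reads([read], self.regions)
        return cls

    def test_designed_read_is_perfect(self):
        cls = self._classify_one(wrap(self.regions["v1"]))
        assert cls.status == PERFECT and cls.reporter_id == "v1"

    def test_substitution_routes_to_imperfect_with_orf(self):
        region = self.regions["v0"]
        mutated = "A" + region[1:] if region[0] != "A" else "C" + region[1:]
        cls = self._classify_one(wrap(mutated))
        assert cls.status == IMPERFECT
        # ORF parsed from the re-attached context: starts at the constant
        # region's ATG, runs in triplets to the first stop
        orf = cls.reporter_id.removeprefix("imperfect:")
        assert orf.startswith("ATGGTGAGC")
        assert len(orf) % 3 == 0

    def test_three_nt_deletion_routes_to_imperfect_by_length(self):
        region = self.regions["v2"]
        cls = self._classify_one(wrap(region[:100] + region[103:]))
        assert cls.status == IMPERFECT

    def test_unmatched_at_expected_length_is_imperfect(self, rng):
        cls = self._classify_one(wrap(make_region(rng)))
        assert cls.status == IMPERFECT

    def test_read_without_constants_is_discarded(self, rng):
        cls = self._classify_one(make_region(rng))
        assert cls.status == "discarded" and cls.reason == "NO_CONSTANT"


class TestQuantify:
    def test_single_reporter_tpm(self):
        reads = [ReadRecord(wrap("ATG" * 99), s) for s in SAMPLES]
        m = co.quantify(co.classify_reads(reads, {"v": "ATG" * 99}))
        assert (m.tpm.loc["v"] == 1e6).all()

    def test_proportional_counts(self, rng):
        a, b = make_region(rng), make_region(rng)
        reads = [ReadRecord(wrap(a), SAMPLES[0], count=3),
                 ReadRecord(wrap(b), SAMPLES[0], count=1)]
        m = co.quantify(co.classify_reads(reads, {"A": a, "B": b}))
        col = (2.0, 1)
        assert m.tpm.loc["A", col] == pytest.approx(750_000)
        assert m.tpm.loc["B", col] == pytest.approx(250_000)

    def test_column_sums_are_one_million(self, rng):
        regions = {f"v{i}": make_region(rng) for i in range(5)}
        reads = [
            ReadRecord(wrap(r), s, count=int(rng.integers(1, 50)))
            for s in SAMPLES for r in regions.values()
        ]
        m = co.quantify(co.classify_reads(reads, regions))
        assert np.allclose(m.tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_sample_with_only_discarded_reads_is_an_error(self, rng):
        reads = [ReadRecord(wrap(make_region(rng)), SAMPLES[0]),
                 ReadRecord("ACGTACGT", SAMPLES[1])]
        with pytest.raises(ValueError, match="no quantifiable read"):
            co.quantify(co.classify_reads(reads, {}))


def toy_matrix(rows: dict[str, list[int]], sets: dict[str, str]):
    """Build an AbundanceMatrix from 9 per-sample counts per reporter."""
    import pandas as pd
    from codonopt.reporter_decay import AbundanceMatrix

    cols = pd.MultiIndex.from_tuples([(s.timepoint, s.replicate) for s in SAMPLES],
                                     names=["timepoint", "replicate"])
    counts = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    counts.columns = cols
    tpm = counts / counts.sum(axis=0) * 1e6
    return AbundanceMatrix(counts=counts, tpm=tpm, reporter_sets=sets)


class TestFilters:
    def test_every_branch_with_hand_computed_survivors(self):
        # sample order: (2,1)(2,2)(2,3)(5,1)(5,2)(5,3)(8,1)(8,2)(8,3)
        rows = {
            "p_all": [5, 5, 5, 4, 4, 4, 3, 3, 3],       # perfect, all 9 -> keep
            "p_gap": [5, 5, 5, 4, 0, 4, 3, 3, 3],       # one zero -> drop
            "i_good": [25, 30, 0, 40, 22, 0, 21, 20, 0],  # 2/3 reps, all >=20 -> keep
            "i_low": [25, 30, 0, 40, 19, 0, 21, 20, 0],   # one detected rep at 19 -> drop
            "i_onerep": [25, 0, 0, 40, 22, 0, 21, 20, 0],  # 1/3 reps at 2h -> drop
            "i_full": [25, 30, 35, 40, 22, 28, 21, 20, 30],  # 9/9 all >=20 -> keep
        }
        sets = {"p_all": "perfect", "p_gap": "perfect",
                "i_good": "imperfect", "i_low": "imperfect",
                "i_onerep": "imperfect", "i_full": "imperfect"}
        m = toy_matrix(rows, sets)
        assert co.filter_detected(m, "perfect") == ["p_all"]
        assert sorted(co.filter_detected(m, "imperfect")) == ["i_full", "i_good"]

    def test_surviving_imperfect_has_six_points(self):
        rows = {"i_good": [25, 30, 0, 40, 22, 0, 21, 20, 0]}
        m = toy_matrix(rows, {"i_good": "imperfect"})
        assert co.filter_detected(m, "imperfect") == ["i_good"]
        fits = co.fit_all(m, ["i_good"])
        assert fits["i_good"].n_points == 6

    def test_orf_length_post_filter(self):
        short = "imperfect:" + "ATG" * 70   # 70 codons -> dropped
        long = "imperfect:" + "ATG" * 71    # 71 codons -> kept
        assert co.filter_orf_length([short, long, "v1"]) == [long, "v1"]


class TestFitDecay:
    def test_constant_abundance_zero_slope(self):
        series = [(t, 500.0) for t in (2, 5, 8) for _ in range(3)]
        fit = fit_decay(series)
        assert fit.decay_rate == pytest.approx(0.0, abs=1e-12)

    def test_exact_exponential_recovery(self):
        series = [(t, 1000 * math.exp(-0.5 * t)) for t in (2, 5, 8)
                  for _ in range(3)]
        fit = fit_decay(series)
        assert fit.decay_rate == pytest.approx(-0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points == 9

    def test_poisson_noise_recovery(self, rng):
        # depth-like counts around 1e5 * exp(-0.3 t): slope within +/-0.05
        series = [
            (t, rng.poisson(1e5 * math.exp(-0.3 * t)) + 0.0)
            for t in (2, 5, 8) for _ in range(3)
        ]
        fit = fit_decay(series)
        assert fit.decay_rate == pytest.approx(-0.3, abs=0.05)

    @pytest.mark.parametrize(
        "series", [[(2, 0.0), (5, 10.0)], [(2, 5.0), (2, 6.0)]]
    )
    def test_degenerate_series_rejected(self, series):
        with pytest.raises(ValueError):
            fit_decay(series)


class TestToolWinProbability:
    @staticmethod
    def _fits(rates: dict[str, float]):
        return {k: co.DecayFit(k, v, 0.0, 1.0, 9) for k, v in rates.items()}

    def test_focal_always_best_gives_ones(self):
        fits = self._fits({"a1": 1.0, "a2": 0.9, "b1": 0.1, "b2": 0.2})
        manifest = {"a1": ("p1", "A"), "a2": ("p2", "A"),
                    "b1": ("p1", "B"), "b2": ("p2", "B")}
        res = co.tool_win_probability(fits, manifest, "A", reps=50, seed=1)
        assert res["mean"] == 1.0
        assert all(a == 1.0 for a in res["averages"])

    def test_all_ties_give_zero(self):
        fits = self._fits({"a1": 0.5, "b1": 0.5})
        manifest = {"a1": ("p1", "A"), "b1": ("p1", "B")}
        res = co.tool_win_probability(fits, manifest, "A", reps=50, seed=1)
        assert res["mean"] == 0.0

    def test_only_fully_covered_proteins_are_eligible(self):
        fits = self._fits({"a1": 1.0, "b1": 0.0, "a2": 1.0})
        manifest = {"a1": ("p1", "A"), "b1": ("p1", "B"), "a2": ("p2", "A")}
        res = co.tool_win_probability(fits, manifest, "A", reps=10, seed=0)
        assert res["n_proteins"] == 1  # p2 has no tool-B variant

    def test_no_eligible_protein_is_error(self):
        fits = self._fits({"a1": 1.0})
        manifest = {"a1": ("p1", "A"), "b1": ("p2", "B")}
        with pytest.raises(ValueError):
            co.tool_win_probability(fits, manifest, "A", reps=10, seed=0)

    def test_iid_rates_win_probability_near_half(self):
        # symmetry Monte-Carlo: i.i.d. continuous rates for two tools
        rng = np.random.default_rng(4)
        rates = {}
        manifest = {}
        for p in range(25):
            for tool in ("A", "B"):
                for k in range(8):
                    vid = f"{tool}{p}_{k}"
                    rates[vid] = float(rng.standard_normal())
                    manifest[vid] = (f"p{p}", tool)
        res = co.tool_win_probability(self._fits(rates), manifest, "A",
                                      reps=300, seed=5)
        assert all(0.0 <= a <= 1.0 for a in res["averages"])
        # 3 SE of a Bernoulli(1/2) mean over 25 proteins x 300 reps, dominated
        # by the per-dataset spread of the 25 protein-level win probabilities
        assert abs(res["mean"] - 0.5) < 3 * (0.5 / math.sqrt(25))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        rates = {f"{t}{i}": float(rng.random()) for t in "AB" for i in range(5)}
        manifest = {k: ("p1", k[0]) for k in rates}
        a = co.tool_win_probability(self._fits(rates), manifest, "A", seed=3)
        b = co.tool_win_probability(self._fits(rates), manifest, "A", seed=3)
        assert a["averages"] == b["averages"]


class TestSmallFormulas:
    def test_absorbance_identities(self):
        assert co.pigment_absorbance(100, 0, 100) == pytest.approx(0.0)
        assert co.pigment_absorbance(10, 0, 100) == pytest.approx(1.0)
        assert co.pigment_absorbance(50, 0, 100) == pytest.approx(
            -math.log10(0.5))

    def test_absorbance_errors_and_clipping(self):
        with pytest.raises(ValueError):
            co.pigment_absorbance(0, 0, 100)  # T = 0
        with pytest.raises(ValueError):
            co.pigment_absorbance(50, 100, 100)  # blanks inverted
        with pytest.warns(UserWarning, match="clipped"):
            assert co.pigment_absorbance(120, 0, 100) == 0.0

    def test_correlations_on_identical_and_reversed(self):
        fits = {f"v{i}": co.DecayFit(f"v{i}", float(i), 0, 1, 9)
                for i in range(6)}
        same = {f"v{i}": float(i) for i in range(6)}
        res = co.correlate_predictions(fits, same)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["spearman_r"] == pytest.approx(1.0)
        reverse = {f"v{i}": float(-i) for i in range(6)}
        assert co.correlate_predictions(fits, reverse)["spearman_r"] == \
            pytest.approx(-1.0)

    def test_correlation_null_is_centered(self):
        rng = np.random.default_rng(10)
        rs = []
        for _ in range(300):
            fits = {f"v{i}": co.DecayFit(f"v{i}", float(x), 0, 1, 9)
                    for i, x in enumerate(rng.standard_normal(100))}
            preds = {f"v{i}": float(x)
                     for i, x in enumerate(rng.standard_normal(100))}
            rs.append(co.correlate_predictions(fits, preds)["pearson_r"])
        assert abs(np.mean(rs)) < 0.05

    def test_too_few_pairs_is_error(self):
        fits = {"a": co.DecayFit("a", 0.1, 0, 1, 9)}
        with pytest.raises(ValueError):
            co.correlate_predictions(fits, {"a": 0.1})
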