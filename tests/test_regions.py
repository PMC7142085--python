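"""Neighborhood/control windows, paired metrics and the Wilcoxon test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from glycolocale.io_annotation import GlycoproteinRecord, Locale
from glycolocale.regions import (
    DISORDERED_CONTROL,
    ORDERED_CONTROL,
    WINDOW_LENGTH,
    eligible_control_starts,
    extract_neighborhoods,
    metric_glycosite_ordered_fraction,
    metric_residue_percent,
    metric_sequon_density,
    sample_control_windows,
    summarize_metric,
    wilcoxon_signed_rank,
)


def _rec(seq, glyco=(), intervals=()):
    return GlycoproteinRecord("p", seq, frozenset(glyco), tuple(intervals))


def _seq_with_n(length, positions):
    seq = ["A"] * length
    for p in positions:
        seq[p] = "N"
    return "".join(seq)


class TestNeighborhoods:
    def test_window_centered_on_glycosite(self):
        rec = _rec(_seq_with_n(20, [10]), glyco=[10])
        (w,) = extract_neighborhoods(rec)
        assert (w.start, len(w.residues)) == (5, WINDOW_LENGTH)
        assert w.residues[5] == "N"

    def test_terminal_glycosite_skipped(self):
        rec = _rec(_seq_with_n(20, [3]), glyco=[3])
        assert extract_neighborhoods(rec) == []

    def test_overlapping_windows_both_emitted(self):
        rec = _rec(_seq_with_n(25, [10, 12]), glyco=[10, 12])
        windows = extract_neighborhoods(rec)
        assert [w.start for w in windows] == [5, 7]

    def test_purity_records_boundary_spanning(self):
        rec = _rec(_seq_with_n(20, [10]), glyco=[10], intervals=[(13, 20)])
        (w,) = extract_neighborhoods(rec)
        assert w.center_locale is Locale.ORDERED
        assert w.locale_purity == pytest.approx(8 / 11)


class TestControlWindows:
    def test_short_disordered_run_gives_na(self):
        rec = _rec("A" * 30, intervals=[(5, 15)])  # disordered run of 10 < 11
        out = sample_control_windows(rec, np.random.default_rng(0))
        assert out[DISORDERED_CONTROL] == []
        assert len(out[ORDERED_CONTROL]) == 1  # the [15, 30) ordered run fits an 11-mer

    def test_seed_determinism(self):
        rec = _rec("A" * 30)
        w1 = sample_control_windows(rec, np.random.default_rng(42))
        w2 = sample_control_windows(rec, np.random.default_rng(42))
        assert w1 == w2
        assert len(w1[ORDERED_CONTROL]) == 1

    def test_eligible_starts_match_bruteforce(self):
        """Sampler's eligible-start set equals a brute-force scan."""
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(15, 80))
            seq = list("A" * n)
            glyco = sorted(rng.choice(n, size=int(rng.integers(0, 3)), replace=False))
            for g in glyco:
                seq[g] = "N"
            cut = sorted(rng.choice(n + 1, size=2, replace=False))
            intervals = [(int(cut[0]), int(cut[1]))] if cut[0] < cut[1] else []
            rec = _rec("".join(seq), glyco=glyco, intervals=intervals)
            for region in (Locale.ORDERED, Locale.DISORDERED):
                got = set(eligible_control_starts(rec, region).tolist())
                want = set()
                for s in range(n - WINDOW_LENGTH + 1):
                    span = range(s, s + WINDOW_LENGTH)
                    in_class = all(
                        (rec.disorder_mask[i] == (region is Locale.DISORDERED))
                        for i in span
                    )
                    clear = all(
                        abs(i - g) > 5 for i in span for g in glyco
                    ) if glyco else True
                    if in_class and clear:
                        want.add(s)
                assert got == want

    def test_controls_never_touch_neighborhoods(self, small_cohort, rng):
        for rec in small_cohort.records:
            hoods = {
                i
                for w in extract_neighborhoods(rec)
                for i in range(w.start, w.start + WINDOW_LENGTH)
            }
            controls = sample_control_windows(rec, rng)
            for kind in (ORDERED_CONTROL, DISORDERED_CONTROL):
                for w in controls[kind]:
                    span = set(range(w.start, w.start + WINDOW_LENGTH))
                    assert not span & hoods
                    assert not span & rec.glycosites


class TestMetrics:
    def test_glycosite_ordered_fraction(self):
        rec = _rec(_seq_with_n(30, [2, 10, 20]), glyco=[2, 10, 20],
                   intervals=[(18, 25)])
        assert metric_glycosite_ordered_fraction(rec) == pytest.approx(2 / 3)

    def test_fraction_nan_without_glycosites(self):
        assert np.isnan(metric_glycosite_ordered_fraction(_rec("AAAA")))

    def test_fractions_sum_to_one(self, small_cohort):
        for rec in small_cohort.records:
            f = metric_glycosite_ordered_fraction(rec)
            assert 0.0 <= f <= 1.0

    def test_residue_percent(self):
        rec = _rec("NNSA")
        assert metric_residue_percent(rec, {"N"}, Locale.ORDERED) == 50.0
        assert metric_residue_percent(rec, {"S", "T"}, Locale.ORDERED) == 25.0
        assert np.isnan(metric_residue_percent(rec, {"N"}, Locale.DISORDERED))

    def test_sequon_density(self):
        seq = "NGS" + "A" * 94 + "NGT"
        rec = _rec(seq)
        assert metric_sequon_density(rec, Locale.ORDERED) == pytest.approx(2.0)
        assert np.isnan(metric_sequon_density(rec, Locale.DISORDERED))


def _enumeration_p(diffs):
    """Full 2^n sign enumeration of the exact two-sided signed-rank p."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, keep in zip(ranks, signs) if keep)
        for signs in itertools.product([False, True], repeat=n)
    ]
    sums = np.array(sums)
    p_le = np.mean(sums <= w_obs)
    p_ge = np.mean(sums >= w_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_six_positive_distinct_pairs(self):
        pairs = [(i + 1.0, 0.0) for i in range(6)]
        res = wilcoxon_signed_rank(pairs)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(2 / 64)

    def test_all_equal_pairs_is_na(self):
        res = wilcoxon_signed_rank([(1.0, 1.0), (2.0, 2.0)])
        assert res.method == "na"
        assert res.n_effective == 0

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([(1, 2), (3, 1), (5, 5)])
        assert res.n_effective == 2
        assert res.n_dropped_zero == 1
        assert res.statistic == 2.0  # |2| outranks |-1|
        assert res.p_two_sided == pytest.approx(_enumeration_p([-1, 2]))

    def test_na_pairs_dropped(self):
        res = wilcoxon_signed_rank([(1, 2), (np.nan, 1), (4, 1)])
        assert res.n_dropped_na == 1
        assert res.n_effective == 2

    @pytest.mark.parametrize("n", range(2, 11))
    def test_exact_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            res = wilcoxon_signed_rank(np.column_stack([a, b]))
            assert res.method == "exact"
            assert res.p_two_sided == pytest.approx(_enumeration_p(a - b))

    def test_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        for n in (5, 8, 12, 20):
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(np.column_stack([d, np.zeros(n)]))
            ref = stats.wilcoxon(d, method="exact").pvalue
            assert res.p_two_sided == pytest.approx(float(ref))

    def test_ties_fall_back_to_normal_approx(self):
        pairs = [(2.0, 1.0)] * 30
        res = wilcoxon_signed_rank(pairs)
        assert res.method == "normal_approx"
        assert res.p_two_sided < 1e-4


class TestSummarize:
    def test_closed_form(self):
        mean, median, sem = summarize_metric([1.0, 2.0, 3.0])
        assert (mean, median) == (2.0, 2.0)
        assert sem == pytest.approx(1 / np.sqrt(3))

    def test_single_value_sem_na(self):
        mean, _, sem = summarize_metric([5.0])
        assert mean == 5.0 and np.isnan(sem)

    def test_na_aware(self):
        mean, _, _ = summarize_metric([1.0, np.nan, 3.0])
        assert mean == 2.0

    def test_all_na(self):
        assert all(np.isnan(v) for v in summarize_metric([np.nan]))
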