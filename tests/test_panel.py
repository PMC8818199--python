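"""Youden thresholds, believe-the-positive calls and exact binomial CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methylpanel.panel import (
    INDETERMINATE,
    NEGATIVE,
    POSITIVE,
    PanelModel,
    classify,
    fit_panel,
    panel_score,
    performance,
    youden_threshold,
)
from methylpanel.qmsp import MULTIPLEX_MAP, MethylationProfile


def _profile(ghsr=None, mal=None, ghsr_valid=True, mal_valid=True, sid="s"):
    prof = MethylationProfile(sample_id=sid)
    prof.ratios["GHSR"] = ghsr if ghsr_valid else None
    prof.valid["GHSR"] = ghsr_valid
    prof.ratios["MAL"] = mal if mal_valid else None
    prof.valid["MAL"] = mal_valid
    return prof


def _brute_force_youden(scores, labels):
    """Exhaustive search over all candidate cuts; returns max J."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    distinct = np.unique(scores)
    cuts = np.concatenate(
        [[distinct[0] - 1], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1] + 1]]
    )
    best = -2.0
    for c in cuts:
        sens = (scores[labels] >= c).mean()
        spec = (scores[~labels] < c).mean()
        best = max(best, sens + spec - 1.0)
    return best


def _j_at(scores, labels, threshold):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    sens = (scores[labels] >= threshold).mean()
    spec = (scores[~labels] < threshold).mean()
    return sens + spec - 1.0


class TestYoudenThreshold:
    def test_worked_example_with_tie_break(self):
        # cuts 2.5 and 3.5 both reach J = 2/3 with equal specificity;
        # the larger threshold wins
        thr = youden_threshold([5, 6, 7, 1, 2, 6], [1, 1, 1, 0, 0, 0])
        assert thr == pytest.approx(3.5)
        assert _j_at([5, 6, 7, 1, 2, 6], [1, 1, 1, 0, 0, 0], thr) == pytest.approx(2 / 3)

    def test_perfect_separation_midpoint(self):
        thr = youden_threshold([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert thr == pytest.approx(6.5)
        assert _j_at([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0], thr) == 1.0

    def test_specificity_tie_break(self):
        # interleaved groups: J ties at 0 across several cuts; the
        # specificity-favouring cut (everything negative) is chosen
        scores = [1.0, 3.0, 2.0, 4.0]
        labels = [1, 1, 0, 0]
        thr = youden_threshold(scores, labels)
        spec = (np.array(scores)[2:] < thr).mean()
        assert spec == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            youden_threshold([1, 2], [True, True])

    @given(
        cases=st.lists(st.integers(0, 10).map(float), min_size=1, max_size=10),
        controls=st.lists(st.integers(0, 10).map(float), min_size=1, max_size=10),
    )
    @settings(max_examples=150, deadline=None)
    def test_attains_exhaustive_maximum(self, cases, controls):
        scores = cases + controls
        labels = [True] * len(cases) + [False] * len(controls)
        thr = youden_threshold(scores, labels)
        assert _j_at(scores, labels, thr) == pytest.approx(
            _brute_force_youden(scores, labels), abs=1e-12
        )

    @given(
        cases=st.lists(st.integers(0, 10).map(float), min_size=1, max_size=8),
        controls=st.lists(st.integers(0, 10).map(float), min_size=1, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_flipped_orientation_attains_its_own_maximum(self, cases, controls):
        # swapping the class labels, the derived cut still maximizes J for
        # the swapped problem (orientation is a property of the labels)
        scores = cases + controls
        flipped = [False] * len(cases) + [True] * len(controls)
        thr = youden_threshold(scores, flipped)
        assert _j_at(scores, flipped, thr) == pytest.approx(
            _brute_force_youden(scores, flipped), abs=1e-12
        )


class TestClassify:
    MODEL = PanelModel(thresholds={"GHSR": 1.0, "MAL": 2.0})

    @pytest.mark.parametrize(
        "ghsr,mal,expected",
        [
            (5.0, 0.1, POSITIVE),  # GHSR positive alone suffices
            (0.1, 5.0, POSITIVE),
            (0.1, 0.1, NEGATIVE),
            (1.0, 0.1, POSITIVE),  # boundary counts positive
        ],
    )
    def test_or_rule(self, ghsr, mal, expected):
        assert classify(_profile(ghsr=ghsr, mal=mal), self.MODEL) == expected

    def test_invalid_marker_with_valid_positive_is_positive(self):
        prof = _profile(mal=5.0, ghsr_valid=False)
        assert classify(prof, self.MODEL) == POSITIVE

    def test_invalid_marker_with_valid_negative_is_indeterminate(self):
        prof = _profile(mal=0.1, ghsr_valid=False)
        assert classify(prof, self.MODEL) == INDETERMINATE

    def test_all_invalid_is_indeterminate(self):
        prof = _profile(ghsr_valid=False, mal_valid=False)
        assert classify(prof, self.MODEL) == INDETERMINATE


class TestPanelScore:
    MODEL = PanelModel(thresholds={"GHSR": 1.0, "MAL": 2.0})

    def test_zero_at_threshold(self):
        assert panel_score(_profile(ghsr=1.0, mal=2.0), self.MODEL) == pytest.approx(0.0)

    def test_max_rule_dominated_by_strong_marker(self):
        high = panel_score(_profile(ghsr=100.0, mal=0.001), self.MODEL)
        assert high > 5.0

    def test_sign_agrees_with_call(self, rng):
        for _ in range(200):
            ghsr, mal = rng.uniform(0, 4, 2)
            prof = _profile(ghsr=ghsr, mal=mal)
            call = classify(prof, self.MODEL)
            score = panel_score(prof, self.MODEL)
            assert (score >= 0) == (call == POSITIVE)

    def test_missing_when_no_valid_marker(self):
        assert panel_score(_profile(ghsr_valid=False, mal_valid=False), self.MODEL) is None


class TestPerformance:
    def test_all_positive_cases_closed_form(self):
        calls = [POSITIVE] * 23 + [NEGATIVE] * 10
        labels = [True] * 23 + [False] * 10
        perf = performance(calls, labels)
        assert perf.sensitivity == 1.0
        assert perf.sensitivity_ci[0] == pytest.approx(0.025 ** (1 / 23), abs=1e-9)
        assert perf.sensitivity_ci[1] == 1.0

    def test_zero_positive_symmetry(self):
        calls = [NEGATIVE] * 15 + [NEGATIVE] * 5
        labels = [True] * 15 + [False] * 5
        perf = performance(calls, labels)
        assert perf.sensitivity == 0.0
        assert perf.sensitivity_ci[1] == pytest.approx(1 - 0.025 ** (1 / 15), abs=1e-9)

    def test_published_scale_example(self):
        from methylpanel.pipeline import round_half_up

        calls = [POSITIVE] * 86 + [NEGATIVE] * 22 + [NEGATIVE] * 93 + [POSITIVE] * 7
        labels = [True] * 108 + [False] * 100
        perf = performance(calls, labels)
        assert perf.sensitivity == pytest.approx(86 / 108)
        assert round_half_up(perf.sensitivity, 2) == 0.80
        assert perf.specificity == pytest.approx(0.93)

    def test_indeterminate_excluded_and_counted(self):
        calls = [POSITIVE, INDETERMINATE, NEGATIVE, NEGATIVE]
        labels = [True, True, False, False]
        perf = performance(calls, labels)
        assert perf.n_indeterminate == 1
        assert perf.tp + perf.fn == 1

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            performance([POSITIVE, POSITIVE], [True, True])

    @pytest.mark.parametrize("p", [0.6, 0.95])
    @pytest.mark.parametrize("n", [23, 108])
    def test_clopper_pearson_coverage(self, p, n):
        # exact intervals are conservative: coverage >= nominal
        rng = np.random.default_rng(1000 + n)
        xs = rng.binomial(n, p, size=500)
        lo = np.where(xs > 0, stats.beta.ppf(0.025, xs, n - xs + 1), 0.0)
        hi = np.where(xs < n, stats.beta.ppf(0.975, xs + 1, n - xs), 1.0)
        coverage = np.mean((lo <= p) & (p <= hi))
        assert coverage >= 0.94


class TestDominance:
    def test_panel_dominates_members(self, clean_cohort):
        # believe-the-positive: sens >= each marker, spec <= each marker
        profiles, clinical = clean_cohort
        labels = dict(zip(clinical["sample_id"], clinical["group"] == "case"))
        model = fit_panel(profiles, labels)
        is_case = np.array([labels[p.sample_id] for p in profiles])
        marker_pos = {
            m: np.array([p.ratio(m) >= model.thresholds[m] for p in profiles])
            for m in model.markers
        }
        panel_pos = np.array([classify(p, model) == POSITIVE for p in profiles])
        for m in model.markers:
            assert panel_pos[is_case].mean() >= marker_pos[m][is_case].mean()
            assert (~panel_pos[~is_case]).mean() <= (~marker_pos[m][~is_case]).mean()


class TestPanelModelSerialization:
    def test_json_round_trip(self, tmp_path):
        model = PanelModel(thresholds={"GHSR": 0.5, "MAL": 1.25}, derivation_stratum="male")
        path = tmp_path / "panel.json"
        model.to_json(path)
        loaded = PanelModel.from_json(path)
        assert loaded.markers == model.markers
        assert loaded.thresholds == model.thresholds
        assert loaded.derivation_stratum == "male"

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            PanelModel(thresholds={"GHSR": float("inf"), "MAL": 1.0})
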