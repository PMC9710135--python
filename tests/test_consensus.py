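"""The Δβ consensus caller: arithmetic, counting, properties, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_calls
from dietmeth.consensus import (
    DeltaCallParams,
    call_sites,
    compute_delta,
    min_patients,
    subset_median_profile,
    subset_variance_test,
)


def _cohort_frame(samples: dict[str, list[float]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    betas = pd.DataFrame(samples, index=pd.Index(["cg1"], name="probe_id"))
    sheet = pd.DataFrame(
        [
            dict(sample_id=sid, patient_id=sid.split("_")[0], timepoint=sid.split("_")[1],
                 group="study", tissue="blood", fibrosis_grade=np.nan)
            for sid in samples
        ]
    )
    return betas, sheet


class TestComputeDelta:
    def test_mean_post_minus_baseline(self):
        betas, sheet = _cohort_frame({"P1_T1": [0.2], "P1_T2": [0.5], "P1_T3": [0.7]})
        delta = compute_delta(betas, sheet)
        assert delta.loc["cg1", "P1"] == pytest.approx(0.4)

    def test_identity_when_flat(self):
        betas, sheet = _cohort_frame({"P1_T1": [0.5], "P1_T2": [0.5], "P1_T3": [0.5]})
        assert compute_delta(betas, sheet).loc["cg1", "P1"] == pytest.approx(0.0)

    def test_single_post_timepoint_fallback(self):
        betas, sheet = _cohort_frame({"P1_T1": [0.9], "P1_T2": [0.6]})
        assert compute_delta(betas, sheet).loc["cg1", "P1"] == pytest.approx(-0.3)

    def test_missing_baseline_is_error(self):
        betas, sheet = _cohort_frame({"P1_T2": [0.6], "P1_T3": [0.7]})
        with pytest.raises(ValueError, match="T1"):
            compute_delta(betas, sheet)

    def test_missing_all_post_is_error(self):
        betas, sheet = _cohort_frame({"P1_T1": [0.6]})
        with pytest.raises(ValueError, match="T2 nor a T3"):
            compute_delta(betas, sheet)

    def test_probe_level_missing_post_uses_available(self):
        betas, sheet = _cohort_frame({"P1_T1": [0.2], "P1_T2": [np.nan], "P1_T3": [0.6]})
        assert compute_delta(betas, sheet).loc["cg1", "P1"] == pytest.approx(0.4)


@pytest.mark.parametrize(
    "n, fraction, expected",
    [(18, 0.77, 14), (4, 0.77, 4), (1, 0.77, 1), (20, 0.5, 10), (30, 0.1, 3)],
)
def test_min_patients_ceiling(n, fraction, expected):
    assert min_patients(n, fraction) == expected


class TestCallSites:
    def _delta(self, values: list[float]) -> pd.DataFrame:
        return pd.DataFrame(
            [values], index=pd.Index(["cg1"], name="probe_id"),
            columns=[f"P{i}" for i in range(len(values))],
        )

    def test_consensus_reached_at_14_of_18(self):
        delta = self._delta([0.15] * 14 + [0.0] * 4)
        assert call_sites(delta).call["cg1"] == "hyper"

    def test_consensus_missed_at_13_of_18(self):
        delta = self._delta([0.15] * 13 + [0.0] * 5)
        assert call_sites(delta).call["cg1"] == "none"

    def test_unanimous_hypomethylation(self):
        delta = self._delta([-0.2] * 18)
        res = call_sites(delta)
        assert res.call["cg1"] == "hypo"
        assert res.hypo_count["cg1"] == 18

    def test_missing_patients_shrink_denominator(self):
        # 11 of 14 evaluable passes (bar 11); the 4 NaN patients do not count against
        delta = self._delta([0.15] * 11 + [0.0] * 3 + [np.nan] * 4)
        res = call_sites(delta)
        assert res.n_eval["cg1"] == 14
        assert res.call["cg1"] == "hyper"

    def test_majority_sign_mode_and_tie(self):
        params = DeltaCallParams(
            delta_threshold=0.1, consensus_fraction=0.77,
            require_direction_consistency=False,
        )
        mixed = self._delta([0.15] * 9 + [-0.15] * 5 + [0.0] * 4)
        assert call_sites(mixed, params).call["cg1"] == "hyper"
        tied = self._delta([0.15] * 7 + [-0.15] * 7 + [0.0] * 4)
        assert call_sites(tied, params).call["cg1"] == "none"
        # strict mode: neither direction reaches 14 on its own
        assert call_sites(mixed).call["cg1"] == "none"


@st.composite
def delta_matrices(draw):
    n_probes = draw(st.integers(1, 12))
    n_patients = draw(st.integers(1, 10))
    values = draw(
        st.lists(
            st.lists(
                st.one_of(st.floats(-0.5, 0.5), st.just(np.nan)),
                min_size=n_patients, max_size=n_patients,
            ),
            min_size=n_probes, max_size=n_probes,
        )
    )
    return pd.DataFrame(
        values, index=[f"cg{i}" for i in range(n_probes)],
        columns=[f"P{j}" for j in range(n_patients)],
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(delta=delta_matrices(), thr=st.floats(0.05, 0.4), frac=st.floats(0.55, 1.0))
def test_caller_matches_brute_force_oracle(delta, thr, frac):
    params = DeltaCallParams(delta_threshold=thr, consensus_fraction=frac)
    assert list(call_sites(delta, params).call) == brute_force_calls(delta, thr, frac)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(delta=delta_matrices())
def test_negating_delta_swaps_directions(delta):
    res = call_sites(delta)
    neg = call_sites(-delta)
    assert (res.hyper_count == neg.hypo_count).all()
    assert (res.hypo_count == neg.hyper_count).all()
    swap = {"hyper": "hypo", "hypo": "hyper", "none": "none"}
    assert list(neg.call) == [swap[c] for c in res.call]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    delta=delta_matrices(),
    thr=st.floats(0.05, 0.3),
    bump_thr=st.floats(0.0, 0.2),
    frac=st.floats(0.55, 0.9),
    bump_frac=st.floats(0.0, 0.1),
)
def test_raising_thresholds_never_adds_calls(delta, thr, bump_thr, frac, bump_frac):
    lax = call_sites(delta, DeltaCallParams(delta_threshold=thr, consensus_fraction=frac))
    strict = call_sites(
        delta,
        DeltaCallParams(delta_threshold=thr + bump_thr, consensus_fraction=frac + bump_frac),
    )
    assert len(strict.called_subset) <= len(lax.called_subset)


def test_never_called_in_both_directions(cohort):
    betas, sheet, _, _ = cohort
    res = call_sites(compute_delta(betas, sheet))
    assert not ((res.hyper_count >= 14) & (res.hypo_count >= 14)).any()
    assert set(res.call) <= {"hyper", "hypo", "none"}


def test_planted_recovery_on_small_cohort(cohort):
    betas, sheet, _, truth = cohort
    res = call_sites(compute_delta(betas, sheet))
    called = set(res.called_subset)
    planted = set(truth.planted)
    sensitivity = len(called & planted) / len(planted)
    fpr = len(called - planted) / (betas.shape[0] - len(planted))
    assert sensitivity >= 0.95
    assert fpr <= 0.01
    for probe in called & set(truth.planted_hyper):
        assert res.call[probe] == "hyper"
    for probe in called & set(truth.planted_hypo):
        assert res.call[probe] == "hypo"


class TestSubsetSummaries:
    def test_constant_matrix_medians(self, cohort):
        betas, sheet, _, _ = cohort
        const = betas.copy()
        const.iloc[:, :] = 0.5
        medians = subset_median_profile(const, betas.index[:10], sheet)
        assert (medians == 0.5).all()

    def test_two_probe_median(self):
        betas, sheet = _cohort_frame({"P1_T1": [0.2]})
        betas.loc["cg2"] = 0.4
        med = subset_median_profile(betas, ["cg1", "cg2"], sheet)
        assert med["T1"] == pytest.approx(0.3)

    def test_post_diet_medians_track_healthy(self, cohort):
        betas, sheet, _, truth = cohort
        med = subset_median_profile(betas, truth.planted_hyper, sheet)
        healthy = med["healthy_blood"]
        assert abs(med["T2"] - healthy) < abs(med["T1"] - healthy)
        assert abs(med["T3"] - healthy) < abs(med["T1"] - healthy)

    def test_empty_subset_is_error(self, cohort):
        betas, sheet, _, _ = cohort
        with pytest.raises(ValueError, match="empty"):
            subset_median_profile(betas, [], sheet)

    def test_variance_identical_groups(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.3, 0.7, size=20)
        samples = {}
        rows = []
        for tp in ("T1", "T2"):
            for i in range(20):
                sid = f"P{i}_{tp}"
                samples[sid] = [vals[i]]
                rows.append(dict(sample_id=sid, patient_id=f"P{i}", timepoint=tp,
                                 group="study", tissue="blood", fibrosis_grade=np.nan))
        betas = pd.DataFrame(samples, index=pd.Index(["cg1"], name="probe_id"))
        out = subset_variance_test(betas, ["cg1"], pd.DataFrame(rows))
        assert out.loc["T2", "p_vs_reference"] > 0.9
        assert out.loc["T1", "variance"] == pytest.approx(out.loc["T2", "variance"])

    def test_tenfold_spread_detected(self):
        rng = np.random.default_rng(1)
        wide = 0.5 + rng.normal(0, 0.10, size=20)
        tight = 0.5 + rng.normal(0, 0.01, size=20)
        samples, rows = {}, []
        for tp, vals in (("T1", wide), ("T2", tight)):
            for i, v in enumerate(vals):
                sid = f"P{i}_{tp}"
                samples[sid] = [float(np.clip(v, 0, 1))]
                rows.append(dict(sample_id=sid, patient_id=f"P{i}", timepoint=tp,
                                 group="study", tissue="blood", fibrosis_grade=np.nan))
        betas = pd.DataFrame(samples, index=pd.Index(["cg1"], name="probe_id"))
        out = subset_variance_test(betas, ["cg1"], pd.DataFrame(rows))
        assert out.loc["T2", "p_vs_reference"] < 0.05
        assert out.loc["T1", "variance"] > out.loc["T2", "variance"]

    def test_baseline_variance_exceeds_post_diet(self, cohort):
        # heterogeneity at T1 is the design motivation for the consensus caller
        betas, sheet, _, truth = cohort
        out = subset_variance_test(betas, truth.planted, sheet)
        assert out.loc["T1", "variance"] > out.loc["T2", "variance"]
        assert out.loc["T1", "variance"] > out.loc["healthy_blood", "variance"]
        assert out.loc["healthy_blood", "p_vs_reference"] < 0.05
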