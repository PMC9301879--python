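"""Baseline-coded errors, VE/VAEi/VAEc, precision and group-level tests."""

import numpy as np
import pandas as pd
import pytest

from ventriloquo.design import bin_responses, generate_block1, generate_block2
from ventriloquo.effects import (
    cumulative_aftereffect,
    effect_summary,
    group_tests,
    immediate_aftereffect,
    localization_errors,
    unimodal_precision,
    ventriloquism_effect,
)


def _toy_table():
    """Minimal participant: one unimodal baseline trial per cell, then probes."""
    rows = []
    idx = 0
    # Block 1 baselines: A responses one button right of the speaker button,
    # V responses exactly on it.
    for loc, btn in [(-15, 2), (-5, 5), (5, 8), (15, 11)]:
        rows.append(dict(block=1, trial_index=idx, modality="A", s_A=loc,
                         s_V=np.nan, resp_A=btn + 1, resp_V=np.nan)); idx += 1
        rows.append(dict(block=1, trial_index=idx, modality="V", s_A=np.nan,
                         s_V=loc, resp_A=np.nan, resp_V=btn)); idx += 1
    # probe AV trial: A response at its own baseline, V one button left of baseline
    rows.append(dict(block=1, trial_index=idx, modality="AV", s_A=-5, s_V=5,
                     resp_A=6, resp_V=7)); idx += 1
    # Block 2 unimodal probe: A at baseline + 2 buttons
    rows.append(dict(block=2, trial_index=idx, modality="A", s_A=5,
                     s_V=np.nan, resp_A=11, resp_V=np.nan))
    frame = pd.DataFrame(rows)
    frame["response_order"] = "A-first"
    frame["participant"] = "toy"
    frame["group"] = "SC"
    return frame


class TestLocalizationErrors:
    def test_toy_table_hand_computation(self):
        err = localization_errors(_toy_table())
        av = err[err["modality"] == "AV"]
        a_err = av[av["response_modality"] == "A"]["error_deg"].iloc[0]
        v_err = av[av["response_modality"] == "V"]["error_deg"].iloc[0]
        assert a_err == pytest.approx(0.0)  # resp 6 == baseline 6 at -5°
        assert v_err == pytest.approx(-10.0 / 3.0)  # one button left of baseline 8
        b2 = err[err["block"] == 2]
        assert b2["error_deg"].iloc[0] == pytest.approx(2 * 10.0 / 3.0)

    def test_baseline_zeroes_unimodal_block1_errors(self):
        err = localization_errors(_toy_table())
        uni = err[(err["block"] == 1) & (err["modality"] != "AV")]
        assert np.allclose(uni["error_deg"], 0.0)

    def test_missing_baseline_cell_is_reported(self):
        frame = _toy_table()
        frame = frame[~((frame["modality"] == "A") & (frame["s_A"] == -15))]
        with pytest.raises(ValueError, match="-15"):
            localization_errors(frame)


def _capture_dataset(mode: str) -> pd.DataFrame:
    """Block 1+2 data with deterministic response rules for capture scenarios."""
    b1 = generate_block1(seed=5)
    b2 = generate_block2(seed=6)
    frames = []
    for seq in (b1, b2):
        f = seq.to_frame()
        aligned_A = bin_responses(f["s_A"].fillna(0.0).to_numpy())
        aligned_V = bin_responses(f["s_V"].fillna(0.0).to_numpy())
        f["resp_A"] = aligned_A
        f["resp_V"] = aligned_V
        av = f["modality"] == "AV"
        if mode == "visual_capture":
            f.loc[av, "resp_A"] = aligned_V[av]
        elif mode == "auditory_capture":
            f.loc[av, "resp_V"] = aligned_A[av]
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["participant"] = "cap"
    out["group"] = "SC"
    return out


class TestVentriloquismEffect:
    def test_unbiased_responses_give_zero(self):
        err = localization_errors(_capture_dataset("none"))
        ve_a, ve_v = ventriloquism_effect(err)
        assert ve_a == pytest.approx(0.0)
        assert ve_v == pytest.approx(0.0)

    def test_full_visual_capture(self):
        # mean rightward discrepancy on Block 1 is (30·10+20·20+10·30)/60 = 16.67°;
        # the right-minus-left contrast doubles it
        err = localization_errors(_capture_dataset("visual_capture"))
        ve_a, _ = ventriloquism_effect(err)
        assert ve_a == pytest.approx(100.0 / 3.0, abs=1e-9)

    def test_full_auditory_capture_mirrors(self):
        err = localization_errors(_capture_dataset("auditory_capture"))
        _, ve_v = ventriloquism_effect(err)
        assert ve_v == pytest.approx(-100.0 / 3.0, abs=1e-9)


class TestAftereffects:
    def test_history_independent_errors_give_zero_vaei(self):
        err = localization_errors(_capture_dataset("none"))
        vaei_a, vaei_v = immediate_aftereffect(err)
        assert vaei_a == pytest.approx(0.0)
        assert vaei_v == pytest.approx(0.0)

    def test_condition_cells_have_eight_trials(self):
        err = localization_errors(_capture_dataset("none"))
        uni = err[(err["block"] == 1) & (err["modality"] != "AV")]
        cells = uni.groupby(["response_modality", "preceding_disc"]).size()
        assert (cells == 8).all()
        assert len(cells) == 10

    def test_planted_immediate_shift_recovered(self):
        frame = _capture_dataset("none")
        err = localization_errors(frame)
        # plant: shift unimodal A responses by +2° after rightward discrepancies
        uni_a = (
            (err["block"] == 1)
            & (err["modality"] == "A")
            & (err["preceding_disc"] > 0)
        )
        err.loc[uni_a, "error_deg"] += 2.0
        vaei_a, _ = immediate_aftereffect(err)
        assert vaei_a == pytest.approx(2.0)

    def test_planted_cumulative_shifts_recovered(self):
        frame = _capture_dataset("none")
        err = localization_errors(frame)
        err.loc[(err["block"] == 2) & (err["modality"] == "A"), "error_deg"] += 4.0
        err.loc[(err["block"] == 2) & (err["modality"] == "V"), "error_deg"] -= 2.0
        vaec_a, vaec_v = cumulative_aftereffect(err)
        assert vaec_a == pytest.approx(4.0)
        assert vaec_v == pytest.approx(-2.0)


class TestInvariances:
    def test_constant_response_shift_cancels(self, sc_frame):
        base = effect_summary(sc_frame)
        shifted = sc_frame.copy()
        for col in ("resp_A", "resp_V"):
            shifted[col] = np.clip(shifted[col] + 1, 1, 12)
        # avoid clipping artifacts: only compare when no response hit the rails
        if (shifted[["resp_A", "resp_V"]].max().max() < 12):
            moved = effect_summary(shifted)
            for key in ("VE_A", "VE_V", "VAEi_A", "VAEi_V", "VAEc_A", "VAEc_V"):
                assert moved[key] == pytest.approx(base[key], abs=1e-9)

    def test_mirror_reflection_symmetry(self, sc_frame):
        """Mirroring stimuli and responses about 0° flips the cumulative
        aftereffect (a plain mean error) but leaves the right-minus-left
        contrasts unchanged: under reflection both the errors and the
        discrepancy labels flip, so 'attraction toward V' keeps its sign."""
        base = effect_summary(sc_frame)
        mirrored = sc_frame.copy()
        mirrored["s_A"] = -mirrored["s_A"]
        mirrored["s_V"] = -mirrored["s_V"]
        mirrored["resp_A"] = 13 - mirrored["resp_A"]
        mirrored["resp_V"] = 13 - mirrored["resp_V"]
        flipped = effect_summary(mirrored)
        for key in ("VAEc_A", "VAEc_V"):
            assert flipped[key] == pytest.approx(-base[key], abs=1e-9)
        for key in ("VE_A", "VE_V", "VAEi_A", "VAEi_V"):
            assert flipped[key] == pytest.approx(base[key], abs=1e-9)
        assert flipped["SD_A"] == pytest.approx(base["SD_A"])


class TestPrecision:
    def test_zero_for_constant_responses(self):
        err = localization_errors(_capture_dataset("none"))
        sd_a, sd_v = unimodal_precision(err)
        assert sd_a == 0.0 and sd_v == 0.0

    def test_sampling_scale(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(50):
            frame = _capture_dataset("none")
            uni_a = (frame["modality"] == "A") & (frame["block"] == 1)
            draws = rng.normal(frame.loc[uni_a, "s_A"], 2.0)
            frame.loc[uni_a, "resp_A"] = bin_responses(draws)
            sd_a, _ = unimodal_precision(localization_errors(frame))
            hits += 1.4 <= sd_a <= 2.8
        assert hits >= 45


class TestGroupTests:
    @staticmethod
    def _summaries(rng, group_specs):
        rows = []
        for group, n, mean, sd in group_specs:
            for i in range(n):
                eff = rng.normal(mean, sd)
                rows.append(
                    {"participant": f"{group}{i}", "group": group,
                     "VE_A": eff, "VE_V": eff / 2, "VAEi_A": eff / 3,
                     "VAEi_V": eff / 4, "VAEc_A": eff / 5, "VAEc_V": eff / 6,
                     "SD_A": 5.0, "SD_V": 2.0}
                )
        return pd.DataFrame(rows)

    def test_identical_groups_give_near_zero_f(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(2.0, 1.0, size=10)
        rows = []
        for group in ("CC", "DC", "SC"):
            for i, eff in enumerate(vals):
                rows.append(
                    {"participant": f"{group}{i}", "group": group,
                     "VE_A": eff, "VE_V": eff, "VAEi_A": eff, "VAEi_V": eff,
                     "VAEc_A": eff, "VAEc_V": eff, "SD_A": 5.0, "SD_V": 2.0}
                )
        report = group_tests(pd.DataFrame(rows))
        assert (report.welch["F"].abs() < 1e-10).all()
        assert (report.games_howell["p"] > 0.9).all()

    def test_welch_f_matches_hand_formula(self):
        rng = np.random.default_rng(2)
        summaries = self._summaries(
            rng, [("CC", 11, 0.0, 1.0), ("DC", 10, 1.0, 3.0), ("SC", 10, 2.0, 0.5)]
        )
        report = group_tests(summaries)
        row = report.welch[report.welch["effect"] == "VE_A"].iloc[0]

        # independent hand computation of Welch's heteroscedastic F
        groups = [g["VE_A"].to_numpy() for _, g in summaries.groupby("group")]
        w = np.array([len(g) / g.var(ddof=1) for g in groups])
        means = np.array([g.mean() for g in groups])
        k = len(groups)
        xbar = np.sum(w * means) / np.sum(w)
        num = np.sum(w * (means - xbar) ** 2) / (k - 1)
        lam = np.array(
            [(1 - wi / w.sum()) ** 2 / (len(g) - 1) for wi, g in zip(w, groups)]
        )
        den = 1 + 2 * (k - 2) / (k**2 - 1) * lam.sum()
        f_hand = num / den
        df2_hand = (k**2 - 1) / (3 * lam.sum())
        assert row["F"] == pytest.approx(f_hand, rel=1e-6)
        assert row["df2"] == pytest.approx(df2_hand, rel=1e-6)

    def test_one_sample_tests_detect_positive_effects(self):
        rng = np.random.default_rng(3)
        summaries = self._summaries(
            rng, [("CC", 11, 5.0, 1.0), ("DC", 10, 5.0, 1.0), ("SC", 10, 5.0, 1.0)]
        )
        report = group_tests(summaries)
        ve = report.one_sample[report.one_sample["effect_type"] == "VE"]
        assert (ve["p_holm"] < 0.01).all()

    def test_spearman_perfect_monotone(self):
        rng = np.random.default_rng(4)
        summaries = self._summaries(
            rng, [("CC", 8, 0.0, 2.0), ("DC", 8, 1.0, 2.0)]
        )
        # effects are exact multiples of each other -> rho = 1
        report = group_tests(summaries)
        overall = report.spearman[report.spearman["scope"] == "overall"]
        assert np.allclose(overall["rho"], 1.0)

    def test_small_group_excluded(self):
        rng = np.random.default_rng(5)
        summaries = self._summaries(
            rng, [("CC", 8, 0.0, 1.0), ("DC", 8, 1.0, 1.0), ("XX", 1, 0.0, 1.0)]
        )
        report = group_tests(summaries)
        assert report.excluded_groups == ["XX"]
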