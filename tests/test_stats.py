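"""EF composite, mixed ANOVA, t-family with Levene gate, correlations."""

import numpy as np
import pandas as pd
import pytest

from metaconf import (correlation, ef_composite, mixed_anova, one_sample_t,
                      t_compare)


def hand_mixed_anova(data, dv, within, subject, between):
    """Independent oracle: classical sums-of-squares decomposition of a
    balanced 2 (between) x 2 (within) mixed design."""
    y = data[dv].to_numpy(float)
    grand = y.mean()
    k = data[within].nunique()
    subj_means = data.groupby(subject)[dv].mean()
    n_subj = len(subj_means)
    groups = data.groupby(subject)[between].first()
    ss_subjects = k * ((subj_means - grand) ** 2).sum()
    ss_group = sum(
        k * len(subj_means[groups == g]) *
        (subj_means[groups == g].mean() - grand) ** 2
        for g in groups.unique())
    ss_between_err = ss_subjects - ss_group
    within_means = data.groupby(within)[dv].mean()
    counts_w = data.groupby(within)[dv].size()
    ss_within = ((within_means - grand) ** 2 * counts_w).sum()
    cell = data.groupby([between, within])[dv].agg(["mean", "size"])
    ss_cells = ((cell["mean"] - grand) ** 2 * cell["size"]).sum()
    ss_inter = ss_cells - ss_group - ss_within
    ss_total = ((y - grand) ** 2).sum()
    ss_within_err = ss_total - ss_subjects - ss_within - ss_inter
    df_err_b = n_subj - 2
    df_err_w = n_subj - 2
    return {
        "between": ss_group / (ss_between_err / df_err_b),
        "within": ss_within / (ss_within_err / df_err_w),
        "interaction": ss_inter / (ss_within_err / df_err_w),
    }


def long_data(rng, n_per_group=6, group_shift=1.0, set_shift=0.5,
              interaction=0.0):
    rows = []
    for g, gshift in (("older", group_shift), ("younger", 0.0)):
        for i in range(n_per_group):
            base = rng.normal()
            for w, wshift in (("chosen", set_shift), ("unsorted", 0.0)):
                extra = interaction if (g == "older" and w == "chosen") else 0
                rows.append({
                    "participant_id": f"{g}{i}", "age_group": g,
                    "set_label": w,
                    "y": base + gshift + wshift + extra + rng.normal(0, 0.3)})
    return pd.DataFrame(rows)


class TestEFComposite:
    def test_three_participant_hand_computation(self):
        records = pd.DataFrame({
            "participant_id": ["a", "b", "c"],
            "dsst": [60.0, 70.0, 80.0],
            "tmt_b_s": [80.0, 60.0, 40.0],
            "vst_c_s": [70.0, 50.0, 30.0],
            "lps3": [15.0, 20.0, 25.0],
        })
        ef = ef_composite(records)
        # every oriented measure is a linear increasing sequence, so each
        # z-score is (-1, 0, 1) and the composite equals it
        assert ef["ef"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert ef.loc[1, "ef"] == pytest.approx(0.0)  # pooled-mean participant

    def test_faster_timed_scores_give_larger_z(self):
        records = pd.DataFrame({
            "participant_id": list("abcd"),
            "dsst": [70.0] * 4, "lps3": [20.0] * 4,
            "vst_c_s": [40.0] * 4,
            "tmt_b_s": [30.0, 50.0, 70.0, 90.0],
        })
        ef = ef_composite(records)
        assert ef["z_tmtb"].is_monotonic_decreasing
        assert ef.loc[0, "z_tmtb"] > 0

    def test_missing_measure_excluded_with_warning(self):
        records = pd.DataFrame({
            "participant_id": list("abc"),
            "dsst": [60.0, np.nan, 80.0], "tmt_b_s": [80.0, 60.0, 40.0],
            "vst_c_s": [70.0, 50.0, 30.0], "lps3": [15.0, 20.0, 25.0]})
        with pytest.warns(RuntimeWarning, match="missing EF"):
            ef = ef_composite(records)
        assert ef["participant_id"].tolist() == ["a", "c"]


class TestMixedANOVA:
    def test_matches_hand_sums_of_squares(self):
        rng = np.random.default_rng(4)
        data = long_data(rng, n_per_group=8, interaction=0.8)
        results = {r.name: r for r in mixed_anova(
            data, dv="y", within="set_label", subject="participant_id",
            between="age_group")}
        oracle = hand_mixed_anova(data, "y", "set_label", "participant_id",
                                  "age_group")
        assert results["main effect age_group"].statistic == \
            pytest.approx(oracle["between"])
        assert results["main effect set_label"].statistic == \
            pytest.approx(oracle["within"])
        assert results["interaction age_group x set_label"].statistic == \
            pytest.approx(oracle["interaction"])

    def test_within_f_equals_squared_paired_t_without_interaction(self):
        # identical within-subject differences in both groups: interaction
        # SS is exactly zero and the within F collapses to the paired t^2
        rng = np.random.default_rng(5)
        diffs = rng.normal(0.6, 1.0, 6)
        rows = []
        for g in ("older", "younger"):
            base = rng.normal(0, 1, 6) + (1.0 if g == "older" else 0.0)
            for i in range(6):
                rows.append({"participant_id": f"{g}{i}", "age_group": g,
                             "set_label": "chosen",
                             "y": base[i] + diffs[i]})
                rows.append({"participant_id": f"{g}{i}", "age_group": g,
                             "set_label": "unsorted", "y": base[i]})
        data = pd.DataFrame(rows)
        results = {r.name: r for r in mixed_anova(
            data, dv="y", within="set_label", subject="participant_id",
            between="age_group")}
        wide = data.pivot(index="participant_id", columns="set_label",
                          values="y")
        d = (wide["chosen"] - wide["unsorted"]).to_numpy()
        # paired t with the ANOVA's error df (differences centred per group;
        # identical here because the interaction is exactly zero)
        n = d.size
        t_sq = n * d.mean() ** 2 / (((d - d.mean()) ** 2).sum() / (n - 2))
        assert results["interaction age_group x set_label"].statistic == \
            pytest.approx(0.0, abs=1e-9)
        assert results["main effect set_label"].statistic == \
            pytest.approx(t_sq)

    def test_incomplete_cells_rejected(self):
        rng = np.random.default_rng(6)
        data = long_data(rng).iloc[:-1]
        with pytest.raises(ValueError, match="within"):
            mixed_anova(data, dv="y", within="set_label",
                        subject="participant_id", between="age_group")


class TestTCompare:
    def test_hand_computed_student_case(self):
        res = t_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], n_boot=0)
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2 / 3))
        assert res.df == 4
        assert res.effect_size == pytest.approx(-3.0)

    def test_identical_samples(self):
        res = t_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_boot=0)
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_levene_gate_selects_welch(self, rng):
        a = rng.normal(0, 0.5, 40)
        b = rng.normal(0, 5.0, 25)
        res = t_compare(a, b, n_boot=0)
        assert "Welch" in res.note
        assert res.df < 63  # fractional, below the pooled n1 + n2 - 2

    def test_paired_uses_difference_sd(self):
        a = np.array([3.0, 5.0, 7.0, 9.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        res = t_compare(a, b, paired=True, n_boot=0)
        d = a - b
        assert res.statistic == pytest.approx(
            d.mean() / (d.std(ddof=1) / 2))
        assert res.df == 3

    def test_bootstrap_ci_reproducible_and_covers_estimate(self, rng):
        a = rng.normal(1.0, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        r1 = t_compare(a, b, n_boot=500, seed=7)
        r2 = t_compare(a, b, n_boot=500, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= a.mean() - b.mean() <= r1.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            t_compare([1.0, 1.0], [2.0, 2.0], n_boot=0)


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        res = one_sample_t([-2.0, -1.0, 1.0, 2.0], 0.0, n_boot=0)
        assert res.statistic == 0.0

    def test_hand_computed_case(self):
        res = one_sample_t([1.0, 2.0, 6.0], 2.0, n_boot=0)
        sd = np.std([1.0, 2.0, 6.0], ddof=1)
        assert res.statistic == pytest.approx(1.0 / (sd / np.sqrt(3)))
        assert res.effect_size == pytest.approx(1.0 / sd)


class TestCorrelation:
    def test_five_point_hand_example(self):
        res = correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], n_boot=0)
        assert res.statistic == pytest.approx(0.8)
        assert res.df == 3

    def test_partial_reduces_to_plain_when_control_orthogonal(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        z = rng.normal(size=40)
        # orthogonalize the control against x and y exactly
        design = np.column_stack([np.ones(40), x, y])
        z = z - design @ np.linalg.lstsq(design, z, rcond=None)[0]
        plain = correlation(x, y, n_boot=0)
        partial = correlation(x, y, control=z, n_boot=0)
        assert partial.statistic == pytest.approx(plain.statistic)

    def test_partial_with_binary_control_equals_centred_pearson(self, rng):
        group = np.repeat([0.0, 1.0], 20)
        x = rng.normal(size=40) + group
        y = 0.5 * x + rng.normal(size=40) + 2 * group
        partial = correlation(x, y, control=group, n_boot=0)
        xc = x.copy()
        yc = y.copy()
        for g in (0.0, 1.0):
            xc[group == g] -= x[group == g].mean()
            yc[group == g] -= y[group == g].mean()
        assert partial.statistic == pytest.approx(
            np.corrcoef(xc, yc)[0, 1])

    def test_bootstrap_ci_reproducible(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r1 = correlation(x, y, n_boot=300, seed=3)
        r2 = correlation(x, y, n_boot=300, seed=3)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.statistic <= r1.ci_high

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0], n_boot=0)
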