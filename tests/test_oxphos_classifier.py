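"""Tests of mass-normalized z-scoring and four-way deficiency calling."""

import numpy as np
import pandas as pd
import pytest

from cryptmosaic.oxphos_classifier import (
    ReferenceDistribution,
    build_reference,
    classify_cohort,
    classify_crypt,
    mass_marker_qc,
    per_mouse_percentages,
    score_crypts,
    summarize_categories,
)
from cryptmosaic.synthetic_cohort import IntensityConfig, generate_intensity_cohort


def _frame(ndufb8, mtco1, tomm20, vdac1=None, genotype="+/+"):
    n = len(ndufb8)
    return pd.DataFrame(
        {
            "mouse_id": ["m1"] * n,
            "genotype": [genotype] * n,
            "crypt_id": [f"c{i}" for i in range(n)],
            "ndufb8": ndufb8,
            "mtco1": mtco1,
            "tomm20": tomm20,
            "vdac1": vdac1 if vdac1 is not None else tomm20,
        }
    )


def test_reference_moments_match_hand_arithmetic():
    # marker/mass ratios 0.9, 1.0, 1.1 for both markers
    tomm20 = np.array([1.0, 2.0, 1.5])
    ratios = np.array([0.9, 1.0, 1.1])
    df = _frame(ratios * tomm20, ratios * tomm20, tomm20)
    ref = build_reference(df)
    assert ref.ratio_mean["ndufb8"] == pytest.approx(1.0)
    assert ref.ratio_sd["ndufb8"] == pytest.approx(0.1)
    assert ref.ratio_mean["mtco1"] == pytest.approx(1.0)
    assert ref.n_control_crypts == 3


def test_single_control_crypt_rejected():
    df = _frame([1.0], [1.0], [1.0])
    with pytest.raises(ValueError, match="2 control crypts"):
        build_reference(df)


def test_missing_marker_column_named_in_error(control_cohort):
    ref = build_reference(control_cohort)
    broken = control_cohort.drop(columns=["mtco1"])
    with pytest.raises(ValueError, match="mtco1"):
        score_crypts(broken, ref)


def test_control_cohort_self_standardizes_to_mean0_sd1(control_cohort):
    ref = build_reference(control_cohort)
    scored = score_crypts(control_cohort, ref)
    for col in ("z_ci", "z_civ", "z_mass"):
        assert abs(scored[col].mean()) < 1e-9
        assert abs(scored[col].std(ddof=1) - 1.0) < 1e-9


def test_score_arithmetic_known_reference():
    ref = ReferenceDistribution(
        ratio_mean={"ndufb8": 1.0, "mtco1": 1.0},
        ratio_sd={"ndufb8": 0.1, "mtco1": 0.1},
        mass_mean={"tomm20": 1.0},
        mass_sd={"tomm20": 0.5},
        n_control_crypts=10,
    )
    df = _frame([0.5, 1.0], [1.0, 1.0], [1.0, 1.0])
    scored = score_crypts(df, ref)
    assert scored["z_ci"].iloc[0] == pytest.approx(-5.0)
    assert scored["z_ci"].iloc[1] == pytest.approx(0.0)


@pytest.mark.parametrize(
    "z_ci, z_civ, expected",
    [
        (-5.0, -0.2, "CI_DEF"),
        (-0.2, -5.0, "CIV_DEF"),
        (-6.0, -7.0, "CI_CIV_DEF"),
        (0.0, 0.0, "NORMAL"),
        (-4.5, -4.5, "NORMAL"),  # strict inequality at the threshold
        (-4.5000001, -4.5, "CI_DEF"),
    ],
)
def test_four_way_classification(z_ci, z_civ, expected):
    assert classify_crypt(z_ci, z_civ) == expected


def test_nonfinite_z_rejected():
    with pytest.raises(ValueError, match="finite"):
        classify_crypt(np.nan, 0.0)


def test_calls_match_from_scratch_rederivation(control_cohort, rng):
    """Independent oracle: recompute ratios, moments, z and thresholds by hand."""
    idx = rng.choice(len(control_cohort), size=50, replace=False)
    # perturb to create a mix of categories
    crypts = control_cohort.iloc[idx].copy()
    scale_ci = rng.choice([1.0, 0.35], size=50)
    scale_civ = rng.choice([1.0, 0.35], size=50)
    crypts["ndufb8"] *= scale_ci
    crypts["mtco1"] *= scale_civ
    ref = build_reference(control_cohort)
    calls = classify_cohort(crypts, reference=ref)

    # from-scratch re-derivation with plain numpy
    r_ci = control_cohort["ndufb8"].to_numpy() / control_cohort["tomm20"].to_numpy()
    r_civ = control_cohort["mtco1"].to_numpy() / control_cohort["tomm20"].to_numpy()
    ms = {
        "ci": (r_ci.mean(), r_ci.std(ddof=1)),
        "civ": (r_civ.mean(), r_civ.std(ddof=1)),
    }
    for (_, row), call in zip(crypts.iterrows(), calls["category"]):
        z1 = (row["ndufb8"] / row["tomm20"] - ms["ci"][0]) / ms["ci"][1]
        z2 = (row["mtco1"] / row["tomm20"] - ms["civ"][0]) / ms["civ"][1]
        expected = {
            (True, True): "CI_CIV_DEF",
            (True, False): "CI_DEF",
            (False, True): "CIV_DEF",
            (False, False): "NORMAL",
        }[(z1 < -4.5, z2 < -4.5)]
        assert call == expected


def test_classification_invariant_to_row_order_and_mouse_relabelling(small_cohort):
    calls = classify_cohort(small_cohort)
    shuffled = small_cohort.sample(frac=1.0, random_state=0)
    calls_shuffled = classify_cohort(shuffled).sort_index()
    pd.testing.assert_frame_equal(
        calls.sort_index(), calls_shuffled, check_like=True
    )
    relabelled = small_cohort.copy()
    relabelled["mouse_id"] = relabelled["mouse_id"].map(lambda m: f"X{m}")
    calls_relabelled = classify_cohort(relabelled)
    assert (calls_relabelled["category"].to_numpy() == calls["category"].to_numpy()).all()


def test_summary_mean_and_sem_two_mice():
    # two mice, CI_DEF percentages 40 and 60
    rows = []
    for mouse, n_ci in (("m1", 4), ("m2", 6)):
        for i in range(10):
            rows.append(
                {
                    "mouse_id": mouse,
                    "genotype": "+/mut",
                    "crypt_id": f"c{i}",
                    "category": "CI_DEF" if i < n_ci else "NORMAL",
                }
            )
    summary = summarize_categories(pd.DataFrame(rows))
    ci = summary[(summary.category == "CI_DEF")].iloc[0]
    assert ci["mean_pct"] == pytest.approx(50.0)
    assert ci["sem_pct"] == pytest.approx(10.0)


def test_single_mouse_sem_zero_with_warning():
    df = pd.DataFrame(
        {
            "mouse_id": ["m1"] * 5,
            "genotype": ["+/+"] * 5,
            "crypt_id": list("abcde"),
            "category": ["NORMAL"] * 5,
        }
    )
    with pytest.warns(UserWarning, match="single mouse"):
        summary = summarize_categories(df)
    normal = summary[summary.category == "NORMAL"].iloc[0]
    assert normal["mean_pct"] == pytest.approx(100.0)
    assert normal["sem_pct"] == 0.0


def test_per_mouse_percentages_partition_to_100(small_cohort):
    calls = classify_cohort(small_cohort)
    pct = per_mouse_percentages(calls)
    sums = pct[["NORMAL", "CI_DEF", "CIV_DEF", "CI_CIV_DEF"]].sum(axis=1)
    assert np.allclose(sums, 100.0, atol=1e-9)


def test_mass_qc_flags_only_injected_outlier(control_cohort):
    ref = build_reference(control_cohort)
    clean = mass_marker_qc(control_cohort, ref)
    records = control_cohort.copy()
    # push one crypt's tomm20 far below the reference
    low_mean = ref.mass_mean["tomm20"] - 6 * ref.mass_sd["tomm20"]
    records.loc[records.index[0], "tomm20"] = low_mean
    report = mass_marker_qc(records, ref)
    tom = report.flagged[report.flagged.mass_marker == "tomm20"]
    assert len(tom) == 1
    assert tom.iloc[0]["crypt_id"] == records.iloc[0]["crypt_id"]
    assert clean.n_flagged <= report.n_flagged


def test_deficiency_recovery_confusion_better_than_99_percent():
    """With effect 0.6 and CV 0.10 the deficient cloud sits ~6 SD below the
    reference, so called categories should recover truth essentially always."""
    probs = (0.5282, 0.3188, 0.0424, 0.1106)
    cfg = IntensityConfig(
        n_mice_per_genotype=4,
        crypts_per_mouse=2500,
        category_probs={"+/+": (1, 0, 0, 0), "+/mut": probs},
        seed=21,
    )
    df = generate_intensity_cohort(cfg)
    calls = classify_cohort(df)
    merged = calls.merge(
        df[["mouse_id", "crypt_id", "true_category"]], on=["mouse_id", "crypt_id"]
    )
    mosaic = merged[merged.genotype == "+/mut"]
    for cat in ("NORMAL", "CI_DEF", "CIV_DEF", "CI_CIV_DEF"):
        sub = mosaic[mosaic.true_category == cat]
        assert (sub.category == cat).mean() > 0.99
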