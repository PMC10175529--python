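"""Aggregation logic of the robustness pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radrobust import StudyConfig
from radrobust import feature_extraction as fx
from radrobust import robustness_pipeline as rp


def synthetic_table(n_platforms=4, value_fn=None, image_types=("VUE", "VMI70keV"),
                    n_repeats=2):
    """Feature table with controllable values for aggregation tests."""
    rng = np.random.default_rng(0)
    base = {}
    rows = []
    for pid in range(1, n_platforms + 1):
        for itype in image_types:
            for rep in range(1, n_repeats + 1):
                for roi in range(1, 17):
                    for fclass, names in (("firstorder", fx.FIRSTORDER_NAMES),
                                          ("glcm", fx.GLCM_NAMES),
                                          ("gldm", fx.GLDM_NAMES),
                                          ("glrlm", fx.GLRLM_NAMES),
                                          ("glszm", fx.GLSZM_NAMES),
                                          ("ngtdm", fx.NGTDM_NAMES)):
                        for name in names:
                            key = (itype, roi, fclass, name)
                            if key not in base:
                                base[key] = rng.normal(100, 20)
                            if value_fn is None:
                                v = base[key]
                            else:
                                v = value_fn(base[key], pid, itype, rep, roi,
                                             fclass, name)
                            rows.append((pid, itype, rep, roi, fclass, name, v))
    return pd.DataFrame(rows, columns=fx.FEATURE_TABLE_COLUMNS)


class TestRepeatability:
    def test_identical_scan_rescan_fully_repeatable(self):
        table = synthetic_table(n_platforms=2)
        summary = rp.run_repeatability(table)
        assert (summary.per_platform["pct_repeatable"] == 100.0).all()
        assert (summary.per_feature["frac_within"] == 1.0).all()

    def test_missing_repeat_names_the_gap(self):
        table = synthetic_table(n_platforms=2)
        broken = table[~((table.platform_id == 2) & (table.repeat_idx == 2)
                         & (table.image_type == "VUE"))]
        with pytest.raises(ValueError, match="platform 2 VUE"):
            rp.run_repeatability(broken)

    def test_one_pct_value_per_platform_and_type(self, small_study):
        per = small_study.repeatability.per_platform
        assert len(per) == 4 * 2
        assert per["pct_repeatable"].between(0, 100).all()

    def test_rollup_uses_sample_sd(self, small_study):
        per = small_study.repeatability.per_platform
        roll = small_study.repeatability.rollup.set_index("image_type")
        for itype, g in per.groupby("image_type"):
            assert roll.loc[itype, "mean_pct"] == pytest.approx(g.pct_repeatable.mean())
            assert roll.loc[itype, "sd_pct"] == pytest.approx(g.pct_repeatable.std(ddof=1))


class TestDispersion:
    def test_identical_platforms_give_zero_cv(self):
        table = synthetic_table(n_platforms=4)  # same value on every platform
        summary = rp.run_dispersion(table)
        prf = summary.per_roi_feature
        assert (prf["cv_pct"] == 0.0).all()
        assert (summary.per_roi["pct_cv_lt10"] == 100.0).all()

    def test_single_platform_rejected(self):
        table = synthetic_table(n_platforms=2)
        with pytest.raises(ValueError, match="platforms"):
            rp.run_dispersion(table[table.platform_id == 1])

    def test_class_partition_19_24_14_16_16_5(self, small_study):
        ct = small_study.dispersion.class_table
        by_label = ct[ct.image_type == "VUE"].set_index("feature_class")["n_features"]
        assert by_label["First order"] == 19
        assert by_label["Texture"] == 75
        assert (by_label["GLCM"], by_label["GLDM"], by_label["GLRLM"],
                by_label["GLSZM"], by_label["NGTDM"]) == (24, 14, 16, 16, 5)
        assert by_label["Overall"] == 94

    def test_spread_increase_degrades_first_order_reproducibility(self):
        # same seed, larger inter-platform CT-number spread -> fewer
        # first-order features below the 10% CV cutoff
        results = {}
        for spread in (0.0, 30.0):
            cfg = StudyConfig(n_platforms=4, spread_hu=spread, bias_sd_hu=0.0,
                              kernel_jitter=0.0)
            res = rp.run_full_study(cfg, seed=21)
            ctab = res.dispersion.class_table
            row = ctab[(ctab.feature_class == "First order")
                       & (ctab.image_type == "VMI70keV")]
            results[spread] = float(row["pct_cv_lt10"].iloc[0])
        assert results[30.0] < results[0.0]

    def test_repeat_policy_selects_the_right_scan(self):
        table = synthetic_table(
            n_platforms=4,
            value_fn=lambda b, pid, t, rep, roi, c, n: b + pid if rep == 1 else -999.0)
        first = rp.run_dispersion(table, repeat_policy="first")
        second = rp.run_dispersion(table, repeat_policy="second")
        # "first" ignores the rescan entirely; "second" sees the constant
        # sentinel, so every feature collapses to zero dispersion
        assert (first.per_roi_feature["cv_pct"] > 0.0).any()
        assert (second.per_roi_feature["cv_pct"] == 0.0).all()


class TestPairwise:
    def test_pair_counts(self, small_study):
        per_pair = small_study.pairwise.per_pair
        n_pairs = len(list(itertools.combinations(range(4), 2)))
        assert len(per_pair) == n_pairs * 2  # per image type
        ppf = small_study.pairwise.per_pair_feature
        for itype in ("VUE", "VMI70keV"):
            assert len(ppf[ppf.image_type == itype]) == n_pairs * 94

    def test_identical_platforms_agree_perfectly(self):
        # distinct values across ROIs, identical across platforms
        table = synthetic_table(n_platforms=3)
        summary = rp.run_pairwise(table)
        ppf = summary.per_pair_feature
        assert np.allclose(ppf["icc"], 1.0, atol=1e-12)
        assert np.allclose(ppf["ccc"], 1.0, atol=1e-12)
        assert not ppf["degenerate"].any()

    def test_pair_order_symmetry(self, small_features):
        from radrobust import agreement_stats as ast

        sub = small_features.query(
            "image_type=='VUE' and repeat_idx==1 and feature_name=='Entropy'")
        wide = sub.pivot_table(index="roi_id", columns="platform_id",
                               values="value")
        x, y = wide[1].to_numpy(), wide[2].to_numpy()
        assert ast.icc_a1(np.column_stack([x, y])) == pytest.approx(
            ast.icc_a1(np.column_stack([y, x])), abs=1e-12)
        assert ast.ccc(x, y) == pytest.approx(ast.ccc(y, x), abs=1e-12)

    def test_top_features_ranked_by_mean_icc(self, small_study):
        top = small_study.pairwise.top_features
        for itype, g in top.groupby("image_type"):
            assert len(g) == 10
            assert (np.diff(g["icc"].to_numpy()) <= 1e-12).all()

    def test_shortlist_has_14_features_per_type(self, small_study):
        sl = small_study.pairwise.shortlist
        for itype, g in sl.groupby("image_type"):
            assert len(g) == 14


class TestCTAnalysis:
    def test_homogeneous_platforms_flag_correlation_undefined(self):
        table = synthetic_table(n_platforms=4)
        report = rp.run_ct_analysis(table)
        assert (report.per_roi["cv_pct"] == 0.0).all()
        assert not report.correlations["defined"].any()

    def test_ct_number_equals_first_order_mean(self, small_study):
        # the CT-number analysis is defined on the first-order Mean feature
        feats = small_study.features
        mean_rows = feats[(feats.feature_class == "firstorder")
                          & (feats.feature_name == "Mean")
                          & (feats.repeat_idx == 1)]
        wide = mean_rows.pivot_table(index=["image_type", "roi_id"],
                                     columns="platform_id", values="value")
        from radrobust import agreement_stats as ast
        row = wide.loc[("VUE", 1)].to_numpy()
        want_cv = ast.cv(row)
        got = small_study.ct_report.per_roi
        got_cv = got[(got.image_type == "VUE") & (got.roi_id == 1)]["cv_pct"].iloc[0]
        assert got_cv == pytest.approx(want_cv, rel=1e-12)

    def test_correlation_sample_sizes(self, small_study):
        corr = small_study.ct_report.correlations
        roi_level = corr[corr.metric.isin(["cv", "qcd"])]
        pair_level = corr[corr.metric.isin(["icc", "ccc"])]
        assert (roi_level["n"] == 16).all()
        assert (pair_level["n"] == 6).all()  # C(4,2) pairs


class TestReport:
    def test_report_files_and_layout(self, small_study, tmp_path):
        files = rp.report(small_study, tmp_path)
        names = {f.split("/")[-1] for f in files}
        assert {"table2_analog.csv", "table3_analog.csv", "table4_analog.csv",
                "run_summary.json", "config_frozen.yaml"} <= names
        t2 = pd.read_csv(tmp_path / "table2_analog.csv")
        for itype in ("VUE", "VMI70keV"):
            assert len(t2[t2.image_type == itype]) == 8  # 7 class rows + overall

    def test_report_byte_identical_across_reruns(self, tmp_path):
        cfg = StudyConfig(n_platforms=2)
        a = rp.run_full_study(cfg, seed=5, out_dir=tmp_path / "a")
        b = rp.run_full_study(cfg, seed=5, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_json_summary_roundtrip(self, small_study, tmp_path):
        import json

        rp.report(small_study, tmp_path)
        summary = json.loads((tmp_path / "run_summary.json").read_text())
        assert summary["seed"] == small_study.seed
        cfg = StudyConfig.from_dict(summary["config"])
        assert cfg.hash() == small_study.config.hash()
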