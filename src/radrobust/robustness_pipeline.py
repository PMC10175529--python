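"""End-to-end robustness pipeline: simulate → register → extract → analyze.

Aggregation mirrors the standard multi-platform phantom design:

* test–retest repeatability: Bland–Altman per (platform, image type,
  feature) across the 16 paired ROI values, then percent repeatable of
  the 94-feature panel per platform, rolled up mean ± SD per image type;
* inter-platform dispersion: CV and QCD per (image type, ROI, feature)
  across platforms, percent of features under the 10% cutoff per ROI,
  per-class rollups;
* pairwise agreement: ICC(A,1) and CCC per platform pair over the 16
  ROI values, percent above the 0.90 cutoff per pair (45 pairs for ten
  platforms), per-class rollups, top-k ranking and a configurable
  14-feature shortlist report;
* CT-number analysis: the per-ROI mean HU plays the role of the CT
  number; its dispersion/agreement across platforms is summarized the
  same way and rank-correlated (Spearman) with the percentage of
  first-order features meeting the matching cutoff.

Degenerate (flagged) statistics count as failing every cutoff; they are
never silently dropped from percentages.  Mean rollups of CV/QCD use
finite values only.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement_stats as ast
from . import feature_extraction as fx
from . import phantom_synth as ph
from . import roi_tools as rt
from .config import StudyConfig

__all__ = [
    "RepeatabilitySummary",
    "DispersionSummary",
    "PairwiseSummary",
    "CTNumberReport",
    "StudyResult",
    "build_feature_table",
    "run_repeatability",
    "run_dispersion",
    "run_pairwise",
    "run_ct_analysis",
    "report",
    "run_full_study",
]

_CLASS_LABELS = {
    "firstorder": "First order",
    "glcm": "GLCM",
    "gldm": "GLDM",
    "glrlm": "GLRLM",
    "glszm": "GLSZM",
    "ngtdm": "NGTDM",
}
_TEXTURE_CLASSES = ("glcm", "gldm", "glrlm", "glszm", "ngtdm")


@dataclass
class RepeatabilitySummary:
    per_feature: pd.DataFrame   # one Bland–Altman row per (platform, type, feature)
    per_platform: pd.DataFrame  # pct_repeatable per (platform, type)
    rollup: pd.DataFrame        # mean ± SD of pct across platforms per type


@dataclass
class DispersionSummary:
    per_roi_feature: pd.DataFrame  # cv/qcd per (type, roi, feature)
    per_roi: pd.DataFrame          # pct under cutoff per (type, roi)
    rollup: pd.DataFrame           # mean ± SD of per-ROI pct per type
    heatmap: pd.DataFrame          # ROI-averaged cv/qcd per (type, feature)
    class_table: pd.DataFrame      # per-class pct and mean metric per type


@dataclass
class PairwiseSummary:
    per_pair_feature: pd.DataFrame  # icc/ccc per (type, pair, feature)
    per_pair: pd.DataFrame          # pct above cutoff per (type, pair)
    rollup: pd.DataFrame            # mean ± SD of per-pair pct per type
    class_table: pd.DataFrame       # per-class pct and mean agreement per type
    top_features: pd.DataFrame      # top-k by mean ICC per type
    shortlist: pd.DataFrame         # agreement ranges for the named subset


@dataclass
class CTNumberReport:
    per_roi: pd.DataFrame        # CT-number cv/qcd per (type, roi)
    per_pair: pd.DataFrame       # CT-number icc/ccc per (type, pair)
    table: pd.DataFrame          # dispersion/agreement rollup per type
    correlations: pd.DataFrame   # Spearman rho/rho²/p per (type, metric)


@dataclass
class StudyResult:
    config: StudyConfig
    seed: int
    manifest: pd.DataFrame
    registration: pd.DataFrame
    features: pd.DataFrame
    repeatability: RepeatabilitySummary
    dispersion: DispersionSummary
    pairwise: PairwiseSummary
    ct_report: CTNumberReport


# ---------------------------------------------------------------------------
# feature-table construction


def build_feature_table(scans, spec: ph.PhantomSpec,
                        config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Register every scan to a noise-free reference and extract features.

    The registration reference is the analytically rasterized, unshifted
    phantom (reference platform, no noise, no smoothing) of the matching
    image type.  Returns the long feature table and a registration log
    with estimated vs. ground-truth shifts.
    """
    ref_platform = ph.PlatformModel(
        platform_id=0, scanner_type="reference",
        hu_bias={t: 0.0 for t in ph.IMAGE_TYPES},
        hu_insert_deviation={(t, i): 0.0 for t in ph.IMAGE_TYPES
                             for i in range(1, 17)},
        noise_sd={t: 1.0 for t in ph.IMAGE_TYPES}, kernel_fwhm_px=0.0)
    references = {
        t: ph.ScanImage(pixels=ph.rasterize(spec, ref_platform, t),
                        pixel_spacing_mm=ph.PIXEL_SPACING_MM, platform_id=0,
                        image_type=t, repeat_idx=1,
                        applied_shift_px=(0.0, 0.0), seed_used=-1)
        for t in config.image_types}
    tables = []
    reg_rows = []
    for scan in scans:
        tf = rt.estimate_rigid(scan, references[scan.image_type])
        rois = rt.make_roi_masks(spec, tf, diameter_px=config.roi_diameter_px)
        tables.append(fx.extract_all(scan, rois, bin_width=config.bin_width))
        reg_rows.append({
            "platform_id": scan.platform_id, "image_type": scan.image_type,
            "repeat_idx": scan.repeat_idx,
            "dx_true_px": scan.applied_shift_px[0],
            "dy_true_px": scan.applied_shift_px[1],
            "dx_est_px": tf.dx_px, "dy_est_px": tf.dy_px})
    features = pd.concat(tables, ignore_index=True)
    return features, pd.DataFrame(reg_rows)


def _check_complete_repeats(features: pd.DataFrame) -> None:
    have = features.groupby(["platform_id", "image_type"])["repeat_idx"].unique()
    for (pid, itype), reps in have.items():
        if 1 not in reps or 2 not in reps:
            raise ValueError(
                f"platform {pid} {itype}: need repeats 1 and 2, have {sorted(reps)}")


def _select_repeat(features: pd.DataFrame, policy: str) -> pd.DataFrame:
    """Collapse the repeat axis per the configured policy."""
    if policy == "first":
        return features[features["repeat_idx"] == 1].copy()
    if policy == "second":
        return features[features["repeat_idx"] == 2].copy()
    if policy == "mean":
        keys = ["platform_id", "image_type", "roi_id", "feature_class",
                "feature_name"]
        out = features.groupby(keys, as_index=False, sort=False)["value"].mean()
        out["repeat_idx"] = 0
        return out
    raise ValueError(f"unknown repeat policy {policy!r}")


# ---------------------------------------------------------------------------
# analyses


def run_repeatability(features: pd.DataFrame,
                      cutoff: float = 0.90) -> RepeatabilitySummary:
    """Bland–Altman test–retest repeatability, per platform and feature."""
    _check_complete_repeats(features)
    sub = features[features["repeat_idx"].isin([1, 2])]
    wide = sub.pivot_table(index=["platform_id", "image_type", "feature_class",
                                  "feature_name", "roi_id"],
                           columns="repeat_idx", values="value")
    rows = []
    for (pid, itype, fclass, fname), g in wide.groupby(
            level=["platform_id", "image_type", "feature_class", "feature_name"],
            sort=False):
        g = g.sort_index(level="roi_id")
        res = ast.bland_altman(g[1].to_numpy(), g[2].to_numpy(), cutoff=cutoff)
        rows.append({"platform_id": pid, "image_type": itype,
                     "feature_class": fclass, "feature_name": fname,
                     "bias": res.bias, "sd_diff": res.sd_diff,
                     "loa_low": res.loa_low, "loa_high": res.loa_high,
                     "frac_within": res.frac_within,
                     "repeatable": res.repeatable, "p_bias": res.p_bias})
    per_feature = pd.DataFrame(rows)
    per_platform = (per_feature.groupby(["platform_id", "image_type"])["repeatable"]
                    .mean().mul(100.0).rename("pct_repeatable").reset_index())
    rollup = (per_platform.groupby("image_type")["pct_repeatable"]
              .agg(mean_pct="mean", sd_pct=lambda v: v.std(ddof=1))
              .reset_index())
    return RepeatabilitySummary(per_feature=per_feature,
                                per_platform=per_platform, rollup=rollup)


def _class_rows(df: pd.DataFrame, value_cols: dict[str, str],
                pass_cols: dict[str, str]) -> pd.DataFrame:
    """Per-class rollup with the First order / Texture / per-class / Overall rows."""
    blocks = [("First order", df["feature_class"] == "firstorder"),
              ("Texture", df["feature_class"].isin(_TEXTURE_CLASSES))]
    blocks += [(_CLASS_LABELS[c], df["feature_class"] == c)
               for c in _TEXTURE_CLASSES]
    blocks += [("Overall", df["feature_class"].notna())]
    rows = []
    for itype, g in df.groupby("image_type", sort=False):
        for label, sel in blocks:
            gg = g[sel.loc[g.index]]
            row = {"image_type": itype, "feature_class": label,
                   "n_features": gg.drop_duplicates(
                       ["feature_class", "feature_name"]).shape[0]}
            for out, col in pass_cols.items():
                row[out] = 100.0 * gg[col].mean()
            for out, col in value_cols.items():
                v = gg[col].to_numpy()
                v = v[np.isfinite(v)]
                row[out] = v.mean() if v.size else math.nan
            rows.append(row)
    return pd.DataFrame(rows)


def run_dispersion(features: pd.DataFrame, repeat_policy: str = "first",
                   cutoff_pct: float = 10.0) -> DispersionSummary:
    """CV/QCD of every feature across platforms, per image type and ROI."""
    if features["platform_id"].nunique() < 2:
        raise ValueError("dispersion analysis needs at least 2 platforms")
    sub = _select_repeat(features, repeat_policy)
    wide = sub.pivot_table(index=["image_type", "roi_id", "feature_class",
                                  "feature_name"],
                           columns="platform_id", values="value")
    vals = wide.to_numpy()
    n_plat = vals.shape[1]
    rows = []
    for (itype, roi, fclass, fname), v in zip(wide.index, vals):
        d = ast.dispersion(v)
        rows.append({"image_type": itype, "roi_id": roi,
                     "feature_class": fclass, "feature_name": fname,
                     "cv_pct": d.cv_pct, "qcd_pct": d.qcd_pct,
                     "degenerate": d.degenerate_flag, "n_platforms": n_plat})
    prf = pd.DataFrame(rows)
    prf["cv_pass"] = np.isfinite(prf["cv_pct"]) & (prf["cv_pct"] < cutoff_pct)
    prf["qcd_pass"] = np.isfinite(prf["qcd_pct"]) & (prf["qcd_pct"] < cutoff_pct)

    per_roi = (prf.groupby(["image_type", "roi_id"])[["cv_pass", "qcd_pass"]]
               .mean().mul(100.0)
               .rename(columns={"cv_pass": "pct_cv_lt10",
                                "qcd_pass": "pct_qcd_lt10"})
               .reset_index())
    rollup = (per_roi.groupby("image_type")[["pct_cv_lt10", "pct_qcd_lt10"]]
              .agg(["mean", lambda v: v.std(ddof=1)]))
    rollup.columns = ["cv_mean_pct", "cv_sd_pct", "qcd_mean_pct", "qcd_sd_pct"]
    rollup = rollup.reset_index()

    def _finite_mean(v):
        v = v[np.isfinite(v)]
        return v.mean() if len(v) else math.nan

    heatmap = (prf.groupby(["image_type", "feature_class", "feature_name"])
               [["cv_pct", "qcd_pct"]].agg(_finite_mean)
               .rename(columns={"cv_pct": "mean_cv_pct",
                                "qcd_pct": "mean_qcd_pct"})
               .reset_index())
    class_table = _class_rows(
        prf,
        value_cols={"cv_mean": "cv_pct", "qcd_mean": "qcd_pct"},
        pass_cols={"pct_cv_lt10": "cv_pass", "pct_qcd_lt10": "qcd_pass"})
    return DispersionSummary(per_roi_feature=prf, per_roi=per_roi,
                             rollup=rollup, heatmap=heatmap,
                             class_table=class_table)


def _agreement_pair(x: np.ndarray, y: np.ndarray) -> ast.AgreementValue:
    both = np.concatenate([x, y])
    scale = max(1.0, float(np.abs(both).max()))
    degenerate = float(both.std()) < 1e-12 * scale
    return ast.AgreementValue(icc=ast.icc_a1(np.column_stack([x, y])),
                              ccc=ast.ccc(x, y), n_subjects=len(x),
                              degenerate_flag=degenerate)


def run_pairwise(features: pd.DataFrame, repeat_policy: str = "first",
                 cutoff: float = 0.90, top_k: int = 10,
                 shortlist=()) -> PairwiseSummary:
    """ICC(A,1)/CCC between every platform pair over the 16 ROI values."""
    platforms = sorted(features["platform_id"].unique())
    if len(platforms) < 2:
        raise ValueError("pairwise analysis needs at least 2 platforms")
    sub = _select_repeat(features, repeat_policy)
    wide = sub.pivot_table(index=["image_type", "feature_class", "feature_name",
                                  "roi_id"],
                           columns="platform_id", values="value")
    pairs = list(itertools.combinations(platforms, 2))
    rows = []
    for (itype, fclass, fname), g in wide.groupby(
            level=["image_type", "feature_class", "feature_name"], sort=False):
        g = g.sort_index(level="roi_id")
        cols = {p: g[p].to_numpy() for p in platforms}
        for a, b in pairs:
            res = _agreement_pair(cols[a], cols[b])
            rows.append({"image_type": itype, "platform_a": a, "platform_b": b,
                         "feature_class": fclass, "feature_name": fname,
                         "icc": res.icc, "ccc": res.ccc,
                         "degenerate": res.degenerate_flag})
    ppf = pd.DataFrame(rows)
    ppf["icc_pass"] = (ppf["icc"] > cutoff) & ~ppf["degenerate"]
    ppf["ccc_pass"] = (ppf["ccc"] > cutoff) & ~ppf["degenerate"]

    per_pair = (ppf.groupby(["image_type", "platform_a", "platform_b"])
                [["icc_pass", "ccc_pass"]].mean().mul(100.0)
                .rename(columns={"icc_pass": "pct_icc_gt090",
                                 "ccc_pass": "pct_ccc_gt090"})
                .reset_index())
    rollup = (per_pair.groupby("image_type")[["pct_icc_gt090", "pct_ccc_gt090"]]
              .agg(["mean", lambda v: v.std(ddof=1)]))
    rollup.columns = ["icc_mean_pct", "icc_sd_pct", "ccc_mean_pct", "ccc_sd_pct"]
    rollup = rollup.reset_index()
    class_table = _class_rows(
        ppf,
        value_cols={"icc_mean": "icc", "ccc_mean": "ccc"},
        pass_cols={"pct_icc_gt090": "icc_pass", "pct_ccc_gt090": "ccc_pass"})

    mean_agreement = (ppf.groupby(["image_type", "feature_class", "feature_name"])
                      [["icc", "ccc"]].mean().reset_index())
    top = (mean_agreement
           .sort_values(["image_type", "icc", "feature_name"],
                        ascending=[True, False, True], kind="mergesort")
           .groupby("image_type", sort=False).head(top_k)
           .reset_index(drop=True))

    sl_keys = set(tuple(p) for p in shortlist)
    sl = ppf[[tuple(t) in sl_keys for t in
              zip(ppf["feature_class"], ppf["feature_name"])]]
    shortlist_df = (sl.groupby(["image_type", "feature_class", "feature_name"])
                    [["icc", "ccc"]].agg(["min", "max", "mean"]))
    shortlist_df.columns = ["_".join(c) for c in shortlist_df.columns]
    shortlist_df = shortlist_df.reset_index()
    return PairwiseSummary(per_pair_feature=ppf, per_pair=per_pair,
                           rollup=rollup, class_table=class_table,
                           top_features=top, shortlist=shortlist_df)


def run_ct_analysis(features: pd.DataFrame,
                    dispersion: DispersionSummary | None = None,
                    pairwise: PairwiseSummary | None = None,
                    repeat_policy: str = "first",
                    cutoff_pct: float = 10.0,
                    cutoff_agreement: float = 0.90) -> CTNumberReport:
    """CT-number robustness and its correlation with first-order robustness.

    The CT number of an ROI is its mean HU, i.e. the first-order Mean
    feature.  Correlations (Spearman) relate, per image type: per-ROI
    CT-number CV/QCD with the per-ROI percentage of the 19 first-order
    features under the 10% cutoff (n = 16); and per-pair CT-number
    ICC/CCC with the per-pair percentage of first-order features above
    0.90 (n = 45 for ten platforms).
    """
    if dispersion is None:
        dispersion = run_dispersion(features, repeat_policy, cutoff_pct)
    if pairwise is None:
        pairwise = run_pairwise(features, repeat_policy, cutoff_agreement)
    ct = features[(features["feature_class"] == "firstorder")
                  & (features["feature_name"] == "Mean")]
    ct = _select_repeat(ct, repeat_policy)
    wide = ct.pivot_table(index=["image_type", "roi_id"],
                          columns="platform_id", values="value")
    platforms = sorted(features["platform_id"].unique())
    pairs = list(itertools.combinations(platforms, 2))

    roi_rows = []
    for (itype, roi), v in zip(wide.index, wide.to_numpy()):
        d = ast.dispersion(v)
        roi_rows.append({"image_type": itype, "roi_id": roi,
                         "cv_pct": d.cv_pct, "qcd_pct": d.qcd_pct,
                         "degenerate": d.degenerate_flag})
    per_roi = pd.DataFrame(roi_rows)
    per_roi["cv_pass"] = np.isfinite(per_roi["cv_pct"]) & (per_roi["cv_pct"] < cutoff_pct)
    per_roi["qcd_pass"] = np.isfinite(per_roi["qcd_pct"]) & (per_roi["qcd_pct"] < cutoff_pct)

    pair_rows = []
    for itype in wide.index.get_level_values("image_type").unique():
        g = wide.loc[itype].sort_index()
        for a, b in pairs:
            res = _agreement_pair(g[a].to_numpy(), g[b].to_numpy())
            pair_rows.append({"image_type": itype, "platform_a": a,
                              "platform_b": b, "icc": res.icc, "ccc": res.ccc,
                              "degenerate": res.degenerate_flag})
    per_pair = pd.DataFrame(pair_rows)
    per_pair["icc_pass"] = (per_pair["icc"] > cutoff_agreement) & ~per_pair["degenerate"]
    per_pair["ccc_pass"] = (per_pair["ccc"] > cutoff_agreement) & ~per_pair["degenerate"]

    def _finite_mean(v: np.ndarray) -> float:
        v = v[np.isfinite(v)]
        return float(v.mean()) if v.size else math.nan

    table_rows = []
    for itype in per_roi["image_type"].unique():
        r = per_roi[per_roi["image_type"] == itype]
        p = per_pair[per_pair["image_type"] == itype]
        table_rows.append({
            "image_type": itype,
            "pct_cv_lt10": 100.0 * r["cv_pass"].mean(),
            "cv_mean": _finite_mean(r["cv_pct"].to_numpy()),
            "pct_qcd_lt10": 100.0 * r["qcd_pass"].mean(),
            "qcd_mean": _finite_mean(r["qcd_pct"].to_numpy()),
            "pct_icc_gt090": 100.0 * p["icc_pass"].mean(),
            "icc_mean": float(p["icc"].mean()),
            "pct_ccc_gt090": 100.0 * p["ccc_pass"].mean(),
            "ccc_mean": float(p["ccc"].mean()),
        })
    table = pd.DataFrame(table_rows)

    # first-order robustness percentages to correlate against
    fo = dispersion.per_roi_feature[
        dispersion.per_roi_feature["feature_class"] == "firstorder"]
    fo_roi = (fo.groupby(["image_type", "roi_id"])[["cv_pass", "qcd_pass"]]
              .mean().mul(100.0).reset_index())
    fo_pair_src = pairwise.per_pair_feature[
        pairwise.per_pair_feature["feature_class"] == "firstorder"]
    fo_pair = (fo_pair_src.groupby(["image_type", "platform_a", "platform_b"])
               [["icc_pass", "ccc_pass"]].mean().mul(100.0).reset_index())

    corr_rows = []
    for itype in per_roi["image_type"].unique():
        r = per_roi[per_roi["image_type"] == itype].sort_values("roi_id")
        f = fo_roi[fo_roi["image_type"] == itype].sort_values("roi_id")
        for metric, xcol, ycol in (("cv", "cv_pct", "cv_pass"),
                                   ("qcd", "qcd_pct", "qcd_pass")):
            x = r[xcol].to_numpy()
            y = f[ycol].to_numpy()
            corr_rows.append(_spearman_row(itype, metric, x, y))
        rp = per_pair[per_pair["image_type"] == itype].sort_values(
            ["platform_a", "platform_b"])
        fp = fo_pair[fo_pair["image_type"] == itype].sort_values(
            ["platform_a", "platform_b"])
        for metric, xcol, ycol in (("icc", "icc", "icc_pass"),
                                   ("ccc", "ccc", "ccc_pass")):
            x = rp[xcol].to_numpy()
            y = fp[ycol].to_numpy()
            corr_rows.append(_spearman_row(itype, metric, x, y))
    correlations = pd.DataFrame(corr_rows)
    return CTNumberReport(per_roi=per_roi, per_pair=per_pair, table=table,
                          correlations=correlations)


def _spearman_row(itype: str, metric: str, x: np.ndarray,
                  y: np.ndarray) -> dict:
    finite = np.isfinite(x) & np.isfinite(y)
    row = {"image_type": itype, "metric": metric, "n": int(finite.sum()),
           "rho": math.nan, "rho_squared": math.nan, "p": math.nan,
           "defined": False}
    xs, ys = x[finite], y[finite]
    if len(xs) >= 4 and np.ptp(xs) > 0 and np.ptp(ys) > 0:
        rho, r2, p = ast.spearman(xs, ys)
        row.update(rho=rho, rho_squared=r2, p=p, defined=True)
    return row


# ---------------------------------------------------------------------------
# reporting


def report(result: StudyResult, out_dir: str | os.PathLike) -> list[str]:
    """Write the CSV/JSON report mirroring the study's table layouts."""
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    files = {
        "table2_analog.csv": result.dispersion.class_table,
        "table3_analog.csv": result.pairwise.class_table,
        "table4_analog.csv": result.ct_report.table,
        "feature_heatmap.csv": result.dispersion.heatmap,
        "per_roi_reproducibility.csv": result.dispersion.per_roi,
        "per_pair_reproducibility.csv": result.pairwise.per_pair,
        "repeatability_per_platform.csv": result.repeatability.per_platform,
        "repeatability_per_feature.csv": result.repeatability.per_feature,
        "top_features.csv": result.pairwise.top_features,
        "shortlist_report.csv": result.pairwise.shortlist,
        "ct_correlations.csv": result.ct_report.correlations,
        "registration_log.csv": result.registration,
    }
    written = []
    for name, df in files.items():
        path = os.path.join(out, name)
        df.to_csv(path, index=False)
        written.append(path)
    summary = {
        "seed": result.seed,
        "config_hash": result.config.hash(),
        "config": result.config.to_dict(),
        "n_scans": int(len(result.manifest)),
        "n_feature_records": int(len(result.features)),
        "repeatability_rollup": result.repeatability.rollup.to_dict("records"),
        "dispersion_rollup": result.dispersion.rollup.to_dict("records"),
        "pairwise_rollup": result.pairwise.rollup.to_dict("records"),
        "ct_table": result.ct_report.table.to_dict("records"),
        "ct_correlations": result.ct_report.correlations.to_dict("records"),
    }
    spath = os.path.join(out, "run_summary.json")
    with open(spath, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
    written.append(spath)
    cpath = os.path.join(out, "config_frozen.yaml")
    result.config.to_yaml(cpath)
    written.append(cpath)
    return written


# ---------------------------------------------------------------------------
# orchestration


def run_full_study(config: StudyConfig, seed: int,
                   out_dir: str | os.PathLike | None = None,
                   write_images: bool = False) -> StudyResult:
    """Simulate the study, extract features, run every analysis.

    With ``out_dir`` set, writes the report CSVs (and the NIfTI images
    when ``write_images`` is also set).  Fully deterministic in
    (config, seed).
    """
    spec = ph.default_phantom_spec()
    platforms = ph.default_platform_models(
        config.n_platforms, seed, config.spread_hu,
        vue_spread_factor=config.vue_spread_factor,
        bias_sd_hu=config.bias_sd_hu, noise_sd_hu=config.noise_sd_hu,
        kernel_fwhm_px=config.kernel_fwhm_px,
        kernel_jitter=config.kernel_jitter,
        insert_spread_scale=config.insert_spread_scale or None)
    images_dir = None
    if out_dir is not None and write_images:
        images_dir = os.path.join(os.fspath(out_dir), "images")
    manifest, scans = ph.simulate_study(spec, platforms, config.image_types,
                                        config.n_repeats, seed,
                                        out_dir=images_dir)
    features, registration = build_feature_table(scans, spec, config)
    fx.validate_feature_table(features)
    rep = run_repeatability(features, cutoff=config.repeatability_cutoff)
    disp = run_dispersion(features, config.repeat_policy,
                          config.dispersion_cutoff_pct)
    pair = run_pairwise(features, config.repeat_policy,
                        config.agreement_cutoff, config.top_k,
                        config.shortlist)
    ct = run_ct_analysis(features, dispersion=disp, pairwise=pair,
                         repeat_policy=config.repeat_policy,
                         cutoff_pct=config.dispersion_cutoff_pct,
                         cutoff_agreement=config.agreement_cutoff)
    result = StudyResult(config=config, seed=seed, manifest=manifest,
                         registration=registration, features=features,
                         repeatability=rep, dispersion=disp, pairwise=pair,
                         ct_report=ct)
    if out_dir is not None:
        report(result, out_dir)
    return result
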