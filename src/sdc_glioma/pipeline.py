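"""End-to-end run configuration, report assembly and stage orchestration.

One declarative config drives the whole chain: (optional) phantom/cohort
simulation -> metric maps -> ROI statistics -> cohort statistics ->
ROC/cutoff tables -> genotype model.  Every run writes its resolved config
next to its outputs, a machine-readable JSON report (versioned schema) and a
human-readable Markdown summary.  Identical config + seed gives identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as dio
from . import metrics as dm
from . import model as gm
from . import stats as dst
from . import synthetic as syn
from .roc import roc as roc_analysis, cutoff_table, cutoff_table_frame

log = logging.getLogger("sdc_glioma")

REPORT_SCHEMA_VERSION = "1"

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration (caught before any computation)."""


@dataclasses.dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Default b-value pairs: SDC 500/750, DDVD 0/10, ADC 0/1000 s/mm^2.
    When ``dwi`` (and ``bval``) are unset, a phantom is simulated; when
    ``cohort`` is unset, a calibrated synthetic cohort is simulated.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    dwi: str | None = None
    bval: str | None = None
    mask: str | None = None
    exclusion_mask: str | None = None
    cohort: str | None = None
    sdc_b: tuple[float, float] = dm.SDC_B
    ddvd_b: tuple[float, float] = dm.DDVD_B
    adc_b: tuple[float, float] = dm.ADC_B
    label: str = "idh_gene"
    exclude_partial: bool = False
    thresholds: list[float] | None = None
    phantom_snr: float = 50.0

    def validate(self) -> None:
        for name, (b1, b2) in (("sdc", self.sdc_b), ("ddvd", self.ddvd_b),
                               ("adc", self.adc_b)):
            if not b1 < b2:
                raise ConfigError(
                    f"{name} b-pair must be increasing, got ({b1:g}, {b2:g})")
        if self.label not in ("idh_gene", "idh_ihc"):
            raise ConfigError(f"unknown label column {self.label!r}")
        if (self.dwi is None) != (self.bval is None):
            raise ConfigError("dwi and bval must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for f in ("sdc_b", "ddvd_b", "adc_b"):
            setattr(cfg, f, tuple(float(v) for v in getattr(cfg, f)))
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for f in ("sdc_b", "ddvd_b", "adc_b"):
            d[f] = list(d[f])
        return d


def _stage_simulate(cfg: RunConfig, out: Path) -> dict[str, Any]:
    info: dict[str, Any] = {}
    if cfg.dwi is None:
        spec = syn.default_phantom_spec(snr=cfg.phantom_snr, seed=cfg.seed)
        paths = syn.write_phantom(spec, out / "phantom")
        cfg.dwi = str(paths["dwi"])
        cfg.bval = str(paths["bval"])
        info["phantom"] = {
            "dwi": cfg.dwi, "bval": cfg.bval,
            "labels": str(paths["labels"]),
            "shape": list(spec.shape), "snr": cfg.phantom_snr,
        }
        log.info("simulated phantom -> %s", paths["dwi"])
    if cfg.cohort is None:
        cpath = out / "cohort.csv"
        syn.write_cohort(syn.default_cohort_spec(seed=cfg.seed), cpath)
        cfg.cohort = str(cpath)
        info["cohort"] = {"path": cfg.cohort}
        log.info("simulated cohort -> %s", cpath)
    return info


def _stage_maps(cfg: RunConfig, out: Path) -> tuple[dm.MetricMaps,
                                                    dio.DWISeries,
                                                    dict[str, Any]]:
    series = dio.load_series(cfg.dwi, cfg.bval)
    maps = dm.compute_maps(series, cfg.sdc_b, cfg.ddvd_b, cfg.adc_b)
    mdir = out / "maps"
    mdir.mkdir(parents=True, exist_ok=True)
    dio.save_map(maps.sdc, maps.affine, mdir / "sdc.nii.gz", unit="au/s")
    dio.save_map(maps.ddvd, maps.affine, mdir / "ddvd.nii.gz",
                 unit="au/pixel")
    dio.save_map(maps.adc, maps.affine, mdir / "adc.nii.gz", unit="mm2/s")
    info = {
        "b_values": series.b_values.tolist(),
        "sdc_b": list(cfg.sdc_b), "ddvd_b": list(cfg.ddvd_b),
        "adc_b": list(cfg.adc_b),
        "maps_dir": str(mdir),
        "adc_invalid_voxels": int((~maps.adc_valid).sum()),
    }
    log.info("metric maps written to %s (b-pairs sdc=%s ddvd=%s adc=%s)",
             mdir, cfg.sdc_b, cfg.ddvd_b, cfg.adc_b)
    return maps, series, info


def _stage_roi(cfg: RunConfig, maps: dm.MetricMaps, series: dio.DWISeries,
               out: Path, sim_info: dict[str, Any]) -> dict[str, Any]:
    rois: dict[str, dio.ROIMask] = {}
    if cfg.mask is not None:
        rois["roi"] = dio.load_mask(cfg.mask, series, cfg.exclusion_mask)
    elif "phantom" in sim_info:
        labels = np.asarray(
            __import__("nibabel").load(sim_info["phantom"]["labels"])
            .get_fdata()).astype(int)
        for name, lab in (("wildtype_like", syn.WILDTYPE_LIKE),
                          ("mutant_like", syn.MUTANT_LIKE)):
            rois[name] = dio.ROIMask(mask=labels == lab,
                                     affine=series.affine)
    info: dict[str, Any] = {}
    for name, roi in rois.items():
        st = dm.roi_aggregate(maps, roi)
        info[name] = {
            "n_voxels": st.n_voxels,
            "n_excluded": st.n_excluded,
            "sdc_au_per_s": st.triplet.sdc,
            "ddvd_au_per_pixel": st.triplet.ddvd,
            "adc_e4_mm2_per_s": st.triplet.adc,
        }
    return info


def _stage_cohort_stats(df, cfg: RunConfig) -> dict[str, Any]:
    info: dict[str, Any] = {"groups": {}, "tests": {}, "correlations": {}}
    metrics = list(syn.METRIC_COLS)
    for m in metrics:
        info["groups"][m] = dst.group_summary(df, m, "group").to_dict(
            orient="records")
    g0 = df[df.idh_gene == 0]
    g1 = df[df.idh_gene == 1]
    for m in metrics:
        r = dst.mann_whitney(g0[m], g1[m])
        info["tests"][f"mann_whitney_{m}"] = {
            "u": r.u, "p": r.p, "method": r.method, "n": [r.n1, r.n2]}
    graded = df[df.grade.astype(str).isin(["2", "3", "4"])]
    if graded.grade.astype(str).nunique() >= 2:
        h, p = dst.kruskal_wallis(*[
            grp["sdc_au_per_s"].to_numpy()
            for _, grp in graded.groupby(graded.grade.astype(str))])
        info["tests"]["kruskal_wallis_sdc_by_grade"] = {
            "h": h, "p": p,
            "n_per_grade": graded.grade.astype(str).value_counts()
            .sort_index().to_dict()}
    pairs = [("sdc_au_per_s", "adc_e4_mm2_per_s"),
             ("sdc_au_per_s", "ddvd_au_per_pixel"),
             ("sdc_au_per_s", "ki67_pct")]
    for a, b in pairs:
        c = dst.pearson(df[a], df[b])
        info["correlations"][f"{a}~{b}"] = {
            "r": c.r, "ci": [c.ci_low, c.ci_high], "p": c.p, "n": c.n}
    return info


def _stage_roc(df, cfg: RunConfig) -> dict[str, Any]:
    info: dict[str, Any] = {"auc": {}, "cutoff_table_sdc": None}
    y = df[cfg.label].to_numpy(dtype=float)
    sub = df
    if cfg.label == "idh_ihc" or cfg.exclude_partial:
        keep = y != 0.5
        sub, y = df.loc[keep], y[keep]
    y = y.astype(int)
    for m in syn.METRIC_COLS:
        direction = "less" if m == "ddvd_au_per_pixel" else "greater"
        r = roc_analysis(sub[m], y, positive_direction=direction)
        info["auc"][m] = {"auc": r.auc, "direction": direction}
    rows = cutoff_table(sub["sdc_au_per_s"], y,
                        thresholds=cfg.thresholds,
                        ci_method="wilson_brown")
    info["cutoff_table_sdc"] = cutoff_table_frame(rows).replace(
        [np.inf], "inf").to_dict(orient="records")
    return info


def _stage_model(df, cfg: RunConfig) -> dict[str, Any]:
    info: dict[str, Any] = {}
    fit = gm.fit_logistic(df, label=cfg.label,
                          exclude_partial=cfg.exclude_partial
                          or cfg.label == "idh_ihc")
    info["fitted"] = {
        "coefficients": {
            "beta_sdc": fit.coeffs.beta_sdc,
            "beta_ddvd": fit.coeffs.beta_ddvd,
            "beta_adc": fit.coeffs.beta_adc,
            "intercept": fit.coeffs.intercept,
        },
        "se": fit.se, "converged": fit.converged,
        "n": fit.n, "n_positive": fit.n_positive,
        "auc_in_sample": fit.auc_in_sample,
    }
    cls = gm.classify_cohort(df, gm.REFERENCE_MODEL)
    info["reference_model"] = {
        "name": gm.REFERENCE_MODEL.name,
        "n_predicted_positive": int(cls.predicted_class.sum()),
        "mean_probability": float(cls.probability.mean()),
    }
    return info


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns and writes the JSON report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "stages": {},
    }
    stage = "simulate"
    try:
        report["stages"]["simulate"] = _stage_simulate(cfg, out)
        stage = "maps"
        maps, series, info = _stage_maps(cfg, out)
        report["stages"]["maps"] = info
        stage = "roi_stats"
        report["stages"]["roi_stats"] = _stage_roi(
            cfg, maps, series, out, report["stages"]["simulate"])
        stage = "cohort_stats"
        df = dio.load_cohort(cfg.cohort)
        report["stages"]["cohort_stats"] = _stage_cohort_stats(df, cfg)
        stage = "roc_cutoffs"
        report["stages"]["roc_cutoffs"] = _stage_roc(df, cfg)
        stage = "genotype_model"
        report["stages"]["genotype_model"] = _stage_model(df, cfg)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report["config"] = cfg.to_dict()
    _validate_report(report)
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "report.md").write_text(_markdown_report(report))
    return report


def _validate_report(report: dict[str, Any]) -> None:
    required = {"simulate", "maps", "roi_stats", "cohort_stats",
                "roc_cutoffs", "genotype_model"}
    missing = required - set(report["stages"])
    if missing:
        raise RuntimeError(f"report missing stage sections: {missing}")
    json.dumps(report)   # must be serializable


def _markdown_report(report: dict[str, Any]) -> str:
    st = report["stages"]
    lines = ["# Diffusion-metric pipeline report", ""]
    lines.append("## Metric maps")
    lines.append(f"- b-values: {st['maps']['b_values']}")
    lines.append(f"- SDC b-pair: {st['maps']['sdc_b']}, "
                 f"DDVD: {st['maps']['ddvd_b']}, ADC: {st['maps']['adc_b']}")
    lines.append("")
    lines.append("## ROI statistics")
    for name, r in st["roi_stats"].items():
        lines.append(
            f"- {name}: SDC {r['sdc_au_per_s']:.3f} au/s, "
            f"DDVD {r['ddvd_au_per_pixel']:.1f} au/pixel, "
            f"ADC {r['adc_e4_mm2_per_s']:.2f} x1e-4 mm2/s "
            f"({r['n_voxels']} voxels)")
    lines.append("")
    lines.append("## Group comparisons")
    for t, r in st["cohort_stats"]["tests"].items():
        lines.append(f"- {t}: p = {r['p']:.3g}")
    lines.append("")
    lines.append("## Correlations")
    for pair, c in st["cohort_stats"]["correlations"].items():
        lines.append(f"- {pair}: r = {c['r']:.3f} "
                     f"(95% CI {c['ci'][0]:.3f} to {c['ci'][1]:.3f}, "
                     f"p = {c['p']:.3g})")
    lines.append("")
    lines.append("## ROC")
    for m, r in st["roc_cutoffs"]["auc"].items():
        lines.append(f"- {m}: AUC = {r['auc']:.3f} ({r['direction']})")
    lines.append("")
    lines.append("## Genotype model")
    fitted = st["genotype_model"]["fitted"]
    co = fitted["coefficients"]
    lines.append(
        f"- fitted: beta_sdc {co['beta_sdc']:.3f}, beta_ddvd "
        f"{co['beta_ddvd']:.3f}, beta_adc {co['beta_adc']:.3f}, intercept "
        f"{co['intercept']:.3f}; in-sample AUC {fitted['auc_in_sample']:.3f}")
    return "\n".join(lines) + "\n"
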