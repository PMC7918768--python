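"""End-to-end pipeline: simulate -> extract -> analyze.

The pipeline renders a synthetic cohort of muscle PDFF phantoms, extracts
mean PDFF plus the 3 global and 8 co-occurrence texture features per
(subject, muscle group, side), and runs the statistical layer: a
covariate-adjusted single-feature screen (one row per feature x outcome,
with adjusted R^2, feature p-value and Bonferroni flag), SPSS-style
stepwise model building per outcome, and sex-group comparisons.

Configuration is a YAML file with one block per stage; unknown keys are
rejected so typos cannot silently fall back to defaults.  The resolved
configuration and a log (per-stage timings, the 13-direction list, and the
quantizer window per muscle) are written into every run directory, and
re-running with an identical configuration reproduces every CSV
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .glcm import DIRECTIONS, FEATURE_NAMES, rotation_invariant_features
from .histfeat import global_features
from .preprocess import (
    PDFFVolume,
    ROIMask,
    extract_roi_values,
    mean_pdff,
    quantize,
    resample_isotropic,
)
from .stats import (
    adjusted_single_feature_regression,
    bonferroni_flags,
    encode_design,
    stepwise_regression,
    unpaired_ttest,
)
from .synthetic import CohortSpec, EffectSizes, PhantomSpec, generate_cohort

TEXTURE_COLUMNS = (
    "variance_global",
    "skewness_global",
    "kurtosis_global",
) + FEATURE_NAMES  # 3 global + 8 second-order = 11 texture features

FEATURE_COLUMNS = ("pdff",) + TEXTURE_COLUMNS  # + mean PDFF = 12 per muscle


@dataclass(frozen=True)
class QuantizerConfig:
    n_levels: int = 200
    window: str = "roi"  # 'roi' or 'fixed' ([0, 100]%)


@dataclass(frozen=True)
class GLCMConfig:
    log_base: float = 2.0
    weighting: str = "uniform"  # or 'inverse_length'
    mode: str = "averaged"  # or 'pooled'


@dataclass(frozen=True)
class ResampleConfig:
    enabled: bool = True
    target_mm: float = 2.0


@dataclass(frozen=True)
class StatsConfig:
    p_enter: float = 0.05
    p_remove: float = 0.10
    bonferroni_m: int = 12
    alpha: float = 0.05
    equal_var: bool = True  # pooled-variance t-test; False = Welch
    cluster_robust: bool = False  # cluster SEs on subject in the screen


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(pattern="streaks"))
    cohort: CohortSpec = field(default_factory=CohortSpec)
    quantizer: QuantizerConfig = field(default_factory=QuantizerConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            phantom=dataclasses.replace(self.phantom, seed=seed),
            cohort=dataclasses.replace(self.cohort, seed=seed),
        )


def _build(cls, data: dict, path: str):
    """Construct a (nested) config dataclass, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        sub = {
            "PhantomSpec": PhantomSpec,
            "CohortSpec": CohortSpec,
            "EffectSizes": EffectSizes,
            "QuantizerConfig": QuantizerConfig,
            "GLCMConfig": GLCMConfig,
            "ResampleConfig": ResampleConfig,
            "StatsConfig": StatsConfig,
        }.get(str(ftype).split(".")[-1].strip("'\" "))
        if isinstance(value, dict) and sub is not None:
            kwargs[name] = _build(sub, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(PipelineConfig, data, "config")


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def extract_features_single(
    vol: PDFFVolume, mask: ROIMask, cfg: PipelineConfig
) -> dict[str, float]:
    """All 12 per-muscle features (mean PDFF + 3 global + 8 GLCM)."""
    if cfg.resample.enabled:
        vol, mask = resample_isotropic(vol, mask, cfg.resample.target_mm)
    values = extract_roi_values(vol, mask)
    out: dict[str, float] = {"pdff": mean_pdff(values)}
    gf = global_features(values)
    out["variance_global"] = gf.variance_global
    out["skewness_global"] = gf.skewness_global
    out["kurtosis_global"] = gf.kurtosis_global
    q = quantize(vol, mask, Ng=cfg.quantizer.n_levels, window=cfg.quantizer.window)
    sof = rotation_invariant_features(
        q,
        log_base=cfg.glcm.log_base,
        weighting=cfg.glcm.weighting,
        mode=cfg.glcm.mode,
    )
    out.update(sof.as_dict())
    return out


def _check_outputs(outdir: Path, names: list[str], overwrite: bool) -> None:
    stale = [n for n in names if (outdir / n).exists()]
    if stale and not overwrite:
        raise FileExistsError(
            f"outputs already exist in {outdir}: {stale}; pass overwrite to redo"
        )


def stage_simulate(cfg: PipelineConfig, outdir: str | Path,
                   overwrite: bool = False) -> Path:
    """Render the cohort: NIfTI map/mask pairs + cohort.csv + truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_outputs(outdir, ["cohort.csv", "phantoms"], overwrite)
    res = generate_cohort(cfg.cohort, cfg.phantom, render_phantoms=True)
    pdir = outdir / "phantoms"
    pdir.mkdir(exist_ok=True)
    for (sid, group, side), (vol, mask) in res.phantoms.items():
        stem = f"{sid}_{group.lower()}_{side}"
        mio.save_volume(vol, pdir / f"{stem}_pdff.nii.gz")
        mio.save_mask(mask, pdir / mio.mask_filename(sid, group, side),
                      spacing_mm=vol.spacing_mm)
    res.table.to_csv(outdir / "cohort.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(res.truth, fh, indent=2)
    return outdir


def stage_extract(cfg: PipelineConfig, outdir: str | Path,
                  overwrite: bool = False,
                  log_lines: list[str] | None = None) -> Path:
    """Compute the per-muscle feature table from the phantom directory."""
    outdir = Path(outdir)
    _check_outputs(outdir, ["features.csv"], overwrite)
    pdir = outdir / "phantoms"
    rows = []
    for map_path in sorted(pdir.glob("*_pdff.nii.gz")):
        stem = map_path.name[: -len("_pdff.nii.gz")]
        sid, group, side = stem.rsplit("_", 2)
        vol = mio.load_volume(map_path)
        mask = mio.load_mask(pdir / mio.mask_filename(sid, group, side))
        mask = ROIMask(mask.values, group.upper(), side)
        feats = extract_features_single(vol, mask, cfg)
        if log_lines is not None:
            vals = extract_roi_values(*resample_isotropic(
                vol, mask, cfg.resample.target_mm
            ) if cfg.resample.enabled else (vol, mask))
            log_lines.append(
                f"quantizer window {stem}: [{vals.min():.4f}, {vals.max():.4f}] %"
            )
        rows.append(
            {"subject_id": sid, "muscle_group": group.upper(), "side": side, **feats}
        )
    feat = pd.DataFrame(rows).sort_values(
        ["subject_id", "muscle_group", "side"], kind="mergesort"
    )
    feat.to_csv(outdir / "features.csv", index=False)
    return outdir


def build_analysis_table(cohort: pd.DataFrame, feat: pd.DataFrame) -> pd.DataFrame:
    """Side-matched wide table: one row per (subject, side), per-group columns."""
    wide = cohort.copy()
    for group, suffix in (("EXT", "_ext"), ("FLEX", "_flex")):
        sub = feat[feat["muscle_group"] == group].drop(columns=["muscle_group"])
        sub = sub.rename(
            columns={c: c + suffix for c in FEATURE_COLUMNS}
        )
        wide = wide.merge(sub, on=["subject_id", "side"], how="inner")
    return encode_design(wide)


def stage_analyze(cfg: PipelineConfig, outdir: str | Path,
                  overwrite: bool = False) -> Path:
    """Feature screen, stepwise models, and sex comparisons -> CSV reports."""
    outdir = Path(outdir)
    _check_outputs(
        outdir,
        ["table1.csv", "stepwise_ext.csv", "stepwise_flex.csv",
         "group_comparison.csv", "stepwise_report.txt"],
        overwrite,
    )
    cohort = pd.read_csv(outdir / "cohort.csv")
    feat = pd.read_csv(outdir / "features.csv")
    tbl = build_analysis_table(cohort, feat)
    cluster = "subject_id" if cfg.stats.cluster_robust else None

    # single-feature screen (one row per feature x outcome)
    screen_rows = []
    for outcome, suffix in (("mvic_ext", "_ext"), ("mvic_flex", "_flex")):
        pvals = []
        for base in FEATURE_COLUMNS:
            col = base + suffix
            res = adjusted_single_feature_regression(
                tbl, outcome, col, cluster_by=cluster
            )
            pvals.append(res.pvalues[col])
            screen_rows.append(
                {
                    "feature": base,
                    "outcome": outcome,
                    "coef": res.params[col],
                    "r2_adj": res.r2_adj,
                    "p": res.pvalues[col],
                }
            )
        flags = bonferroni_flags(
            np.array(pvals), m=cfg.stats.bonferroni_m, alpha=cfg.stats.alpha
        )
        for row, flag in zip(screen_rows[-len(FEATURE_COLUMNS):], flags):
            row["bonferroni_significant"] = bool(flag)
    table1 = pd.DataFrame(screen_rows)
    table1.to_csv(outdir / "table1.csv", index=False)

    # stepwise per outcome
    report_lines = []
    for outcome, suffix in (("mvic_ext", "_ext"), ("mvic_flex", "_flex")):
        candidates = ["sex_male", "side_right", "age", "bmi"] + [
            base + suffix for base in FEATURE_COLUMNS
        ]
        sw = stepwise_regression(
            tbl, outcome, candidates,
            p_enter=cfg.stats.p_enter, p_remove=cfg.stats.p_remove,
        )
        pd.DataFrame(sw.log).to_csv(
            outdir / f"stepwise_{suffix[1:]}.csv", index=False
        )
        report_lines.append(f"== stepwise model for {outcome} ==")
        for entry in sw.log:
            report_lines.append(
                f"  step {entry['step']}: {entry['action']} {entry['term']}"
                f" (p={entry['p']:.4g})"
            )
        report_lines.append(f"  selected: {sw.selected or '(none)'}")
        report_lines.append(
            f"  R2_adj = {sw.final.r2_adj:.4f}, model p = {sw.final.p_model:.4g}"
        )
    (outdir / "stepwise_report.txt").write_text("\n".join(report_lines) + "\n")

    # sex-group comparison per side
    comp_rows = []
    compare_cols = ["age", "bmi", "mvic_ext", "mvic_flex"] + [
        b + s for s in ("_ext", "_flex") for b in FEATURE_COLUMNS
    ]
    for side in ("left", "right"):
        sub = tbl[tbl["side"] == side]
        males = sub[sub["sex_male"] == 1]
        females = sub[sub["sex_male"] == 0]
        for col in compare_cols:
            a, b = males[col].to_numpy(), females[col].to_numpy()
            if np.std(a) == 0 and np.std(b) == 0:
                continue
            tt = unpaired_ttest(a, b, equal_var=cfg.stats.equal_var)
            comp_rows.append(
                {
                    "side": side,
                    "variable": col,
                    "mean_male": tt.mean_a,
                    "sd_male": tt.sd_a,
                    "mean_female": tt.mean_b,
                    "sd_female": tt.sd_b,
                    "t": tt.t,
                    "p": tt.p,
                }
            )
    pd.DataFrame(comp_rows).to_csv(outdir / "group_comparison.csv", index=False)
    return outdir


def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 overwrite: bool = False) -> Path:
    """simulate -> extract -> analyze, with resolved config and run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"master seed: {cfg.seed}",
                 f"directions (13): {list(DIRECTIONS)}"]
    t0 = time.perf_counter()
    stage_simulate(cfg, outdir, overwrite=overwrite)
    t1 = time.perf_counter()
    log_lines.append(f"simulate: {t1 - t0:.2f} s")
    stage_extract(cfg, outdir, overwrite=overwrite, log_lines=log_lines)
    t2 = time.perf_counter()
    log_lines.append(f"extract: {t2 - t1:.2f} s")
    stage_analyze(cfg, outdir, overwrite=overwrite)
    t3 = time.perf_counter()
    log_lines.append(f"analyze: {t3 - t2:.2f} s")
    dump_config(cfg, outdir / "resolved_config.yaml")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
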