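"""Configuration-driven orchestration: simulate -> preprocess -> quantify ->
stats -> classify, with seeded reproducibility and a run report.

A :class:`RunConfig` describes exactly one input source -- either a synthetic
cohort configuration or a directory of measured image matrices -- plus the
parameters of every stage.  :func:`run_pipeline` executes the stages in
order, writes every intermediate table as CSV into the output directory, and
returns a :class:`RunReport`.  Every random stage consumes a stage-specific
child seed spawned from the global seed, so a config maps to bit-identical
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bands as bq
from . import preprocess as pp
from . import splsda as sx
from . import stats as st
from . import synthesis as syn
from .spectra import (
    CohortTable,
    SpectraError,
    Spectrum,
    read_cohort_metadata,
    read_spectral_matrix,
    write_cohort_metadata,
    write_spectral_matrix,
)

__all__ = ["RunConfig", "RunReport", "ConfigError", "StageError", "validate_config", "run_pipeline"]

CSV_FLOAT_FORMAT = "%.12g"

DEFAULT_PEAK_REGIONS = ("Amide I", "Amide II", "Amide A", "Acyl chain")


class ConfigError(SpectraError):
    """Invalid run configuration; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid configuration:\n- " + "\n- ".join(errors))
        self.errors = errors


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and offending sample."""

    def __init__(self, stage: str, sample_id: str | None, cause: Exception):
        where = f"stage {stage!r}" + (f", sample {sample_id!r}" if sample_id else "")
        super().__init__(f"{where}: {cause}")
        self.stage, self.sample_id = stage, sample_id


@dataclass
class RunConfig:
    synthetic: syn.SyntheticCohortConfig | None = None
    input_dir: Path | None = None
    preprocess: pp.PreprocessParams = field(default_factory=pp.PreprocessParams)
    peak_regions: tuple[str, ...] = DEFAULT_PEAK_REGIONS
    bh_adjust: bool = False
    tune: bool = True
    n_components: int = 3
    keep_x: tuple[int, ...] = (60, 40, 20)
    grid: tuple[int, ...] = sx.DEFAULT_KEEPX_GRID
    folds: int = 3
    #: CV repeats; the desk-scale default is 50 (raise to 200 for the full
    #: protocol with one flag).
    repeats: int = 50
    seed: int = 0
    outdir: Path = Path("fibrospec_out")
    #: raw image cubes are large; written only on request
    write_images: bool = False


@dataclass
class RunReport:
    config_echo: dict
    stage_counts: dict
    ratio_summary: dict
    tuning: dict
    auroc: dict
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1, default=str)

    def to_text(self) -> str:
        lines = ["fibrospec run report", "=" * 40]
        lines.append("stage counts:")
        for k, v in self.stage_counts.items():
            lines.append(f"  {k}: {v}")
        lines.append("ratio panel:")
        for k, v in self.ratio_summary.items():
            lines.append(f"  {k}: {v}")
        lines.append(f"tuning: {self.tuning}")
        lines.append("per-class AUROC:")
        for k, v in self.auroc.items():
            lines.append(f"  {k}: {v:.4f}")
        if self.warnings:
            lines.append(f"warnings ({len(self.warnings)}):")
            lines += [f"  {w}" for w in self.warnings]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# config loading / validation


def _build_dataclass(cls, data: dict, errors: list[str], context: str):
    try:
        return cls(**data)
    except (TypeError, SpectraError) as exc:
        errors.append(f"{context}: {exc}")
        return None


def validate_config(source=None, seed: int | None = None, outdir=None) -> RunConfig:
    """Normalize a YAML/JSON document (path, dict, or None) into a RunConfig.

    Violations are collected -- the raised :class:`ConfigError` lists every
    problem, not just the first.  An empty document yields the
    defaults-complete synthetic run configuration.
    """
    if source is None:
        doc = {}
    elif isinstance(source, dict):
        doc = dict(source)
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ConfigError([f"config root must be a mapping, got {type(doc).__name__}"])

    errors: list[str] = []
    known = {
        "synthetic", "input_dir", "preprocess", "peak_regions", "stats",
        "chemometrics", "seed", "outdir", "write_images",
    }
    for key in doc:
        if key not in known:
            errors.append(f"unknown top-level key {key!r}")

    if "input_dir" in doc and "synthetic" in doc:
        errors.append("exactly one input source allowed: input_dir XOR synthetic")

    global_seed = int(doc.get("seed", 0) if seed is None else seed)

    synthetic = None
    input_dir = None
    if "input_dir" in doc:
        input_dir = Path(doc["input_dir"])
        if not input_dir.exists():
            errors.append(f"input_dir {input_dir} does not exist")
        elif not (input_dir / "metadata.csv").exists():
            errors.append(f"input_dir {input_dir} lacks metadata.csv")
        elif not (input_dir / "reference.csv").exists():
            errors.append(f"input_dir {input_dir} lacks reference.csv")
    else:
        sdoc = dict(doc.get("synthetic") or {})
        sdoc.setdefault("seed", global_seed)
        synthetic = _build_dataclass(syn.SyntheticCohortConfig, sdoc, errors, "synthetic")

    pdoc = dict(doc.get("preprocess") or {})
    for sub, cls in (("smooth", pp.SGParams), ("deriv", pp.SGParams), ("scatter", pp.ScatterParams)):
        if sub in pdoc and isinstance(pdoc[sub], dict):
            built = _build_dataclass(cls, pdoc[sub], errors, f"preprocess.{sub}")
            if built is None:
                pdoc.pop(sub)
            else:
                pdoc[sub] = built
    params = _build_dataclass(pp.PreprocessParams, pdoc, errors, "preprocess")

    cdoc = dict(doc.get("chemometrics") or {})
    sdoc2 = dict(doc.get("stats") or {})

    cfg = None
    if not errors:
        cfg = RunConfig(
            synthetic=synthetic,
            input_dir=input_dir,
            preprocess=params,
            peak_regions=tuple(doc.get("peak_regions", DEFAULT_PEAK_REGIONS)),
            bh_adjust=bool(sdoc2.get("bh_adjust", False)),
            tune=bool(cdoc.get("tune", True)),
            n_components=int(cdoc.get("n_components", 3)),
            keep_x=tuple(cdoc.get("keep_x", (60, 40, 20))),
            grid=tuple(cdoc.get("grid", sx.DEFAULT_KEEPX_GRID)),
            folds=int(cdoc.get("folds", 3)),
            repeats=int(cdoc.get("repeats", 50)),
            seed=global_seed,
            outdir=Path(outdir if outdir is not None else doc.get("outdir", "fibrospec_out")),
            write_images=bool(doc.get("write_images", False)),
        )
        errors.extend(_cross_field_errors(cfg))
    if errors:
        raise ConfigError(errors)
    return cfg


def _cross_field_errors(cfg: RunConfig) -> list[str]:
    errors = []
    if cfg.synthetic is not None:
        s, q = cfg.synthetic, cfg.preprocess
        if not (s.axis_lo < q.excise_lo < q.excise_hi < s.axis_hi):
            errors.append(
                f"excise interval [{q.excise_lo}, {q.excise_hi}] must lie strictly "
                f"inside the axis span [{s.axis_lo}, {s.axis_hi}]"
            )
        else:
            # variable count the classifier will see, after excision/binning
            axis = s.axis()
            n = int(np.sum((axis.values < q.excise_lo) | (axis.values > q.excise_hi)))
            if q.bin_mode == "spectral":
                n = int(np.ceil(n / q.bin_factor))
            for k in list(cfg.keep_x) + list(cfg.grid):
                if k > n:
                    errors.append(f"keep_x/grid entry {k} exceeds the {n} available variables")
                    break
        names = {r.name for r in bq.default_band_table()}
        for r in cfg.peak_regions:
            if r not in names:
                errors.append(f"unknown peak region {r!r}")
    if cfg.folds < 2:
        errors.append("chemometrics.folds must be >= 2")
    if cfg.n_components < 1 or len(cfg.keep_x) < cfg.n_components:
        errors.append("keep_x must provide one entry per component")
    return errors


# ---------------------------------------------------------------------------
# stage helpers


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, float_format=CSV_FLOAT_FORMAT, index=index)


def _load_images(input_dir: Path):
    meta = read_cohort_metadata(input_dir / "metadata.csv")
    reference = read_spectral_matrix(input_dir / "reference.csv")
    if not isinstance(reference, Spectrum):
        raise SpectraError("reference.csv must hold a single spectrum")
    images = []
    for _, row in meta.iterrows():
        path = input_dir / f"{row.sample_id}.csv"
        if not path.exists():
            raise SpectraError(f"missing image file {path}")
        img = read_spectral_matrix(path)
        img.sample_id, img.group = str(row.sample_id), str(row.group)
        images.append(img)
    return images, meta, reference


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all outputs under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # -- stage: simulate / load ---------------------------------------
        stage = "simulate" if config.synthetic is not None else "load"
        try:
            if config.synthetic is not None:
                pairs, meta = syn.generate_cohort(config.synthetic)
                images = [img for img, _ in pairs]
                reference = syn.generate_reference_spectrum(config.synthetic.axis())
                truth = {
                    t.sample_id: {
                        "group": t.group,
                        "bio_factor": t.bio_factor,
                        "band_amplitudes": t.band_amplitudes,
                    }
                    for _, t in pairs
                }
                (out / "truth.json").write_text(
                    json.dumps(truth, sort_keys=True, indent=1) + "\n"
                )
            else:
                images, meta, reference = _load_images(config.input_dir)
            write_cohort_metadata(meta, out / "metadata.csv")
            write_spectral_matrix(reference, out / "reference.csv")
            if config.write_images:
                (out / "images").mkdir(exist_ok=True)
                for img in images:
                    write_spectral_matrix(img, out / "images" / f"{img.sample_id}.csv")
        except Exception as exc:
            raise StageError(stage, None, exc) from exc
        counts["samples"] = len(images)
        counts["pixels_per_image"] = images[0].n_pixels
        counts["axis_points"] = len(images[0].axis)

        # -- stage: preprocess --------------------------------------------
        records, infos = [], []
        for img in images:
            try:
                rec, info = pp.preprocess_sample(img, reference, config.preprocess)
            except Exception as exc:
                raise StageError("preprocess", img.sample_id, exc) from exc
            records.append(rec)
            infos.append(info)
        cohort = CohortTable(records)
        write_spectral_matrix(cohort, out / "records.csv")
        _write_csv(pd.DataFrame(infos, index=cohort.sample_ids), out / "preprocess_log.csv")
        counts["cell_pixels_mean"] = float(np.mean([i["n_cell_pixels"] for i in infos]))
        counts["points_after_binning"] = infos[0]["n_points_binned"]

        # -- stage: quantify ----------------------------------------------
        try:
            panel = bq.compute_ratio_panel(cohort)
            _write_csv(panel.values.rename_axis("sample_id"), out / "ratios.csv")
            regions = {r.name: r for r in bq.default_band_table()}
            peak_rows = []
            for rname in config.peak_regions:
                rep = bq.peak_report(cohort, regions[rname])
                for sid in cohort.sample_ids:
                    peak_rows.append(
                        {
                            "sample_id": sid,
                            "region": rname,
                            "count": rep.counts[sid],
                            "primary_position_cm1": rep.primary[sid],
                            "positions_cm1": ";".join(
                                f"{p:.2f}" for p in rep.positions[sid]
                            ),
                        }
                    )
            _write_csv(pd.DataFrame(peak_rows), out / "peaks.csv", index=False)
        except Exception as exc:
            raise StageError("quantify", None, exc) from exc
        counts["ratios"] = panel.values.shape[1]

        # -- stage: stats --------------------------------------------------
        try:
            _, stats_table = st.ratio_panel_stats(panel, bh_adjust=config.bh_adjust)
            _, diag_table = st.ratio_panel_diagnostics(panel)
            _write_csv(stats_table, out / "stats.csv")
            _write_csv(diag_table, out / "diagnostics.csv")
        except Exception as exc:
            raise StageError("stats", None, exc) from exc
        ratio_summary = {
            "n_ratios": int(stats_table.shape[0]),
            "n_anova_significant": int((stats_table["p_anova"] < 0.05).sum()),
        }

        # -- stage: classify ------------------------------------------------
        try:
            X = cohort.matrix("second_derivative")
            y = np.asarray(cohort.groups)
            wn = cohort.axis.values
            names = [f"{w:.2f}" for w in wn]
            children = np.random.SeedSequence(config.seed).spawn(2)
            tune_seed = int(children[0].generate_state(1)[0] % (2**31))
            cv_seed = int(children[1].generate_state(1)[0] % (2**31))
            if config.tune:
                tr = sx.tune_splsda(
                    X, y, grid=config.grid, n_components_max=config.n_components,
                    folds=config.folds, repeats=config.repeats, seed=tune_seed,
                )
                keep_x, n_comp = tr.keep_x, tr.n_components
                _write_csv(tr.table, out / "tuning.csv", index=False)
                tuning = {"n_components": n_comp, "keep_x": list(keep_x),
                          "error": tr.stage_errors[n_comp - 1]}
            else:
                keep_x = list(config.keep_x[: config.n_components])
                n_comp = config.n_components
                tuning = {"n_components": n_comp, "keep_x": list(keep_x), "error": None}
            res = sx.splsda_fit(X, y, n_comp, keep_x)
            artifacts = sx.export_model_artifacts(res, feature_names=names)
            art_scores = artifacts["scores"].copy()
            art_scores.insert(0, "sample_id", cohort.sample_ids)
            _write_csv(art_scores, out / "scores.csv", index=False)
            _write_csv(artifacts["loadings"], out / "loadings.csv", index=False)
            _write_csv(artifacts["correlations"], out / "correlations.csv", index=False)

            values = sx.cross_validated_values(
                X, y, n_comp, keep_x, folds=config.folds,
                repeats=max(1, config.repeats // 5), seed=cv_seed,
            )
            rocs = sx.one_vs_rest_auroc(values, y)
            _write_csv(
                pd.DataFrame(
                    [{"class": c, "auroc": r.auc} for c, r in rocs.items()]
                ),
                out / "auroc.csv", index=False,
            )
            model_doc = {
                "classes": res.classes_,
                "n_components": n_comp,
                "keep_x": list(keep_x),
                "explained_x_variance": [float(v) for v in res.explained_x_variance],
                "centroids": res.centroids.tolist(),
            }
            (out / "model.json").write_text(
                json.dumps(model_doc, sort_keys=True, indent=1) + "\n"
            )
        except Exception as exc:
            raise StageError("classify", None, exc) from exc

        caught = [str(w.message) for w in wrec]

    report = RunReport(
        config_echo=_echo(config),
        stage_counts=counts,
        ratio_summary=ratio_summary,
        tuning=tuning,
        auroc={c: r.auc for c, r in rocs.items()},
        warnings=caught,
    )
    (out / "report.json").write_text(report.to_json() + "\n")
    (out / "report.txt").write_text(report.to_text())
    return report


def _echo(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (dict,)):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (Path, frozenset)):
            return str(obj) if isinstance(obj, Path) else sorted(obj)
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return clean(config)
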