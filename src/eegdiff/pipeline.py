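"""End-to-end orchestration: simulate -> preprocess -> features -> stats
-> classification, with a provenance manifest.

A :class:`RunConfig` holds every tunable of every stage and round-trips
through JSON or TOML. ``run_all`` executes the stages in order, writes
each stage's outputs under the run directory, and records a manifest
with the config, per-stage bookkeeping counts, and output paths.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import classify, features, io, preprocess, stats_networks, synth


@dataclass
class RunConfig:
    """All pipeline parameters for one reproducible run."""

    out_dir: str = "eegdiff_run"
    # input: either simulate (cohort != None) or read an existing manifest
    simulate: bool = True
    manifest: str | None = None
    # scaled-down simulation defaults; the full-scale protocol values are
    # n_group_a=38, n_group_b=34, duration=600
    n_group_a: int = 10
    n_group_b: int = 10
    duration: float = 60.0
    # preprocessing
    target_fs: float = preprocess.DEFAULT_TARGET_FS
    broadband: tuple[float, float] = preprocess.DEFAULT_BROADBAND
    window: float = preprocess.DEFAULT_WINDOW
    step: float = preprocess.DEFAULT_STEP
    filter_order: int = preprocess.DEFAULT_ORDER
    # features
    fe_m: int = 2
    fe_r: float = 0.2
    fe_r_mode: str = "relative"
    edge_trim: float = features.DEFAULT_EDGE_TRIM
    families: tuple[str, ...] = features.FEATURE_FAMILIES
    # stats
    alpha: float = stats_networks.DEFAULT_ALPHA
    stats_unit: str = "epoch"
    fdr: bool = False
    # classification
    models: tuple[str, ...] = classify.MODEL_NAMES
    folds: int = classify.DEFAULT_FOLDS
    repeats: int = classify.DEFAULT_REPEATS
    split_unit: str = "epoch"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        if path.suffix == ".toml":
            import tomllib
            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        for key in ("broadband", "families", "models"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def full_protocol() -> RunConfig:
    """Full-scale protocol: 38 + 34 subjects, 600 s recordings, 10x5 CV."""
    return RunConfig(n_group_a=38, n_group_b=34, duration=600.0, repeats=10)


def run_all(config: RunConfig, cohort_config: synth.CohortConfig | None = None,
            ) -> Path:
    """Execute every stage; returns the run directory.

    A stage failure aborts with the stage name in the exception; the
    manifest written so far is marked incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.to_json()),
        "complete": False,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest_path = out / "manifest.json"

    def _write_manifest():
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    stage = "simulate"
    try:
        # --- stage 1: cohort -------------------------------------------
        if config.simulate:
            cc = cohort_config or synth.default_cohort_config(seed=config.seed)
            cc.n_group_a, cc.n_group_b = config.n_group_a, config.n_group_b
            cc.duration = config.duration
            cc.validate()
            recordings = synth.generate_cohort(cc)
            io.save_cohort(recordings, out / "cohort")
            manifest["stages"]["simulate"] = {
                "n_recordings": len(recordings),
                "manifest": str(out / "cohort" / "cohort.csv"),
            }
        else:
            if config.manifest is None:
                raise FileNotFoundError("no cohort manifest configured")
            recordings = io.load_cohort(config.manifest)
            manifest["stages"]["simulate"] = {
                "n_recordings": len(recordings), "manifest": config.manifest,
            }
        _write_manifest()

        # --- stage 2+3: preprocess + features --------------------------
        stage = "preprocess/features"
        fe_params = features.FEParams(m=config.fe_m, r=config.fe_r,
                                      r_mode=config.fe_r_mode)
        tables = []
        n_epochs = 0
        for rec in recordings:
            bands = preprocess.preprocess_recording(
                rec, target_fs=config.target_fs, broadband=config.broadband,
                window=config.window, step=config.step,
                order=config.filter_order)
            n_epochs += next(iter(bands.values())).n_epochs
            tables.append(features.build_feature_table(
                bands, fe_params=fe_params, edge_trim=config.edge_trim,
                families=config.families))
        table = pd.concat(tables, ignore_index=True)
        feat_path = io.save_feature_table(
            table, out / "features.csv",
            params={"fe_m": config.fe_m, "fe_r": config.fe_r,
                    "fe_r_mode": config.fe_r_mode,
                    "edge_trim": config.edge_trim,
                    "filter_order": config.filter_order,
                    "broadband": config.broadband})
        manifest["stages"]["features"] = {
            "n_epochs": n_epochs, "n_rows": len(table),
            "n_feature_columns": len(table.columns) - 3,
            "path": str(feat_path),
        }
        _write_manifest()

        # --- stage 4: statistics ---------------------------------------
        stage = "stats"
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        summary: dict = {}
        for family in ("PSD", "FE"):
            if family in config.families:
                res = stats_networks.difference_map(
                    table, family, alpha=config.alpha, unit=config.stats_unit,
                    fdr=config.fdr)
                stats_networks.diff_results_frame(res).to_csv(
                    stats_dir / f"diff_{family.lower()}.csv", index=False)
                summary[family] = sum(r.significant for r in res)
        if "PLI" in config.families:
            nets = stats_networks.differential_network(
                table, alpha=config.alpha, unit=config.stats_unit,
                fdr=config.fdr)
            for band, net in nets.items():
                pd.DataFrame(list(net.edges),
                             columns=["pair", "direction", "p_value"]).to_csv(
                    stats_dir / f"network_{band}.csv", index=False)
            summary["PLI_ratios"] = {b: n.ratio for b, n in nets.items()}
            if any(n.n_edges for n in nets.values()):
                summary["band_shares"] = stats_networks.key_connection_share(nets)
        (stats_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, default=str))
        manifest["stages"]["stats"] = {"summary": str(stats_dir / "summary.json")}
        _write_manifest()

        # --- stage 5: classification -----------------------------------
        stage = "classify"
        cv_kw = dict(models=config.models, k=config.folds,
                     repeats=config.repeats, seed=config.seed,
                     split_unit=config.split_unit)
        fam_reports = classify.feature_family_comparison(table, **cv_kw)
        rhy_reports = classify.rhythm_comparison(table, **cv_kw)
        classify.reports_frame(fam_reports).to_csv(
            out / "classification_by_family.csv", index=False)
        classify.reports_frame(rhy_reports).to_csv(
            out / "classification_by_rhythm.csv", index=False)
        manifest["stages"]["classify"] = {
            "by_family": str(out / "classification_by_family.csv"),
            "by_rhythm": str(out / "classification_by_rhythm.csv"),
            "n_reports": len(fam_reports) + len(rhy_reports),
        }

        manifest["complete"] = True
        manifest["config_hash"] = hashlib.sha256(
            config.to_json().encode()).hexdigest()[:16]
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_manifest()
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
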