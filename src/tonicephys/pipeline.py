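"""End-to-end orchestration: simulate -> features -> cluster -> tonic -> stats.

A run is driven by a single :class:`RunConfig` (loadable from YAML).
One top-level seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn`` -- stage k uses the k-th child --
so stages are independently reproducible.  Every run writes a manifest
(config hash, package and library versions, per-stage seeds) next to
its outputs, and each stage is resumable: it is skipped when its
outputs already exist, unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .trace_io import (
    CellRecord,
    read_cell,
    read_patient_table,
    write_cell,
    write_patient_table,
)
from .synthetic_data import CohortConfig, VCChannelParams, simulate_cohort
from .ap_features import (
    FeatureConfig,
    cohort_feature_matrices,
    extract_cell_features,
)
from .firing_cluster import classify_firing_petilla, cluster_cohort
from .tonic_quant import analyze_vc_trace
from .group_stats import DEFAULT_MODEL_SPECS, build_cell_table, fit_regression_ledger

__all__ = ["RunConfig", "run_pipeline", "stage_seeds", "STAGES"]

STAGES = ("simulate", "features", "cluster", "tonic", "stats")


@dataclass
class RunConfig:
    seed: int
    out_dir: str = "run_out"
    n_cells: int = 30
    archetype_mixture: Optional[list] = None
    cohort: dict = field(default_factory=dict)      # CohortConfig overrides
    vc: dict = field(default_factory=dict)          # VCChannelParams overrides
    features: dict = field(default_factory=dict)    # FeatureConfig overrides
    cluster: dict = field(default_factory=dict)     # cluster_cohort kwargs
    model_specs: Optional[dict] = None              # regression model terms

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config must specify a seed")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seeds(seed: int, n: int = len(STAGES)) -> list[int]:
    """Fan a top-level seed out to per-stage seeds (SeedSequence spawn)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]


def _cohort_config(cfg: RunConfig) -> CohortConfig:
    vc = VCChannelParams(**cfg.vc) if cfg.vc else VCChannelParams()
    opts = dict(cfg.cohort)
    opts.setdefault("simulate_vc", True)
    return CohortConfig(vc_params=vc, **opts)


def _load_cells(cells_dir: Path) -> list[CellRecord]:
    return [read_cell(p) for p in sorted(cells_dir.glob("*.h5"))]


def run_pipeline(config: RunConfig, force: bool = False,
                 log=print) -> Path:
    """Execute all stages in order; returns the output directory.

    Stage outputs::

        cells/*.h5            interchange files with ground truth
        patients.csv          patient covariate table
        cell_features.csv     one row of scalar features per cell
        feature_datasets.npz  per-dataset matrices for clustering
        cluster_labels.csv    firing-cluster label per cell
        cluster_model.json    BIC table and selection summary
        tonic_results.csv     tonic/RMS/capacitance/QC per cell
        ledger.csv            regression-ledger table
        group_tests.json      omnibus test results
        manifest.json         reproducibility record
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, stage_seeds(config.seed)))
    cells_dir = out / "cells"

    # ---- simulate ----------------------------------------------------
    if force or not cells_dir.exists():
        log(f"[simulate] {config.n_cells} cells (seed {seeds['simulate']})")
        cohort_cfg = _cohort_config(config)
        records, patients = simulate_cohort(
            cohort_cfg,
            n_cells=config.n_cells,
            archetype_mixture=config.archetype_mixture,
            seed=seeds["simulate"],
        )
        cells_dir.mkdir(exist_ok=True)
        for rec in records:
            write_cell(rec, cells_dir / f"{rec.cell_id}.h5")
        write_patient_table(patients, out / "patients.csv")
    records = _load_cells(cells_dir)
    patients = read_patient_table(out / "patients.csv")

    # ---- features ----------------------------------------------------
    feats_csv = out / "cell_features.csv"
    mats_file = out / "feature_datasets.npz"
    if force or not feats_csv.exists():
        log(f"[features] extracting from {len(records)} cells")
        feats = [extract_cell_features(r) for r in records]
        mats, impute_report = cohort_feature_matrices(
            records, FeatureConfig(**config.features), feats_list=feats
        )
        rows = []
        for r, f in zip(records, feats):
            ap = f.first_ap
            rows.append({
                "cell_id": r.cell_id,
                "patient_id": r.patient_id,
                "axonal_class": r.axonal_class,
                "R_in": f.R_in,
                "sag_ratio": f.sag_ratio,
                "rheobase": f.rheobase,
                "V_threshold": ap.V_threshold if ap else np.nan,
                "V_peak": ap.V_peak if ap else np.nan,
                "amplitude": ap.amplitude if ap else np.nan,
                "halfwidth_ms": (ap.halfwidth if ap and ap.halfwidth else np.nan),
                "AHP": ap.AHP if ap and ap.AHP is not None else np.nan,
                "accommodation_ratio": f.accommodation_ratio,
                "first_spike_latency_ms": f.first_spike_latency,
                "max_rate_hz": f.max_rate,
                "petilla_label": classify_firing_petilla(f),
                "flags": ";".join(f.flags),
            })
        pd.DataFrame(rows).to_csv(feats_csv, index=False)
        np.savez(mats_file, **{f"dataset_{k:02d}": m for k, m in enumerate(mats)},
                 impute=np.array([impute_report[k] for k in sorted(impute_report)]))
    feats_df = pd.read_csv(feats_csv)

    # ---- cluster -----------------------------------------------------
    labels_csv = out / "cluster_labels.csv"
    if force or not labels_csv.exists():
        log("[cluster] sPCA + GMM/BIC")
        with np.load(mats_file) as z:
            mats = [z[k] for k in sorted(z.files) if k.startswith("dataset_")]
        model = cluster_cohort(mats, seed=seeds["cluster"], **config.cluster)
        pd.DataFrame({
            "cell_id": feats_df["cell_id"],
            "firing_cluster": model.labels,
        }).to_csv(labels_csv, index=False)
        (out / "cluster_model.json").write_text(
            json.dumps(model.to_summary(), indent=1)
        )
    labels_df = pd.read_csv(labels_csv)

    # ---- tonic -------------------------------------------------------
    tonic_csv = out / "tonic_results.csv"
    if force or not tonic_csv.exists():
        with_vc = [r for r in records if r.vc_trace is not None]
        log(f"[tonic] analyzing {len(with_vc)} voltage-clamp traces")
        rows = []
        for r in with_vc:
            res = analyze_vc_trace(r.vc_trace, cell_id=r.cell_id)
            row = {
                "cell_id": r.cell_id,
                "I_tonic": res.I_tonic,
                "raw_delta": res.raw_delta,
                "I_tonic_abs": abs(res.I_tonic) if np.isfinite(res.I_tonic) else np.nan,
                "rms_baseline": res.rms_baseline,
                "rms_block": res.rms_block,
                "delta_rms": res.delta_rms,
                "C_vc": res.C_vc,
                "I_tonic_per_pF": res.I_tonic_per_pF,
                "block_onset_time": res.block_onset_time,
                "onset_from_epoch": res.onset_from_epoch,
                "outliers_removed": res.outliers_removed,
                "qc_pass": res.qc_pass,
                "flags": ";".join(res.flags),
            }
            if r.ground_truth is not None:
                row["true_tonic_shift"] = r.ground_truth.true_tonic_shift
            rows.append(row)
        pd.DataFrame(rows).to_csv(tonic_csv, index=False)
    tonic_df = pd.read_csv(tonic_csv)

    # ---- stats -------------------------------------------------------
    ledger_csv = out / "ledger.csv"
    if force or not ledger_csv.exists():
        log("[stats] group tests + regression ledger")
        pat_df = pd.DataFrame([vars(p) for p in patients])
        meta = feats_df[["cell_id", "patient_id", "axonal_class", "sag_ratio"]]
        table = build_cell_table(tonic_df, labels_df, meta, pat_df)
        specs = config.model_specs or DEFAULT_MODEL_SPECS
        usable = {
            mid: terms for mid, terms in specs.items()
            if not any(t.startswith("cluster:") for t in terms)
            or table["firing_cluster"].nunique() >= 2
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ledgers = fit_regression_ledger(table, usable)
        frames = [led.to_frame() for led in ledgers]
        pd.concat(frames, ignore_index=True).to_csv(ledger_csv, index=False)
        summary = {
            led.model_id: {
                "df": led.df, "n": led.n, "residual_ss": led.residual_ss,
                "r2": led.r2, "adj_r2": led.adj_r2, "F": led.f_stat,
                "p": led.f_p, "references": led.reference_categories,
                "dropped": led.dropped_terms,
            }
            for led in ledgers
        }
        group_tests = _group_tests(table)
        (out / "group_tests.json").write_text(
            json.dumps({"models": summary, "group_tests": group_tests}, indent=1)
        )

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stage_seeds": seeds,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log(f"[done] outputs in {out}")
    return out


def _group_tests(table: pd.DataFrame) -> dict:
    """Standard omnibus comparisons of tonic current across groupings."""
    from .group_stats import correlate, omnibus_and_posthoc

    out: dict[str, dict] = {}
    t = table.dropna(subset=["I_tonic"])
    if t["firing_cluster"].nunique() >= 2 and (t.groupby("firing_cluster").size() >= 2).all():
        r = omnibus_and_posthoc(t["I_tonic"], t["firing_cluster"], "kruskal+dunn")
        out["tonic_by_cluster"] = {
            "test": r.test, "statistic": r.statistic, "p": r.p,
            "post_hoc": [[list(map(str, pair)), p] for pair, p in r.post_hoc],
        }
    if "sag_ratio" in t and t["sag_ratio"].notna().sum() >= 3:
        r = correlate(t["sag_ratio"].dropna(),
                      t.loc[t["sag_ratio"].notna(), "I_tonic"])
        out["tonic_vs_sag"] = {"r": r.statistic, "p": r.p, **r.effect}
    return out
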