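"""End-to-end orchestration: simulate/ingest -> FC -> controllability ->
group comparison -> classifier evaluation.

A single RunConfig (YAML-serializable) drives all stages; one master seed
fans out deterministically to the cohort generator and the classifier, so
repeated runs with the same config produce byte-identical tables. Every
stage writes plain TSV/JSON under the output directory and is recorded in
a machine-readable run report with file checksums and timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import controllability as ctrl
from . import classifier_eval as clf
from . import group_stats as gstats
from .synthetic import CohortConfig, RoiTimeSeries, generate_cohort, write_cohort
from ._seeds import derive_seed

__all__ = ["RunConfig", "RunReport", "run_all", "ingest_real_manifest",
           "profiles_for_cohort", "write_profiles_tsv", "read_profiles_tsv"]


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    manifest_path: str | None = None        # set to ingest real data instead
    manifest_tr_seconds: float = 0.5
    filter_enabled: bool = False
    low_hz: float = 0.01
    high_hz: float = 0.08
    absolute_fc: bool = False
    normalization_c: float = 1.0
    alpha: float = 0.05
    equal_var: bool = True
    classifier: clf.MlpArchitecture = field(default_factory=clf.MlpArchitecture)
    k_folds: int = 10
    output_dir: str = "connectrl_run"
    master_seed: int = 0

    def validate(self) -> None:
        if self.manifest_path is None:
            self.cohort.validate()
        self.classifier.validate()
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.normalization_c <= 0:
            raise ValueError("normalization_c must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "classifier" in d and isinstance(d["classifier"], dict):
            d["classifier"] = clf.MlpArchitecture(**d["classifier"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    config: dict
    stages: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def add_stage(self, name: str, outputs: list[Path], seconds: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "seconds": round(seconds, 3),
                "outputs": [
                    {"path": str(p), "sha256": _sha256(p)} for p in outputs
                ],
            }
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"config": self.config, "stages": self.stages, "summary": self.summary}, indent=2)
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def profiles_for_cohort(
    fcs: list[conn.ConnectivityMatrix], c: float = 1.0
) -> list[ctrl.ControllabilityProfile]:
    """Average-controllability profile for every subject's FC matrix."""
    out = []
    for fc in fcs:
        model = ctrl.stabilize_adjacency(fc, c=c)
        out.append(ctrl.average_controllability_profile(model, fc.subject_id, fc.group_label))
    return out


def write_profiles_tsv(profiles: list[ctrl.ControllabilityProfile], path: str | Path) -> None:
    """Cohort-level profile table: one row per subject, one column per region."""
    labels = profiles[0].region_labels
    df = pd.DataFrame([p.values for p in profiles], columns=labels)
    df.insert(0, "subject_id", [p.subject_id for p in profiles])
    df.insert(1, "group_label", [p.group_label for p in profiles])
    df.to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path) -> list[ctrl.ControllabilityProfile]:
    df = pd.read_csv(path, sep="\t")
    labels = [c for c in df.columns if c not in ("subject_id", "group_label")]
    return [
        ctrl.ControllabilityProfile(
            subject_id=str(row["subject_id"]),
            group_label=int(row["group_label"]),
            values=row[labels].to_numpy(dtype=float),
            region_labels=labels,
        )
        for _, row in df.iterrows()
    ]


def ingest_real_manifest(path: str | Path, tr_seconds: float = 0.5):
    """Load a cohort from a manifest of per-subject files.

    The manifest is a TSV with columns subject_id, group_label, path
    (relative paths resolved against the manifest location). Files may be
    either timepoints x regions series (plain header row) or labeled square
    matrices; a manifest mixing the two kinds is rejected.
    """
    path = Path(path)
    manifest = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group_label", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if manifest["subject_id"].duplicated().any():
        dup = manifest["subject_id"][manifest["subject_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate subject_id in manifest: {dup}")
    bad = set(manifest["group_label"]) - {0, 1}
    if bad:
        raise ValueError(f"group labels must be 0 or 1, found {sorted(bad)}")

    cohort, kinds, n_regions = [], set(), None
    for _, row in manifest.iterrows():
        fpath = Path(row["path"])
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        if not fpath.exists():
            raise ValueError(f"subject {row['subject_id']}: file not found: {fpath}")
        df = pd.read_csv(fpath, sep="\t")
        first_col = str(df.columns[0])
        is_matrix = first_col == "" or first_col.startswith("Unnamed")
        kinds.add("matrix" if is_matrix else "timeseries")
        if len(kinds) > 1:
            raise ValueError("manifest mixes time-series and matrix files")
        if is_matrix:
            item = conn.read_fc_tsv(fpath, str(row["subject_id"]), int(row["group_label"]))
            n_here = item.n_regions
        else:
            item = conn.read_timeseries_tsv(
                fpath, str(row["subject_id"]), int(row["group_label"]), tr_seconds
            )
            n_here = item.n_regions
        if n_regions is None:
            n_regions = n_here
        elif n_here != n_regions:
            raise ValueError(
                f"subject {row['subject_id']} ({fpath.name}) has {n_here} regions, expected {n_regions}"
            )
        cohort.append(item)
    return cohort


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage under config.output_dir and return the run report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    stage = "simulate"

    try:
        # --- simulate or ingest -------------------------------------------
        t0 = time.perf_counter()
        if config.manifest_path is not None:
            items = ingest_real_manifest(config.manifest_path, config.manifest_tr_seconds)
            manifest_out: list[Path] = []
        else:
            cohort_cfg = dataclasses.replace(
                config.cohort, seed=derive_seed(config.master_seed, 0x5EED)
            )
            items = generate_cohort(cohort_cfg)
            manifest_out = [write_cohort(items, out / "cohort")]
        report.add_stage("simulate", manifest_out, time.perf_counter() - t0)

        # --- functional connectivity --------------------------------------
        stage = "fc"
        t0 = time.perf_counter()
        if items and isinstance(items[0], conn.ConnectivityMatrix):
            fcs = items
        else:
            fcs = conn.fc_for_cohort(
                items,
                low_hz=config.low_hz,
                high_hz=config.high_hz,
                apply_bandpass=config.filter_enabled,
                absolute=config.absolute_fc,
            )
        fc_dir = out / "fc"
        fc_dir.mkdir(exist_ok=True)
        fc_paths = []
        for fc in fcs:
            p = fc_dir / f"{fc.subject_id}_fc.tsv"
            conn.write_fc_tsv(fc, p)
            fc_paths.append(p)
        report.add_stage("fc", fc_paths[:3], time.perf_counter() - t0)

        # --- controllability ----------------------------------------------
        stage = "control"
        t0 = time.perf_counter()
        profiles = profiles_for_cohort(fcs, c=config.normalization_c)
        profiles_path = out / "controllability_profiles.tsv"
        write_profiles_tsv(profiles, profiles_path)
        report.add_stage("control", [profiles_path], time.perf_counter() - t0)

        # --- group comparison ---------------------------------------------
        stage = "compare"
        t0 = time.perf_counter()
        table = gstats.compare_groups(profiles, alpha=config.alpha, equal_var=config.equal_var)
        table_path = out / "comparison_table.tsv"
        table.write_tsv(table_path)
        sig = table.significant()
        sig_path = out / "significant_regions.tsv"
        gstats.ComparisonTable(sig, table.n_a, table.n_b, table.alpha).write_tsv(sig_path)
        report.add_stage("compare", [table_path, sig_path], time.perf_counter() - t0)

        # --- classifier evaluation ----------------------------------------
        stage = "classify"
        t0 = time.perf_counter()
        features = clf.select_features(profiles, table, alpha=config.alpha)
        cv = clf.cross_validate(
            features,
            arch=config.classifier,
            k=config.k_folds,
            seed=derive_seed(config.master_seed, 0xC1A55),
        )
        cv_path = out / "cv_report.json"
        cv_path.write_text(json.dumps(cv.to_dict(), indent=2))
        confusion_path = out / "confusion_matrix.tsv"
        pd.DataFrame(
            cv.pooled_confusion,
            index=["true_0", "true_1"],
            columns=["pred_0", "pred_1"],
        ).to_csv(confusion_path, sep="\t")
        report.add_stage("classify", [cv_path, confusion_path], time.perf_counter() - t0)

        report.summary = {
            "n_subjects": len(profiles),
            "n_regions": len(profiles[0].region_labels),
            "n_significant_regions": len(sig),
            "significant_regions": [r.region_name for r in sig],
            "overall_accuracy": cv.overall_accuracy,
            "mean_auc": cv.mean_auc,
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    report.write(out / "run_report.json")
    return report
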