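"""End-to-end orchestration: qc -> impute -> features -> train -> assoc -> report.

Every stage writes its outputs into the run directory as it completes, so a
failing stage leaves the earlier outputs in place; the resolved
configuration (including the seed) is written first and suffices to rerun
the pipeline identically.  Events (stage completions, tie-breaks, dropped
features) go to a JSON-lines log.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .assoc import assoc_all
from .cohort_stats import table1
from .errors import ConfigError, DataError, StageError
from .features import assemble
from .genoqc import QCThresholds, apply_qc
from .impute import impute, load_weight_db
from sklearn.metrics import precision_recall_curve, roc_curve

from .select_train import TrialConfig, rerun_trial, run_trials

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]

_MODES = {"genes-only", "clinical-only", "genes+clinical"}


@dataclass
class PipelineConfig:
    genotypes: str
    clinical: str
    outdir: str
    weights: str | None = None
    tissue: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    trial: TrialConfig = field(default_factory=TrialConfig)
    feature_mode: str = "genes-only"
    scaling: str = "per-split"
    cutoff_from: str = "test"
    standardize_assoc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_mode not in _MODES:
            raise ConfigError(f"feature_mode must be one of {sorted(_MODES)}")
        if self.feature_mode != "clinical-only" and self.weights is None:
            raise ConfigError("gene features requested but no weights file configured")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        qc = QCThresholds(**raw.pop("qc", {}))
        trial_raw = raw.pop("trial", {})
        for key in ("case_split", "c_grid"):
            if key in trial_raw:
                trial_raw[key] = tuple(trial_raw[key])
        trial = TrialConfig(**trial_raw)
        try:
            return cls(qc=qc, trial=trial, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trial"]["case_split"] = list(d["trial"]["case_split"])
        d["trial"]["c_grid"] = list(d["trial"]["c_grid"])
        return d


class _Log:
    def __init__(self, path: Path):
        self.path = path

    def event(self, stage: str, **kw) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps({"t": time.time(), "stage": stage, **kw}) + "\n")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    log = _Log(outdir / "log.jsonl")

    def stage(name: str, fn):
        try:
            out = fn()
        except (DataError, ConfigError, FileNotFoundError) as exc:
            log.event(name, error=str(exc))
            raise StageError(f"stage {name} failed: {exc}") from exc
        log.event(name, done=True)
        return out

    # --- load + qc
    def _qc():
        clinical = io.read_clinical_csv(cfg.clinical)
        g = io.read_genotypes(cfg.genotypes, samples=clinical.index)
        g2, report = apply_qc(g, cfg.qc)
        report.samples.to_csv(outdir / "qc_samples.tsv", sep="\t")
        report.variants.to_csv(outdir / "qc_variants.tsv", sep="\t")
        with open(outdir / "qc_summary.json", "w") as fh:
            json.dump(report.removed, fh, indent=2)
        clinical = clinical.loc[[s for s in clinical.index if s in set(g2.sample_ids)]]
        return g2, clinical

    g, clinical = stage("qc", _qc)
    labels = clinical["label"]

    # --- impute
    expr = None
    if cfg.feature_mode != "clinical-only":
        def _impute():
            db = load_weight_db(cfg.weights, tissue=cfg.tissue)
            em = impute(g, db)
            em.values.to_csv(outdir / "expression.tsv", sep="\t")
            em.coverage.to_csv(outdir / "coverage.tsv", sep="\t")
            return em

        expr = stage("impute", _impute)

    # --- features
    def _features():
        fm = assemble(expr, clinical if cfg.feature_mode != "genes-only" else None, mode=cfg.feature_mode)
        fm.data.to_csv(outdir / "features.tsv", sep="\t")
        with open(outdir / "encoding.json", "w") as fh:
            json.dump({"provenance": fm.provenance, "encoding": fm.encoding}, fh, indent=2)
        return fm

    fm = stage("features", _features)

    # --- train
    def _train():
        trial_cfg = dataclasses.replace(cfg.trial, base_seed=cfg.seed)
        report, trials = run_trials(fm, labels, trial_cfg, scaling=cfg.scaling, cutoff_from=cfg.cutoff_from)
        rows = [
            {
                "trial": t.trial, "selected": "|".join(t.selected), "best_c": t.best_c,
                "cv_auc_roc": t.cv_auc_roc, "test_auc_roc": t.test_auc_roc, "test_auc_prc": t.test_auc_prc,
                "cutoff": t.cutoff, "sensitivity": t.sensitivity, "specificity": t.specificity,
                "precision": t.precision, "youden_j": t.youden_j, "notes": "; ".join(t.notes),
            }
            for t in trials
        ]
        pd.DataFrame(rows).to_csv(outdir / "trials.tsv", sep="\t", index=False)
        with open(outdir / "consensus.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        for t in trials:
            for note in t.notes:
                log.event("train", trial=t.trial, note=note)
        ev = rerun_trial(fm, labels, trial_cfg, report.representative, scaling=cfg.scaling, cutoff_from=cfg.cutoff_from)
        fpr, tpr, roc_thr = roc_curve(ev["y_test"], ev["test_scores"])
        pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr}).to_csv(outdir / "roc_points.tsv", sep="\t", index=False)
        prec, rec, prc_thr = precision_recall_curve(ev["y_test"], ev["test_scores"])
        pd.DataFrame({"recall": rec, "precision": prec, "threshold": list(prc_thr) + [float("nan")]}).to_csv(
            outdir / "prc_points.tsv", sep="\t", index=False
        )
        return report, trials

    report, trials = stage("train", _train)

    # --- assoc (gene features only)
    if expr is not None:
        def _assoc():
            table = assoc_all(expr, labels, standardize=cfg.standardize_assoc)
            table.to_csv(outdir / "association.tsv", sep="\t", index=False)
            return table

        stage("assoc", _assoc)

    # --- cohort stats + report
    def _report():
        t1 = table1(clinical)
        t1.to_csv(outdir / "table1.tsv", sep="\t")
        return render_report(outdir)

    stage("report", _report)
    return outdir


def render_report(run_dir: str | Path) -> Path:
    """Render the run directory into Markdown + JSON summary tables.

    Emits the cohort comparison, the modal feature combinations with their
    selection frequencies and metric summaries, the association ranking,
    and the representative trial's ROC/PRC point files.  Idempotent.
    """
    run_dir = Path(run_dir)
    cons_path = run_dir / "consensus.json"
    if not cons_path.exists():
        raise DataError(f"incomplete run dir: {cons_path} missing")
    with open(cons_path) as fh:
        cons = json.load(fh)
    if cons["n_trials"] == 0:
        raise DataError("no trials in consensus report")
    lines = ["# Run report", ""]
    t1_path = run_dir / "table1.tsv"
    if t1_path.exists():
        lines += ["## Cohort characteristics (NDR vs DR)", "", t1_path.read_text(), ""]
    lines += [f"## Consensus over {cons['n_trials']} trials", "", "combination\tselection frequency /" + str(cons["n_trials"])]
    for combo, freq in cons["combination_freq"].items():
        lines.append(f"{combo}\t{freq}")
    lines += ["", "metric\tmean\tsd"]
    for m, v in cons["metric_means"].items():
        lines.append(f"{m}\t{v:.4f}\t{cons['metric_sds'][m]:.4f}")
    lines.append(f"\nrepresentative trial: {cons['representative']}")
    assoc_path = run_dir / "association.tsv"
    if assoc_path.exists():
        top = pd.read_csv(assoc_path, sep="\t").head(10)
        lines += ["", "## Top univariate associations", "", top.to_csv(sep="\t", index=False)]
    trials_path = run_dir / "trials.tsv"
    if trials_path.exists():
        df = pd.read_csv(trials_path, sep="\t")
        df[df["trial"] == cons["representative"]].to_csv(run_dir / "representative_trial.tsv", sep="\t", index=False)
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
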