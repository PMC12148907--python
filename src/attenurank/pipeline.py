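"""End-to-end orchestration: simulate → rank → synthesize → score → evaluate.

Each stage writes plain CSV/JSON artifacts into the run directory so any
stage can also be run standalone on user data, and a manifest records the
configuration, seeds and SHA-256 hashes of every artifact.  Deterministic
stages re-produce byte-identical CSV/JSON files when re-run with the same
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from ._seeds import child_seed
from .cohort import CohortConfig, INPUT_COLUMNS, generate_cohort, write_cohort
from .evaluation import (
    GridSpec,
    PhaseConfig,
    audit_leakage,
    benchmark_real,
    phase1_hybrid,
    phase2_pure_synthetic,
    render_reports,
    results_frame,
)
from .fidelity import plot_marginals, quality_report
from .ranking import compute_labels, labels_wide, write_labels
from .tvae import TVAEConfig, TVAESynthesizer

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "build_synthesis_table"]

STAGES = ("simulate", "rank", "synth", "fidelity", "evaluate")
TARGET_COLUMNS = tuple(f"group_{v}" for v in ("pr", "ck", "cmj", "dj", "djct", "rsi"))


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    One master ``seed`` fans out to per-stage child seeds, so the whole run
    is a function of a single integer while each stage stays independently
    reproducible.
    """

    seed: int = 0
    n_synthetic: int = 200
    inputs_only: bool = False  # synthesize inputs without the group labels
    fidelity_bins: int = 20
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    tvae: TVAEConfig = dataclasses.field(default_factory=TVAEConfig)
    grids: GridSpec = dataclasses.field(default_factory=GridSpec)
    phase1: PhaseConfig = dataclasses.field(
        default_factory=lambda: PhaseConfig(phase="hybrid")
    )
    phase2: PhaseConfig = dataclasses.field(
        default_factory=lambda: PhaseConfig(phase="pure_synthetic")
    )

    def __post_init__(self) -> None:
        if self.n_synthetic < 0:
            raise ValueError("n_synthetic must be >= 0")
        self.cohort = dataclasses.replace(self.cohort, seed=child_seed(self.seed, "cohort"))
        self.tvae = dataclasses.replace(self.tvae, seed=child_seed(self.seed, "tvae"))
        self.phase1 = dataclasses.replace(
            self.phase1, phase="hybrid", seed=child_seed(self.seed, "eval")
        )
        self.phase2 = dataclasses.replace(
            self.phase2, phase="pure_synthetic", seed=child_seed(self.seed, "eval")
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("seed", "n_synthetic", "inputs_only", "fidelity_bins"):
            if key in raw:
                kwargs[key] = raw[key]
        if "cohort" in raw:
            cohort = dict(raw["cohort"])
            if "moment_table" in cohort:
                cohort["moment_table"] = {
                    k: tuple(v) for k, v in cohort["moment_table"].items()
                }
            kwargs["cohort"] = CohortConfig(**cohort)
        if "tvae" in raw:
            tv = dict(raw["tvae"])
            for k in ("compress_dims", "decompress_dims"):
                if k in tv:
                    tv[k] = tuple(tv[k])
            kwargs["tvae"] = TVAEConfig(**tv)
        if "grids" in raw:
            kwargs["grids"] = GridSpec(grids=raw["grids"])
        for phase_key in ("phase1", "phase2"):
            if phase_key in raw:
                ph = dict(raw[phase_key])
                if "proportions" in ph:
                    ph["proportions"] = tuple(ph["proportions"])
                kwargs[phase_key] = PhaseConfig(**ph)
        return cls(**kwargs)


def build_synthesis_table(
    cohort: pd.DataFrame, labels: pd.DataFrame, inputs_only: bool = False
) -> pd.DataFrame:
    """Assemble the table the synthesizer trains on.

    By default the 14 model inputs and the 6 binary group labels are
    synthesized jointly, so the synthetic pool carries its own labels for
    the train-synthetic-test-real phase.
    """
    features = cohort[list(INPUT_COLUMNS)].reset_index(drop=True)
    if inputs_only:
        return features
    wide = labels_wide(labels).drop(columns=["athlete_id"]).reset_index(drop=True)
    return pd.concat([features, wide], axis=1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages and write a hashed run manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise PipelineStageError("setup", exc) from exc

    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": {
            "cohort": config.cohort.seed,
            "tvae": config.tvae.seed,
            "eval": config.phase1.seed,
        },
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {
            str(p.relative_to(out)): _sha256(p)
            for p in paths
            if p.suffix in (".csv", ".json", ".md")
        }
        manifest["stages"][stage]["_all_files"] = sorted(
            str(p.relative_to(out)) for p in paths
        )

    # ------------------------------------------------------------ simulate
    try:
        cohort = generate_cohort(config.cohort)
        cohort_path = out / "cohort.csv"
        write_cohort(cohort, cohort_path)
        record("simulate", cohort_path)
        logger.info("simulate: %d athletes -> %s", len(cohort), cohort_path)
    except Exception as exc:
        raise PipelineStageError("simulate", exc) from exc

    # ---------------------------------------------------------------- rank
    try:
        labels, ledger = compute_labels(cohort)
        write_labels(labels, ledger, out)
        record("rank", out / "labels.csv", out / "ranking_ledger.json")
        logger.info("rank: %d label rows", len(labels))
    except Exception as exc:
        raise PipelineStageError("rank", exc) from exc

    # --------------------------------------------------------------- synth
    try:
        train_table = build_synthesis_table(cohort, labels, config.inputs_only)
        synthesizer = TVAESynthesizer(config.tvae)
        synthesizer.fit(train_table, categorical_columns=[
            c for c in train_table.columns if c.startswith("group_")
        ])
        synthetic = synthesizer.sample(config.n_synthetic)
        synth_path = out / "synthetic.csv"
        synthetic.to_csv(synth_path, index=False)
        loss_path = out / "tvae_loss.csv"
        pd.DataFrame(
            {"epoch": range(1, len(synthesizer.loss_trace) + 1),
             "loss": synthesizer.loss_trace}
        ).to_csv(loss_path, index=False)
        synthesizer.save(out / "tvae_model")
        train_path = out / "train_table.csv"
        train_table.to_csv(train_path, index=False)
        record("synth", synth_path, loss_path, train_path)
        logger.info("synth: %d synthetic rows, final loss %.3f",
                    len(synthetic), synthesizer.loss_trace[-1])
    except Exception as exc:
        raise PipelineStageError("synth", exc) from exc

    # ------------------------------------------------------------ fidelity
    try:
        report = quality_report(train_table, synthetic, n_bins=config.fidelity_bins)
        report_path = out / "fidelity_report.json"
        report.to_json(report_path)
        md_path = out / "fidelity_report.md"
        md_path.write_text(report.to_markdown() + "\n")
        figs = plot_marginals(train_table, synthetic, report, out / "figures")
        record("fidelity", report_path, md_path, *figs)
        logger.info("fidelity: shapes %.3f, trends %.3f, overall %.3f, Hellinger %.3f",
                    report.column_shapes_score, report.column_pair_trends_score,
                    report.overall_score, report.aggregate_hellinger)
    except Exception as exc:
        raise PipelineStageError("fidelity", exc) from exc

    # ------------------------------------------------------------ evaluate
    try:
        if config.inputs_only:
            logger.info("evaluate: skipped (inputs_only synthesis has no labels)")
            manifest["stages"]["evaluate"] = {"skipped": "inputs_only"}
        else:
            features = cohort[list(INPUT_COLUMNS)].reset_index(drop=True)
            targets = labels_wide(labels).drop(columns=["athlete_id"])
            targets.columns = [c.removeprefix("group_") for c in targets.columns]
            synth_features = synthetic[list(INPUT_COLUMNS)].reset_index(drop=True)
            synth_targets = synthetic[[c for c in synthetic.columns if c.startswith("group_")]].copy()
            synth_targets.columns = [c.removeprefix("group_") for c in synth_targets.columns]

            bench_cfg = dataclasses.replace(
                config.phase1, phase="benchmark", proportions=()
            )
            bench = benchmark_real(features, targets, config.grids, bench_cfg)
            p1 = phase1_hybrid(features, targets, synth_features, synth_targets,
                               config.grids, config.phase1, benchmark=bench)
            p2 = phase2_pure_synthetic(features, targets, synth_features,
                                       synth_targets, config.grids, config.phase2,
                                       benchmark=bench)
            all_results = list(bench.values()) + p1 + p2
            if not audit_leakage(all_results):
                raise RuntimeError("leakage audit failed")
            eval_dir = out / "evaluation"
            files = render_reports(p1 + p2, eval_dir, benchmark=bench)
            bench_path = eval_dir / "benchmark.csv"
            results_frame(list(bench.values())).to_csv(bench_path, index=False)
            record("evaluate", bench_path, *files)
            logger.info("evaluate: %d result rows", len(all_results))
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("evaluate", exc) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
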