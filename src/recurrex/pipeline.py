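"""End-to-end pipeline: preprocess -> tag -> filter -> gate -> featurize ->
select -> train -> evaluate, driven by a single YAML configuration.

Every run is reproducible from the config file alone: all artifacts are
stamped with the config hash and seed, and the JSON-lines log records the
mention counts dropped at each stage, which must reconcile::

    mentions_in == retained + dropped_by_cue + dropped_by_negex
                            + dropped_by_positive_gate
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from recurrex.context import apply_context_filters, load_triggers
from recurrex.corpus import read_corpus
from recurrex.evaluate import ExperimentConfig, run_experiment
from recurrex.features import assemble_matrix, save_matrix
from recurrex.model import DEFAULT_C_GRID, DEFAULT_FRACTION, DEFAULT_GAMMA_GRID, KERNEL_ORDER
from recurrex.positive import filter_to_positive, load_positive_set
from recurrex.resources import lexicon_path, positive_set_path, triggers_path
from recurrex.tagger import load_lexicon, tag_corpus


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    corpus: str = ""
    lexicon: str = ""
    positive_set: str = ""
    triggers: str = ""
    out_dir: str = "out"
    modes: tuple[str, ...] = ("proposed", "filtered_concepts", "full_concepts", "bag_of_words")
    fraction: float = DEFAULT_FRACTION
    folds: int = 5
    split_ratio: float = 0.7
    cutoff: float = 0.5
    seed: int = 0
    kernels: tuple[str, ...] = KERNEL_ORDER
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    min_days: int = 120
    cui_cap: int = 10

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = PipelineConfig()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise PipelineError("config", f"unknown config key {key!r}")
            default = getattr(cfg, key)
            if isinstance(default, tuple):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole workflow; returns artifact paths and the run log."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    def log_stage(stage: str, **counts) -> None:
        log.append({"stage": stage, **stamp, **counts})

    try:
        records = read_corpus(config.corpus)
    except Exception as exc:
        raise PipelineError("read_corpus", str(exc)) from exc
    log_stage("read_corpus", n_patients=len(records))

    try:
        lexicon = load_lexicon(config.lexicon or lexicon_path())
    except Exception as exc:
        raise PipelineError("tagging", f"cannot load lexicon: {exc}") from exc
    triggers = load_triggers(config.triggers or triggers_path())
    positive = load_positive_set(config.positive_set or positive_set_path())

    tagged = tag_corpus(records, lexicon)
    mentions_in = sum(len(ms) for _s, ms in tagged.values())
    log_stage("tag", n_sentences=len(tagged), mentions_in=mentions_in)

    retained, stats = apply_context_filters(tagged, triggers)
    log_stage("context_filter", sentences_dropped=stats.sentences_dropped,
              dropped_by_cue=stats.dropped_by_cue,
              dropped_by_negex=stats.dropped_by_negex)

    after_context = sum(len(ms) for _s, ms in retained.values())
    after_gate = sum(len(filter_to_positive(ms, positive)) for _s, ms in retained.values())
    dropped_by_gate = after_context - after_gate
    log_stage("positive_gate", dropped_by_positive_gate=dropped_by_gate,
              mentions_retained=after_gate)
    assert mentions_in == after_gate + stats.dropped_by_cue + stats.dropped_by_negex + dropped_by_gate

    artifacts: dict = {"log": log}
    for mode in config.modes:
        matrix = assemble_matrix(records, mode, lexicon=lexicon, triggers=triggers,
                                 positive=positive, min_days=config.min_days,
                                 cui_cap=config.cui_cap,
                                 tagged=tagged if mode != "bag_of_words" else None)
        feat_dir = out_dir / f"features_{mode}"
        save_matrix(matrix, feat_dir)
        log_stage("featurize", mode=mode, n_features=len(matrix.keys))
        artifacts[f"features_{mode}"] = str(feat_dir)

    exp = ExperimentConfig(
        modes=tuple(config.modes), split_ratio=config.split_ratio,
        fraction=config.fraction, folds=config.folds, cutoff=config.cutoff,
        seed=config.seed, kernels=tuple(config.kernels),
        C_grid=tuple(config.C_grid), gamma_grid=tuple(config.gamma_grid),
        min_days=config.min_days, cui_cap=config.cui_cap,
    )
    report = run_experiment(records, exp, lexicon=lexicon, triggers=triggers,
                            positive=positive)
    report.update(stamp)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                           encoding="utf-8")
    log_stage("evaluate", report=str(report_path))
    artifacts["report"] = str(report_path)

    log_path = out_dir / "log.jsonl"
    with log_path.open("w", encoding="utf-8") as fh:
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    artifacts["log_path"] = str(log_path)
    return artifacts
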