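"""End-to-end orchestration: extraction → model selection → feature selection.

The two evolutionary stages share one run-level seed: it fixes the 70/30
split and CV folds (so every individual in both stages is scored against
the same partitions) and seeds named substreams for each stage's random
draws.  The final report carries the five hold-out metrics (as percentages),
the selected columns, the final model, and audit counters for the training
budget of each stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .evaluation import Dataset, Evaluator
from .features import DEFAULT_LTP_THRESHOLD, extract_table
from .ga_features import FSConfig, run_feature_selection
from .ga_models import GAConfig, run_model_selection
from .params import PARAM_ORDER, ParameterSpace, build_parameter_space
from .roi import RoiPair


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run depends on, under one seed."""

    group: str = "fractals_3ltp"
    ga: GAConfig = field(default_factory=GAConfig)
    fs: FSConfig = field(default_factory=FSConfig)
    ltp_threshold: float = DEFAULT_LTP_THRESHOLD
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            ga=dataclasses.replace(self.ga, seed=seed),
            fs=dataclasses.replace(self.fs, seed=seed),
        )

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "ga": dataclasses.asdict(self.ga),
            "fs": dataclasses.asdict(self.fs),
            "ltp_threshold": self.ltp_threshold,
            "seed": self.seed,
        }

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    data: Dataset,
    config: Optional[RunConfig] = None,
    space: Optional[ParameterSpace] = None,
    log: Optional[list] = None,
) -> dict:
    """Run model selection then feature selection on a feature table.

    Returns a JSON-serializable report; reruns with the same config and
    seed are reproducible.
    """
    config = config or RunConfig()
    space = space or build_parameter_space()
    ga_cfg = dataclasses.replace(config.ga, seed=config.seed)
    fs_cfg = dataclasses.replace(config.fs, seed=config.seed)
    evaluator = Evaluator(data, config.seed)

    bucket, ms_audit = run_model_selection(
        data, ga_cfg, space, evaluator=evaluator, log=log
    )
    best_subset, fs_audit = run_feature_selection(
        data, bucket, fs_cfg, evaluator=evaluator, log=log
    )
    final = evaluator.holdout(best_subset.model.config, best_subset.bits)

    selected = [
        name
        for name, on in zip(data.column_names, best_subset.bits)
        if on
    ]
    report = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "group": config.group,
        "n_samples": data.n,
        "n_features": data.d,
        "protocol": evaluator.protocol(),
        "model_selection": {
            "audit": _audit_slim(ms_audit),
            "bucket": [
                {
                    "rank": i + 1,
                    "fitness": rm.fitness,
                    "config": rm.config.to_dict(),
                    "canonical": _canonical_dict(rm.config, space),
                }
                for i, rm in enumerate(bucket)
            ],
        },
        "feature_selection": {
            "audit": _audit_slim(fs_audit),
            "n_selected": int(best_subset.n_active),
            "selected_columns": selected,
            "fitness": best_subset.score,
        },
        "final_model": best_subset.model.config.to_dict(),
        "holdout_metrics_percent": final.as_percentages(),
        "audit": {
            "trained_models_model_selection": ms_audit["trained_models"],
            "trained_models_feature_selection": fs_audit["trained_models"],
            "total_trained": ms_audit["trained_models"]
            + fs_audit["trained_models"],
            "perturbation_events": ms_audit["perturbations"]
            + fs_audit["perturbations"],
        },
    }
    return report


def run_pipeline_from_pairs(
    pairs: Sequence[RoiPair],
    config: Optional[RunConfig] = None,
    space: Optional[ParameterSpace] = None,
    log: Optional[list] = None,
) -> dict:
    """Feature extraction followed by :func:`run_pipeline`."""
    config = config or RunConfig()
    data = extract_table(pairs, config.group, t=config.ltp_threshold)
    return run_pipeline(data, config, space, log=log)


def _audit_slim(audit: dict) -> dict:
    drop = ("best_fitness_history", "best_score_history")
    return {k: v for k, v in audit.items() if k not in drop}


def _canonical_dict(config, space: ParameterSpace) -> dict:
    rel = space.relevance[config.kernel]
    out = {"kernel": config.kernel}
    for p in PARAM_ORDER:
        if p != "kernel" and p in rel:
            out[p] = getattr(config, p)
    return out
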