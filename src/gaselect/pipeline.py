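"""End-to-end pipeline orchestration and the run manifest.

``run_pipeline`` wires stage-1 filter -> GA wrapper -> repeated-CV
evaluation (and an optional frozen-subset transfer to a second cohort) and
returns a :class:`RunManifest` that records everything needed to re-run the
pipeline bit-identically: configuration, seeds, the stage-1 ranking, the GA
trajectory and the evaluation reports.  Two runs with the same inputs and
master seed produce manifests whose :meth:`RunManifest.core` dictionaries
are identical (timestamps excluded).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

from .data import FeatureTable
from .fitness import FitnessSpec
from .ga import GAConfig
from .model import GAFeatureSelector

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    """JSON-serializable record of one pipeline run."""

    version: str
    config: dict
    seeds: dict
    stage1: dict
    ga: dict
    evaluation: dict = field(default_factory=dict)
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def core(self) -> dict:
        """Everything except wall-clock metadata — the re-run contract."""
        return {
            "version": self.version,
            "config": self.config,
            "seeds": self.seeds,
            "stage1": self.stage1,
            "ga": self.ga,
            "evaluation": self.evaluation,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({**self.core(), "created": self.created}, indent=indent)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RunManifest":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            version=payload["version"],
            config=payload["config"],
            seeds=payload["seeds"],
            stage1=payload["stage1"],
            ga=payload["ga"],
            evaluation=payload.get("evaluation", {}),
            created=payload.get("created", ""),
        )

    def same_outputs(self, other: "RunManifest") -> bool:
        return self.core() == other.core()


def run_pipeline(
    table: FeatureTable,
    stage1_policy: str = "nonzero_gain",
    stage1_cap: int | None = 40,
    ga_config: GAConfig | None = None,
    fitness_spec: FitnessSpec | None = None,
    eval_repeats: int = 20,
    eval_folds: int = 5,
    eval_seed: int = 0,
    transfer_target: FeatureTable | None = None,
    out_dir=None,
    progress=None,
) -> RunManifest:
    """Full run: stage-1 filter, GA search, repeated-CV evaluation of the
    selected subset, optional transfer evaluation on a second cohort.

    When ``out_dir`` is given, persists ``manifest.json``, the selected
    feature names (one per line in ``selected_features.txt``) and the
    stage-1 ranking (``stage1_ranking.tsv``).
    """
    model = GAFeatureSelector(
        table,
        stage1_policy=stage1_policy,
        stage1_cap=stage1_cap,
        ga_config=ga_config or GAConfig(),
        fitness_spec=fitness_spec or FitnessSpec(),
    )
    results = model.fit(progress=progress)
    reports = {
        "training_cv": results.evaluate(
            n_repeats=eval_repeats, n_folds=eval_folds, seed=eval_seed
        )
    }
    if transfer_target is not None:
        reports["transfer"] = results.transfer(
            transfer_target, n_repeats=eval_repeats, n_folds=eval_folds,
            seed=eval_seed,
        )
    manifest = results.manifest(reports)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.save(out / "manifest.json")
        (out / "selected_features.txt").write_text(
            "\n".join(results.selected_features) + "\n", encoding="utf-8"
        )
        results.ranking.to_tsv(out / "stage1_ranking.tsv")
    return manifest
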