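"""Model / Results interface over the two-stage selection procedure.

:class:`GAFeatureSelector` is constructed from a :class:`FeatureTable`
(or a DataFrame / CSV) plus the stage-1 policy, GA configuration and fitness
specification; ``fit()`` runs the gain-importance pre-filter followed by the
GA wrapper and returns a :class:`GAFeatureSelectionResults` carrying the
ranking, the evolution trajectory, the selected subset, and methods to
evaluate it (repeated-CV report, cross-cohort transfer, summary table,
trajectory plot, run manifest).
"""

from __future__ import annotations

from dataclasses import asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .data import FeatureTable, read_feature_table
from .errors import ConfigurationError
from .evaluation import EvaluationReport, repeated_cv_evaluate, transfer_evaluate
from .fitness import FitnessSpec
from .ga import GAConfig, GAResult, run_ga
from .stage1 import (
    DEFAULT_N_ROUNDS,
    ImportanceRanking,
    fit_gain_importance,
    select_stage1,
)

__all__ = ["GAFeatureSelector", "GAFeatureSelectionResults"]

_SEED_MOD = 2**31


class GAFeatureSelector:
    """Two-stage feature selector bound to one training table.

    Parameters
    ----------
    table : FeatureTable
        Training cohort (binary labels; positive class = 1).
    stage1_policy, stage1_cap :
        Pre-filter policy: ``"nonzero_gain"`` (default, optionally capped at
        ``stage1_cap``; default cap 40) or ``"top_k"`` with ``stage1_cap``
        as k.
    boosting_params, n_boost_rounds :
        Overrides for the stage-1 gradient-boosting fit.
    ga_config : GAConfig
        Evolution hyperparameters (defaults: population 100, crossover 0.8,
        mutation 0.05, 5000 generations, 2 elites).
    fitness_spec : FitnessSpec
        Wrapper fitness: classifier (rf/xgb/svm) and CV scheme.
    canonical_order : bool
        Sort samples by id before fold assignment so results are invariant
        to input row order (default True).
    """

    def __init__(
        self,
        table: FeatureTable,
        stage1_policy: str = "nonzero_gain",
        stage1_cap: int | None = 40,
        boosting_params: Mapping | None = None,
        n_boost_rounds: int = DEFAULT_N_ROUNDS,
        ga_config: GAConfig | None = None,
        fitness_spec: FitnessSpec | None = None,
        canonical_order: bool = True,
    ):
        self.table = table.sorted_by_sample_id() if canonical_order else table
        self.table.require_both_classes()
        self.stage1_policy = stage1_policy
        self.stage1_cap = stage1_cap
        self.boosting_params = dict(boosting_params or {})
        self.n_boost_rounds = n_boost_rounds
        self.ga_config = ga_config or GAConfig()
        self.fitness_spec = fitness_spec or FitnessSpec()
        self.canonical_order = canonical_order

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str,
        positive_label: object = 1,
        **kwargs,
    ) -> "GAFeatureSelector":
        table = FeatureTable.from_dataframe(df, label_column, positive_label)
        return cls(table, **kwargs)

    @classmethod
    def from_csv(
        cls,
        path,
        label_column: str,
        positive_label: object = 1,
        id_column: str | None = None,
        **kwargs,
    ) -> "GAFeatureSelector":
        table = read_feature_table(path, label_column, positive_label, id_column)
        return cls(table, **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int | None = None, progress=None) -> "GAFeatureSelectionResults":
        """Run stage 1 then the GA; ``seed`` overrides the config's master
        seed."""
        config = self.ga_config
        if seed is not None:
            config = replace(config, master_seed=int(seed))
        stage1_seed = int(
            np.random.SeedSequence(config.master_seed).generate_state(1)[0]
            % _SEED_MOD
        )
        ranking = fit_gain_importance(
            self.table,
            params=self.boosting_params,
            n_rounds=self.n_boost_rounds,
            seed=stage1_seed,
        )
        candidates = select_stage1(ranking, self.stage1_policy, self.stage1_cap)
        if len(candidates) < 2:
            raise ConfigurationError(
                "stage 1 retained fewer than 2 features; GA refuses to start"
            )
        ga_result = run_ga(
            candidates, self.table, config, self.fitness_spec, progress=progress
        )
        return GAFeatureSelectionResults(self, config, ranking, candidates, ga_result)


class GAFeatureSelectionResults:
    """Fitted two-stage selection run."""

    def __init__(
        self,
        model: GAFeatureSelector,
        config: GAConfig,
        ranking: ImportanceRanking,
        candidates: tuple[str, ...],
        ga_result: GAResult,
    ):
        self.model = model
        self.config = config
        self.ranking = ranking
        self.candidates = candidates
        self.ga_result = ga_result

    # -- accessors ---------------------------------------------------------

    @property
    def selected_features(self) -> tuple[str, ...]:
        return self.ga_result.selected_feature_names

    @property
    def best_fitness(self) -> float:
        return self.ga_result.best_fitness

    @property
    def best_generation(self) -> int:
        return self.ga_result.best_generation

    def trajectory_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.ga_result.trajectory_best)),
                "best_fitness": self.ga_result.trajectory_best,
                "mean_fitness": self.ga_result.trajectory_mean,
            }
        )

    # -- evaluation --------------------------------------------------------

    def evaluate(
        self, n_repeats: int = 20, n_folds: int = 5, seed: int = 0
    ) -> EvaluationReport:
        """Repeated-CV report of the selected subset on the training table.

        Note this re-uses the table the subset was selected on, so the
        metrics carry wrapper selection bias; use :meth:`transfer` with an
        independent cohort for an unbiased estimate.
        """
        return repeated_cv_evaluate(
            self.model.table,
            self.selected_features,
            self.model.fitness_spec,
            n_repeats=n_repeats,
            n_folds=n_folds,
            seed=seed,
        )

    def transfer(
        self,
        target: FeatureTable,
        n_repeats: int = 20,
        n_folds: int = 5,
        seed: int = 0,
    ) -> EvaluationReport:
        """Apply the frozen subset to another cohort without re-selection."""
        return transfer_evaluate(
            self.selected_features,
            target,
            self.model.fitness_spec,
            n_repeats=n_repeats,
            n_folds=n_folds,
            seed=seed,
        )

    # -- presentation ------------------------------------------------------

    def summary(self, max_features: int = 30) -> str:
        """Human-readable run summary."""
        m = self.model
        lines = [
            "Two-stage GA feature selection".center(62),
            "=" * 62,
            f"{'No. samples:':<28}{m.table.n_samples}",
            f"{'No. features (input):':<28}{m.table.n_features}",
            f"{'Class counts (neg/pos):':<28}"
            f"{m.table.class_counts[0]}/{m.table.class_counts[1]}",
            f"{'Stage-1 policy:':<28}{m.stage1_policy}"
            + (f" (cap {m.stage1_cap})" if m.stage1_cap else ""),
            f"{'Stage-1 candidates:':<28}{len(self.candidates)}",
            f"{'Fitness classifier:':<28}{m.fitness_spec.classifier_id}"
            f" ({m.fitness_spec.n_repeats}x{m.fitness_spec.n_folds}-fold CV)",
            f"{'Population / generations:':<28}"
            f"{self.config.population_size} / {self.config.n_generations}",
            f"{'Crossover / mutation rate:':<28}"
            f"{self.config.crossover_rate} / {self.config.mutation_rate}",
            f"{'Master seed:':<28}{self.config.master_seed}",
            "-" * 62,
            f"{'Best fitness (ACC-bar):':<28}{self.best_fitness:.4f}"
            f"  at generation {self.best_generation}",
            f"{'Selected features:':<28}{len(self.selected_features)}",
            "-" * 62,
        ]
        for name in self.selected_features[:max_features]:
            lines.append(f"  {name}")
        if len(self.selected_features) > max_features:
            lines.append(f"  ... ({len(self.selected_features) - max_features} more)")
        lines.append("=" * 62)
        return "\n".join(lines)

    def plot_trajectory(self, ax=None):
        """Best/mean fitness per generation."""
        from .plots import plot_trajectory

        return plot_trajectory(
            self.ga_result.trajectory_best, self.ga_result.trajectory_mean, ax=ax
        )

    def manifest(self, reports: Mapping[str, EvaluationReport] | None = None):
        """Build a :class:`~gaselect.pipeline.RunManifest` for this run."""
        from .pipeline import RunManifest

        m = self.model
        return RunManifest(
            version=_pkg_version,
            config={
                "stage1_policy": m.stage1_policy,
                "stage1_cap": m.stage1_cap,
                "boosting_params": dict(m.boosting_params),
                "n_boost_rounds": m.n_boost_rounds,
                "ga": asdict(self.config),
                "fitness": {
                    "classifier_id": m.fitness_spec.classifier_id,
                    "classifier_params": dict(m.fitness_spec.classifier_params),
                    "n_folds": m.fitness_spec.n_folds,
                    "n_repeats": m.fitness_spec.n_repeats,
                },
            },
            seeds={"master_seed": self.config.master_seed},
            stage1={
                "n_candidates": len(self.candidates),
                "candidates": list(self.candidates),
                "ranking": [[n, g] for n, g in self.ranking.entries],
            },
            ga={
                "best_fitness": self.best_fitness,
                "best_generation": self.best_generation,
                "n_selected": len(self.selected_features),
                "selected_features": list(self.selected_features),
                "best_chromosome": "".join(
                    str(int(b)) for b in self.ga_result.best_chromosome
                ),
                "trajectory_best": list(self.ga_result.trajectory_best),
                "trajectory_mean": list(self.ga_result.trajectory_mean),
                "n_evaluations": self.ga_result.n_evaluations,
            },
            evaluation={
                name: rep.to_dict() for name, rep in (reports or {}).items()
            },
        )
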