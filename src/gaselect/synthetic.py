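"""Radiomics-like synthetic feature tables with planted ground truth.

Real radiomics tables are small-n / large-d: tens of patients, hundreds of
correlated real-valued texture/intensity/histogram features, near-balanced
binary labels, and only a handful of genuinely class-informative columns.
The generator emulates exactly that shape so every pipeline stage can be
tested against a known answer:

* **informative** features share an equicorrelated latent factor
  (correlation ``rho``) and have their class-1 mean shifted by ``delta``
  standard deviations (each marginal has unit variance, so ``delta`` is the
  standardized effect size; a single feature's theoretical two-class AUC is
  Phi(delta / sqrt(2)));
* **redundant** features are noisy linear copies of informative ones —
  radiomics feature families are notoriously collinear;
* the remaining features are independent standard-normal noise.

Column order and names carry no role information; the ground-truth
informative names are returned separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FeatureTable
from .errors import ConfigurationError

__all__ = ["SyntheticSpec", "generate"]

# Radiomics-flavored name stems; assigned independently of a column's role.
_FAMILIES = (
    "TEXTURE_GLCM", "TEXTURE_GLRLM", "TEXTURE_GLSZM", "TEXTURE_NGTDM",
    "HISTO", "INTENSITY", "VOLUME", "MORPH",
)
_MODALITIES = ("T1", "T1Gd", "T2", "FLAIR")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate a small radiomics cohort: 60 samples, 200 features of
    which 10 are informative (standardized shift 1.2) and 10 redundant,
    within-block correlation 0.3, balanced classes.
    """

    n_samples: int = 60
    n_features: int = 200
    n_informative: int = 10
    effect_size: float = 1.2  # standardized class mean shift (delta)
    n_redundant: int = 10
    correlation: float = 0.3  # within-block feature correlation (rho)
    class_balance: float = 0.5
    heavy_tailed: bool = False
    seed: int = 0
    #: seed for the cohort *design* (feature names, column order, redundant
    #: wiring).  Defaults to ``seed``.  Two specs sharing a design_seed but
    #: differing in ``seed`` model independent cohorts measured by the same
    #: feature-extraction pipeline — the transfer-evaluation scenario.
    design_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ConfigurationError(
                "n_informative + n_redundant must not exceed n_features"
            )
        if self.n_informative < 1:
            raise ConfigurationError("need at least one informative feature")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not 0.0 <= self.correlation < 1.0:
            raise ConfigurationError("correlation must lie in [0, 1)")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigurationError("class_balance must lie in (0, 1)")
        if self.n_samples < 8:
            raise ConfigurationError("n_samples too small for stratified CV")


def _standardized_noise(
    rng: np.random.Generator, shape: tuple, heavy_tailed: bool
) -> np.ndarray:
    if heavy_tailed:
        df = 4  # finite-variance heavy tails
        return rng.standard_t(df, size=shape) / np.sqrt(df / (df - 2))
    return rng.standard_normal(shape)


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, tuple[str, ...]]:
    """Draw one cohort; returns ``(table, informative_feature_names)``.

    Deterministic for a fixed ``spec.seed``.  Class counts are fixed at
    ``round(n_samples * class_balance)`` positives (shuffled over rows) so
    small cohorts always contain both classes, mirroring the near-balanced
    case-control design the method assumes.
    """
    rng = np.random.default_rng(spec.seed)
    design_rng = np.random.default_rng(
        spec.seed if spec.design_seed is None else spec.design_seed
    )
    n, d = spec.n_samples, spec.n_features
    k, r = spec.n_informative, spec.n_redundant

    n_pos = int(round(n * spec.class_balance))
    n_pos = min(max(n_pos, 2), n - 2)
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[:n_pos]] = 1

    rho = spec.correlation
    common = _standardized_noise(rng, (n, 1), spec.heavy_tailed)
    eps = _standardized_noise(rng, (n, k), spec.heavy_tailed)
    informative = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * eps
    informative += spec.effect_size * y[:, None]

    # noisy linear copies: corr(source, copy) = 1/sqrt(1 + tau^2) ~ 0.89
    tau = 0.5
    sources = design_rng.integers(0, k, size=r)
    redundant = informative[:, sources] + tau * _standardized_noise(
        rng, (n, r), spec.heavy_tailed
    )

    noise = _standardized_noise(rng, (n, d - k - r), spec.heavy_tailed)

    values = np.concatenate([informative, redundant, noise], axis=1)
    col_order = design_rng.permutation(d)
    values = values[:, col_order]

    names = tuple(
        f"{design_rng.choice(_FAMILIES)}_{design_rng.choice(_MODALITIES)}_F{i:04d}"
        for i in range(d)
    )
    sample_ids = tuple(f"S{i:04d}" for i in range(n))
    table = FeatureTable(sample_ids, names, values, y)

    # informative columns occupied original slots 0..k-1 before the shuffle
    inv = np.empty(d, dtype=int)
    inv[col_order] = np.arange(d)
    truth = tuple(names[inv[j]] for j in range(k))
    return table, truth
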