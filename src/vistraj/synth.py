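"""Synthetic longitudinal cohorts with a known trajectory-class structure.

The generator draws each subject's latent class from a categorical
distribution, growth factors (intercept, slope) from a class-specific
normal, and wave-level vision scores from the linear growth model

    y_iw = eta0_i + eta1_i * t_w + eps_iw,   eps_iw ~ N(0, theta_w),

optionally clamped to the 1-4 instrument range. Baseline predictors are
drawn from class-conditional distributions and distal outcomes from
class-shifted linear / logistic models, so that every downstream analysis
stage has a known generating truth to recover.

The packaged ``paper_like`` configuration encodes a two-class cohort
(81.9% high-baseline declining, 18.1% low-baseline improving) with
class-conditional predictor distributions and outcome shifts matching a
published visual-trajectory analysis of a Chinese ageing cohort; see
``docs/methods.md`` for the provenance of each number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from vistraj.errors import ConfigError

__all__ = [
    "PredictorSpec",
    "OutcomeSpec",
    "SimConfig",
    "CohortTable",
    "simulate_trajectories",
    "simulate_covariates_outcomes",
    "apply_missingness",
    "simulate_cohort",
    "paper_like",
    "null_one_class",
    "load_config",
]


@dataclass
class PredictorSpec:
    """Class-conditional distribution of one baseline predictor.

    kind
        ``"binary"``: ``class_probs`` holds P(X=1) per class.
        ``"categorical"``: ``levels`` names the categories and
        ``class_probs`` holds one probability vector per class.
        ``"continuous"``: normal with per-class ``class_loc``/``class_scale``.
    """

    name: str
    kind: str
    class_probs: list | None = None
    levels: list[str] | None = None
    class_loc: list[float] | None = None
    class_scale: list[float] | None = None

    def validate(self, n_classes: int) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ConfigError(f"unknown predictor kind {self.kind!r} for {self.name}")
        if self.kind == "continuous":
            if self.class_loc is None or self.class_scale is None:
                raise ConfigError(f"{self.name}: continuous spec needs loc/scale")
            if len(self.class_loc) != n_classes or len(self.class_scale) != n_classes:
                raise ConfigError(f"{self.name}: loc/scale length != n_classes")
            if any(s < 0 for s in self.class_scale):
                raise ConfigError(f"{self.name}: negative scale")
            return
        if self.class_probs is None or len(self.class_probs) != n_classes:
            raise ConfigError(f"{self.name}: class_probs length != n_classes")
        if self.kind == "binary":
            if any(not 0.0 <= p <= 1.0 for p in self.class_probs):
                raise ConfigError(f"{self.name}: probability outside [0, 1]")
        else:
            if self.levels is None or len(self.levels) < 2:
                raise ConfigError(f"{self.name}: categorical spec needs levels")
            for probs in self.class_probs:
                if len(probs) != len(self.levels):
                    raise ConfigError(f"{self.name}: probs/levels length mismatch")
                if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                    raise ConfigError(f"{self.name}: probs must be a distribution")


@dataclass
class OutcomeSpec:
    """Class-shifted distal outcome.

    Continuous: ``baseline + class_shift[k] + sum(coef * predictor) + noise``.
    Binary: logistic with log-odds ``baseline + class_shift[k] + ...``.
    """

    name: str
    kind: str
    baseline: float
    class_shift: list[float]
    noise_scale: float = 1.0
    covariate_coefs: dict[str, float] = field(default_factory=dict)

    def validate(self, n_classes: int) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ConfigError(f"unknown outcome kind {self.kind!r} for {self.name}")
        if len(self.class_shift) != n_classes:
            raise ConfigError(f"{self.name}: class_shift length != n_classes")
        if self.noise_scale < 0:
            raise ConfigError(f"{self.name}: negative noise scale")


@dataclass
class SimConfig:
    """Full description of a synthetic cohort.

    ``class_proportions``, ``class_means`` (intercept, slope per class),
    ``factor_cov`` (2x2, shared across classes) and ``residual_var``
    (scalar or one value per wave) define the growth mixture;
    ``predictor_specs``/``outcome_specs`` define the cross-sectional part.
    """

    n_subjects: int
    n_waves: int = 4
    time_scores: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    class_proportions: tuple[float, ...] = (1.0,)
    class_means: tuple[tuple[float, float], ...] = ((3.745, -0.088),)
    factor_cov: tuple[tuple[float, float], ...] = ((0.30, 0.0), (0.0, 0.01))
    residual_var: float | tuple[float, ...] = 0.20
    censor_to_scale: bool = False
    predictor_specs: list[PredictorSpec] = field(default_factory=list)
    outcome_specs: list[OutcomeSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int | None = None

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    @property
    def theta(self) -> np.ndarray:
        if np.isscalar(self.residual_var):
            return np.full(self.n_waves, float(self.residual_var))
        return np.asarray(self.residual_var, dtype=float)

    @property
    def psi(self) -> np.ndarray:
        return np.asarray(self.factor_cov, dtype=float)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be positive")
        if self.n_classes == 0:
            raise ConfigError("at least one class required")
        pi = np.asarray(self.class_proportions, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi <= 0):
            raise ConfigError("class_proportions must be positive and sum to 1")
        if len(self.class_means) != self.n_classes:
            raise ConfigError("class_means length != number of classes")
        psi = self.psi
        if psi.shape != (2, 2) or abs(psi[0, 1] - psi[1, 0]) > 1e-12:
            raise ConfigError("factor_cov must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(psi) < -1e-10):
            raise ConfigError("factor_cov must be positive semi-definite")
        theta = self.theta
        if theta.shape != (self.n_waves,) or np.any(theta < 0):
            raise ConfigError("residual_var must be >= 0, one per wave")
        t = np.asarray(self.time_scores, dtype=float)
        if t.shape != (self.n_waves,) or np.any(np.diff(t) <= 0):
            raise ConfigError("time_scores must be strictly increasing")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        for spec in self.predictor_specs:
            spec.validate(self.n_classes)
        for spec in self.outcome_specs:
            spec.validate(self.n_classes)

    # -- (de)serialisation -------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["predictor_specs"] = [
            p if isinstance(p, PredictorSpec) else PredictorSpec(**p)
            for p in d.get("predictor_specs", [])
        ]
        d["outcome_specs"] = [
            o if isinstance(o, OutcomeSpec) else OutcomeSpec(**o)
            for o in d.get("outcome_specs", [])
        ]
        for key in ("time_scores", "class_proportions"):
            if key in d:
                d[key] = tuple(d[key])
        if "class_means" in d:
            d["class_means"] = tuple(tuple(m) for m in d["class_means"])
        if "factor_cov" in d:
            d["factor_cov"] = tuple(tuple(r) for r in d["factor_cov"])
        if isinstance(d.get("residual_var"), (list, tuple)):
            d["residual_var"] = tuple(d["residual_var"])
        return cls(**d)

    def with_overrides(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class CohortTable:
    """Wide per-subject table: vision per wave, predictors, outcomes.

    ``true_class`` is the generating label; estimation code must consume
    :meth:`estimation_view`, which omits it.
    """

    data: pd.DataFrame
    n_waves: int
    predictor_names: list[str] = field(default_factory=list)
    outcome_names: list[str] = field(default_factory=list)

    @property
    def vision_cols(self) -> list[str]:
        return [f"vision_w{w + 1}" for w in range(self.n_waves)]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def vision_matrix(self) -> np.ndarray:
        """(n, n_waves) float array with NaN for missing observations."""
        return self.data[self.vision_cols].to_numpy(dtype=float)

    def estimation_view(self) -> pd.DataFrame:
        """The table without the generating class label."""
        return self.data.drop(columns=["true_class"], errors="ignore")

    def complete_cases(self) -> "CohortTable":
        """Subjects with a vision score observed at every wave."""
        keep = self.data[self.vision_cols].notna().all(axis=1)
        return replace(self, data=self.data.loc[keep].reset_index(drop=True))

    def with_min_waves(self, m: int) -> "CohortTable":
        """Subjects with at least ``m`` observed waves."""
        keep = self.data[self.vision_cols].notna().sum(axis=1) >= m
        return replace(self, data=self.data.loc[keep].reset_index(drop=True))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per generation stage."""
    if config.seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def simulate_trajectories(config: SimConfig) -> CohortTable:
    """Draw latent classes, growth factors, and wave-level vision scores."""
    config.validate()
    rng = _rng(config, 0)
    n = config.n_subjects
    pi = np.asarray(config.class_proportions, dtype=float)
    alpha = np.asarray(config.class_means, dtype=float)  # (K, 2)
    t = np.asarray(config.time_scores, dtype=float)
    lam = np.column_stack([np.ones_like(t), t])  # (p, 2)

    cls = rng.choice(len(pi), size=n, p=pi)
    # growth factors: class mean + shared-covariance deviation
    chol = np.linalg.cholesky(config.psi + 1e-12 * np.eye(2))
    eta = alpha[cls] + rng.standard_normal((n, 2)) @ chol.T
    eps = rng.standard_normal((n, config.n_waves)) * np.sqrt(config.theta)
    y = eta @ lam.T + eps
    if config.censor_to_scale:
        y = np.clip(y, 1.0, 4.0)

    df = pd.DataFrame({"id": np.arange(1, n + 1)})
    for w in range(config.n_waves):
        df[f"vision_w{w + 1}"] = y[:, w]
    df["true_class"] = cls
    return CohortTable(data=df, n_waves=config.n_waves)


def simulate_covariates_outcomes(table: CohortTable, config: SimConfig) -> CohortTable:
    """Fill class-conditional predictors and class-shifted outcomes."""
    config.validate()
    if "true_class" not in table.data.columns:
        raise ConfigError("true_class required to draw class-conditional covariates")
    rng = _rng(config, 1)
    df = table.data.copy()
    cls = df["true_class"].to_numpy()
    n = len(df)

    for spec in config.predictor_specs:
        if spec.kind == "binary":
            p = np.asarray(spec.class_probs, dtype=float)[cls]
            df[spec.name] = (rng.random(n) < p).astype(int)
        elif spec.kind == "categorical":
            probs = np.asarray(spec.class_probs, dtype=float)
            probs = probs / probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            cum = np.cumsum(probs[cls], axis=1)
            idx = (u[:, None] > cum).sum(axis=1)
            df[spec.name] = pd.Categorical.from_codes(idx, categories=spec.levels)
        else:
            loc = np.asarray(spec.class_loc, dtype=float)[cls]
            scale = np.asarray(spec.class_scale, dtype=float)[cls]
            df[spec.name] = loc + scale * rng.standard_normal(n)

    for spec in config.outcome_specs:
        lin = spec.baseline + np.asarray(spec.class_shift, dtype=float)[cls]
        for cov, coef in spec.covariate_coefs.items():
            lin = lin + coef * pd.to_numeric(df[cov]).to_numpy()
        if spec.kind == "continuous":
            df[spec.name] = lin + spec.noise_scale * rng.standard_normal(n)
        else:
            p = 1.0 / (1.0 + np.exp(-lin))
            df[spec.name] = (rng.random(n) < p).astype(int)

    return replace(
        table,
        data=df,
        predictor_names=[s.name for s in config.predictor_specs],
        outcome_names=[s.name for s in config.outcome_specs],
    )


def apply_missingness(table: CohortTable, config: SimConfig) -> CohortTable:
    """Mask each vision observation independently (MCAR) at ``missing_rate``."""
    config.validate()
    if config.missing_rate == 0.0:
        return table
    rng = _rng(config, 2)
    df = table.data.copy()
    y = df[table.vision_cols].to_numpy(dtype=float)
    mask = rng.random(y.shape) < config.missing_rate
    y[mask] = np.nan
    df[table.vision_cols] = y
    return replace(table, data=df)


def simulate_cohort(config: SimConfig) -> CohortTable:
    """Trajectories, covariates/outcomes, and missingness in one call."""
    table = simulate_trajectories(config)
    if config.predictor_specs or config.outcome_specs:
        table = simulate_covariates_outcomes(table, config)
    return apply_missingness(table, config)


def load_config(source) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML/JSON file path or mapping."""
    if isinstance(source, SimConfig):
        return source
    if isinstance(source, dict):
        return SimConfig.from_dict(source)
    with open(source) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh))


def _packaged(name: str, **overrides) -> SimConfig:
    text = resources.files("vistraj").joinpath("configs", name).read_text()
    cfg = SimConfig.from_dict(yaml.safe_load(text))
    return cfg.with_overrides(**overrides) if overrides else cfg


def paper_like(**overrides) -> SimConfig:
    """Two-class cohort matching the published visual-trajectory solution."""
    return _packaged("paper_like.yaml", **overrides)


def null_one_class(**overrides) -> SimConfig:
    """Single-class cohort (no trajectory heterogeneity)."""
    return _packaged("null_one_class.yaml", **overrides)
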