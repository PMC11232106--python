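"""Seeded synthetic-data generators with known truth.

Three study designs are provided, each emulating a typical epidemiological
regression problem with two-way interactions:

``sim1``
    n=200 samples of p=10 moderately collinear continuous covariates
    (multivariate normal, exchangeable correlation rho=0.3), giving q=45
    interactions. Five non-zero main effects and 13 non-zero interactions of
    three types: six between two non-zero mains ("both-main"), four between a
    non-zero and an absent main ("one-main"), and three "surprising" ones
    between two absent mains, two of which share a covariate — 18 non-zero
    coefficients in total. Main effects range from small to large, interaction
    effects from small to medium. The last two covariates carry no signal at
    all and act as pure noise controls.
``sim2``
    Sparser: n=500, the same signal structure, plus four independent
    standard-normal noise covariates (p=14, q=91); the signal of one main
    effect and of one interaction of each type is increased.
``helius_like``
    A mixed-type covariate set in the style of a large population cohort:
    three continuous covariates (age, packyears, bmi), three binaries
    (gender, smoking, coffee), one 5-level categorical (ethnicity) and four
    standard-normal noise columns — 14 encoded columns, 85 interaction terms.
    Covariates only; no response truth is defined for it.

Gaussian noise is calibrated so that the population R^2 of the true model is
0.5: ``sigma_eps^2 = Var(X beta) (1 - R^2) / R^2``, with ``Var(X beta)``
estimated once per setting by Monte Carlo (1e5 draws, fixed internal seed),
so the noise level is a deterministic function of the configuration.

The exact correlation level and effect sizes are package conventions (they
are configurable); the *structure* — dimensions, sparsity pattern,
interaction-type counts, R^2 target — defines the study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CovariateSchema

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "sim_config",
    "helius_like_schema",
    "simulate_covariates",
    "true_coefficients",
    "calibrate_noise",
    "generate_dataset",
    "replicates",
]

SETTINGS = ("sim1", "sim2", "helius_like")

# Interaction truth: (pair of 0-based covariate indices) -> (value, type).
# Six both-main, four one-main, three surprising; the surprising ones share
# covariate 6. Covariates 8 and 9 appear nowhere: pure noise controls.
_INTERACTIONS = {
    (0, 1): (0.30, "both-main"),
    (0, 2): (0.25, "both-main"),
    (1, 3): (0.20, "both-main"),
    (2, 4): (0.15, "both-main"),
    (3, 4): (0.12, "both-main"),
    (1, 2): (0.10, "both-main"),
    (0, 5): (0.25, "one-main"),
    (1, 6): (0.20, "one-main"),
    (3, 7): (0.15, "one-main"),
    (4, 5): (0.10, "one-main"),
    (5, 6): (0.30, "surprising"),
    (6, 7): (0.25, "surprising"),
    (5, 7): (0.15, "surprising"),
}
_MAINS = (1.0, 0.75, 0.5, 0.3, 0.15)
# sim2 is sparser; one main effect and one interaction of each type get a
# stronger signal there.
_SIM2_BOOSTS = {"main": (4, 0.5), (1, 2): 0.30, (4, 5): 0.30, (5, 7): 0.35}

_CALIBRATION_SEED = 202406  # fixed: noise level is a function of the config
_CALIBRATION_DRAWS = 100_000


@dataclass(frozen=True)
class SimulationConfig:
    setting: str = "sim1"
    n: int = 200
    p: int = 10
    n_noise: int = 0  # extra independent N(0,1) columns appended
    rho: float = 0.3
    target_r2: float = 0.5
    B: int = 50
    main_effects: tuple = _MAINS
    boost: bool = False  # sim2's increased signals

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if not (0 < self.target_r2 < 1):
            raise ValueError("target_r2 must be in (0, 1)")

    @property
    def p_total(self) -> int:
        return self.p + self.n_noise


def sim_config(setting: str, **overrides) -> SimulationConfig:
    """Standard configuration for one of the named study designs."""
    if setting == "sim1":
        cfg = SimulationConfig(setting="sim1", n=200, p=10)
    elif setting == "sim2":
        cfg = SimulationConfig(setting="sim2", n=500, p=10, n_noise=4, boost=True)
    elif setting == "helius_like":
        cfg = SimulationConfig(setting="helius_like", n=1000, p=10, n_noise=4)
    else:
        raise ValueError(f"unknown setting {setting!r}")
    return replace(cfg, **overrides) if overrides else cfg


def helius_like_schema() -> list:
    """Schema of the mixed-type cohort-style covariate set (14 encoded cols)."""
    return [
        CovariateSchema("age", "continuous"),
        CovariateSchema("packyears", "continuous"),
        CovariateSchema("bmi", "continuous"),
        CovariateSchema("gender", "binary"),
        CovariateSchema("smoking", "binary"),
        CovariateSchema("coffee", "binary"),
        CovariateSchema(
            "ethnicity", "categorical", ("dutch", "south-asian", "african", "turkish", "moroccan")
        ),
        CovariateSchema("noise1", "continuous"),
        CovariateSchema("noise2", "continuous"),
        CovariateSchema("noise3", "continuous"),
        CovariateSchema("noise4", "continuous"),
    ]


def _exchangeable_cov(p: int, rho: float) -> np.ndarray:
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError(f"rho={rho} makes the exchangeable correlation non-PSD for p={p}")
    return cov


def simulate_covariates(config: SimulationConfig, seed) -> pd.DataFrame:
    """Draw one covariate table. Same seed => bit-identical table."""
    rng = np.random.default_rng(seed)
    if config.setting in ("sim1", "sim2"):
        cov = _exchangeable_cov(config.p, config.rho)
        X = rng.multivariate_normal(np.zeros(config.p), cov, size=config.n, method="cholesky")
        cols = {f"x{j + 1}": X[:, j] for j in range(config.p)}
        for j in range(config.n_noise):
            cols[f"noise{j + 1}"] = rng.standard_normal(config.n)
        return pd.DataFrame(cols)

    # helius_like: mixed types; continuous block mildly correlated
    cov = _exchangeable_cov(3, config.rho)
    Z = rng.multivariate_normal(np.zeros(3), cov, size=config.n, method="cholesky")
    table = pd.DataFrame({"age": Z[:, 0], "packyears": Z[:, 1], "bmi": Z[:, 2]})
    for name, prob in (("gender", 0.5), ("smoking", 0.3), ("coffee", 0.7)):
        table[name] = (rng.uniform(size=config.n) < prob).astype(int)
    levels = helius_like_schema()[6].levels
    table["ethnicity"] = rng.choice(levels, size=config.n, p=(0.4, 0.2, 0.2, 0.1, 0.1))
    for j in range(4):
        table[f"noise{j + 1}"] = rng.standard_normal(config.n)
    return table


@dataclass(frozen=True)
class Truth:
    """True coefficients on the covariate scale of a simulation design."""

    beta_main: np.ndarray
    beta_int: np.ndarray  # aligned with lexicographic pairs over all columns
    pairs: tuple
    int_types: dict = field(default_factory=dict)  # pair -> type label

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.beta_main != 0) + np.sum(self.beta_int != 0))

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.beta_main, self.beta_int])


def true_coefficients(config: SimulationConfig) -> Truth:
    """Deterministic truth for sim1/sim2: 18 non-zero coefficients.

    Five non-zero mains; 13 non-zero interactions typed both-main / one-main
    / surprising (6, 4, 3). All coefficients on appended noise covariates are
    zero. sim2 (``boost=True``) strengthens one main effect and one
    interaction of each type.
    """
    if config.setting not in ("sim1", "sim2"):
        raise ValueError("true coefficients are defined for sim1 and sim2 only")
    p = config.p_total
    beta_main = np.zeros(p)
    beta_main[: len(config.main_effects)] = config.main_effects
    inter = {pair: (val, typ) for pair, (val, typ) in _INTERACTIONS.items()}
    if config.boost:
        j, val = _SIM2_BOOSTS["main"]
        beta_main[j] = val
        for pair, val in _SIM2_BOOSTS.items():
            if pair != "main":
                inter[pair] = (val, inter[pair][1])
    pairs = tuple((j, k) for j in range(p) for k in range(j + 1, p))
    beta_int = np.zeros(len(pairs))
    int_types = {}
    for t, pair in enumerate(pairs):
        if pair in inter:
            beta_int[t], int_types[pair] = inter[pair]
    return Truth(beta_main=beta_main, beta_int=beta_int, pairs=pairs, int_types=int_types)


def _linear_predictor(X: np.ndarray, truth: Truth) -> np.ndarray:
    mu = X @ truth.beta_main
    jj = np.array([j for j, _ in truth.pairs])
    kk = np.array([k for _, k in truth.pairs])
    return mu + (X[:, jj] * X[:, kk]) @ truth.beta_int


def calibrate_noise(config: SimulationConfig, n_mc: int = _CALIBRATION_DRAWS) -> float:
    """Noise s.d. sigma_eps giving population R^2 = target on the true model.

    Var(X beta) is estimated on a Monte-Carlo draw of ``n_mc`` covariate rows
    (fixed internal seed), then ``sigma_eps^2 = Var(X beta) (1 - R2) / R2``.
    """
    truth = true_coefficients(config)
    big = replace(config, n=n_mc)
    X = simulate_covariates(big, _CALIBRATION_SEED).to_numpy(dtype=float)
    signal_var = float(np.var(_linear_predictor(X, truth)))
    if signal_var == 0:
        raise ValueError("zero signal variance; cannot calibrate noise")
    r2 = config.target_r2
    return float(np.sqrt(signal_var * (1.0 - r2) / r2))


@dataclass
class SimulatedDataset:
    """One seeded replicate with its generating truth."""

    table: pd.DataFrame
    y: np.ndarray
    truth: Truth
    sigma_eps: float
    seed: int
    setting: str
    schema: list

    @property
    def n(self) -> int:
        return len(self.table)


def generate_dataset(
    config: SimulationConfig, seed, sigma_eps: float | None = None
) -> SimulatedDataset:
    """Covariates plus response ``y = X beta + eps``, eps ~ N(0, sigma_eps^2).

    The response is generated on the encoded (standardized) covariate scale;
    for sim1/sim2 the raw covariates already live on that scale. Pass
    ``sigma_eps`` to reuse a calibration across replicates; otherwise it is
    recomputed (deterministically) from the config.
    """
    truth = true_coefficients(config)  # rejects helius_like
    if sigma_eps is None:
        sigma_eps = calibrate_noise(config)
    table = simulate_covariates(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 1)))
    X = table.to_numpy(dtype=float)
    y = _linear_predictor(X, truth) + sigma_eps * rng.standard_normal(config.n)
    schema = [CovariateSchema(c, "continuous") for c in table.columns]
    return SimulatedDataset(
        table=table,
        y=y,
        truth=truth,
        sigma_eps=float(sigma_eps),
        seed=int(seed),
        setting=config.setting,
        schema=schema,
    )


def replicates(config: SimulationConfig, B: int, seed: int) -> list:
    """B replicate datasets with seeds ``seed+1 .. seed+B``, shared calibration."""
    sigma_eps = calibrate_noise(config)
    return [generate_dataset(config, seed + b, sigma_eps=sigma_eps) for b in range(1, B + 1)]
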