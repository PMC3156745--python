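"""Synthetic survival cohorts with prescribed ordinal-covariate/survival
rank correlations.

The generator emulates the kind of cohort the score was designed for: a few
dozen resected lung-cancer patients with ordinal stage components (T, N, M),
histology, and semi-quantitative immunostaining grades, whose Spearman
correlations with survival time match configured targets.

Construction is a one-factor Gaussian copula. A latent standard-normal
"health" factor Z0 drives survival; each covariate gets its own latent normal
with correlation rho to Z0 and is discretised into its ordinal categories by
thresholds matching the configured marginal probabilities. Survival times
follow a Weibull proportional-hazards model on the factor,

    T = (E * exp(b * Z0) / lam0) ** (1 / k),    E ~ Exp(1),

so a higher factor value lowers the hazard. Discretisation and the
exponential draw both attenuate rank correlations, so the latent rho for each
covariate is calibrated by pilot-simulation inversion: bisect rho until the
realized Spearman correlation of the ordinal covariate with T hits the
target. Follow-up is administratively censored at a time drawn uniformly
from the censoring window (patients accrued over a span and censused on one
date).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .cohort import Cohort, VariableSpec, cohort_from_arrays
from .errors import CalibrationError, ValidationError

#: Default marginal category counts, pooled over the two histology arms of the
#: cohort the defaults emulate (n = 63; zero-count categories keep their slot
#: in the admissible range but are never drawn).
DEFAULT_MARGIN_COUNTS: dict[str, list[int]] = {
    "T": [15, 26, 18, 3],
    "N": [31, 17, 11, 3],
    "M": [53, 10],
    "H": [31, 32],
    "CD68": [0, 3, 60, 0],
    "Gas6": [35, 24, 4, 0],
    "Cox2": [0, 5, 58, 0],
    "MMP2": [0, 20, 43, 0],
    "Notch3": [0, 10, 53, 0],
}

DEFAULT_SPECS: list[VariableSpec] = [
    VariableSpec("T", (1, 2, 3, 4)),
    VariableSpec("N", (0, 1, 2, 3)),
    VariableSpec("M", (0, 1)),
    VariableSpec("H", (1, 2)),
    VariableSpec("CD68", (1, 2, 3, 4)),
    VariableSpec("Gas6", (1, 2, 3, 4)),
    VariableSpec("Cox2", (1, 2, 3, 4)),
    VariableSpec("MMP2", (1, 2, 3, 4)),
    VariableSpec("Notch3", (1, 2, 3, 4)),
]

#: Default Spearman targets: the stage components are aggressive (negative),
#: the two macrophage-associated markers protective (positive), and the
#: remaining variables carry no real association with survival.
DEFAULT_TARGETS: dict[str, float] = {
    "T": -0.55,
    "N": -0.41,
    "M": -0.37,
    "Gas6": 0.31,
    "CD68": 0.32,
    "H": 0.0,
    "Cox2": 0.0,
    "MMP2": 0.0,
    "Notch3": 0.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``latent_coef`` is the log-hazard coefficient of the latent factor (sets
    how tightly survival follows the factor); ``weibull_shape`` the baseline
    Weibull shape (1 = exponential); ``baseline_median`` the median survival
    in months of a patient at factor zero; ``censor_window`` the uniform
    administrative-censoring range in months.
    """

    n: int = 63
    specs: tuple[VariableSpec, ...] = tuple(DEFAULT_SPECS)
    margins: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            k: tuple(np.asarray(v, dtype=float) / sum(v))
            for k, v in DEFAULT_MARGIN_COUNTS.items()
        }
    )
    target_correlations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGETS)
    )
    latent_coef: float = 3.0
    weibull_shape: float = 2.0
    baseline_median: float = 26.0
    censor_window: tuple[float, float] = (54.0, 101.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValidationError("cohort size must be >= 4")
        for name, probs in self.margins.items():
            probs = np.asarray(probs, dtype=float)
            if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
                raise ValidationError(f"margins for {name!r} must be a probability vector")
            spec = self._spec(name)
            if probs.size != spec.divisor:
                raise ValidationError(
                    f"margins for {name!r}: {probs.size} categories but spec has "
                    f"{spec.divisor} admissible values"
                )
        for name, r in self.target_correlations.items():
            if abs(r) >= 1:
                raise ValidationError(f"target correlation for {name!r} must satisfy |r| < 1")
            if name not in self.margins:
                raise ValidationError(f"target for {name!r} has no margins")

    def _spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise ValidationError(f"no VariableSpec for margin variable {name!r}")

    @property
    def baseline_rate(self) -> float:
        return float(np.log(2) / self.baseline_median**self.weibull_shape)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _thresholds(probs) -> np.ndarray:
    """Latent-normal cut points realising the marginal category probabilities."""
    cum = np.cumsum(np.asarray(probs, dtype=float))[:-1]
    return stats.norm.ppf(np.clip(cum, 0.0, 1.0))


def _discretize(z: np.ndarray, probs, spec: VariableSpec) -> np.ndarray:
    idx = np.searchsorted(_thresholds(probs), z, side="right")
    return np.asarray(spec.admissible_values, dtype=int)[idx]


def _survival_times(z0, expo, config: SimulationConfig) -> np.ndarray:
    return (
        expo * np.exp(config.latent_coef * z0) / config.baseline_rate
    ) ** (1.0 / config.weibull_shape)


def _rank_corr(a_ranked: np.ndarray, x: np.ndarray) -> float:
    return float(np.corrcoef(a_ranked, stats.rankdata(x))[0, 1])


_MAX_LATENT_RHO = 0.999
_calibration_cache: dict = {}


def calibrate_copula(
    targets: dict[str, float],
    config: SimulationConfig,
    *,
    pilot_n: int = 100_000,
    pilot_seed: int = 20_111_727,
) -> dict[str, float]:
    """Latent correlations whose realized ordinal-vs-survival Spearman
    correlations match the targets.

    Uses one common pilot sample (factor, per-variable noise, exponential
    draws) and bisects each variable's latent rho independently — the
    one-factor structure makes the realized correlation a monotone function
    of rho. Raises ``CalibrationError`` when a target exceeds the
    margin-limited ceiling (reported in the message).
    """
    key = (
        tuple(sorted(targets.items())),
        tuple(sorted((k, tuple(v)) for k, v in config.margins.items())),
        config.latent_coef,
        config.weibull_shape,
        config.baseline_median,
        pilot_n,
        pilot_seed,
    )
    if key in _calibration_cache:
        return dict(_calibration_cache[key])

    rng = np.random.default_rng(pilot_seed)
    z0 = rng.standard_normal(pilot_n)
    expo = rng.exponential(size=pilot_n)
    t = _survival_times(z0, expo, config)
    t_ranks = stats.rankdata(t)
    eps = rng.standard_normal(pilot_n)  # shared noise: common random numbers

    out: dict[str, float] = {}
    for name, target in targets.items():
        if target == 0.0:
            out[name] = 0.0
            continue
        spec = config._spec(name)
        probs = config.margins[name]

        def realized(rho: float) -> float:
            z = rho * z0 + np.sqrt(1.0 - rho * rho) * eps
            return _rank_corr(t_ranks, _discretize(z, probs, spec))

        sign = 1.0 if target > 0 else -1.0
        ceiling = realized(sign * _MAX_LATENT_RHO)
        if abs(target) >= abs(ceiling):
            raise CalibrationError(
                f"target Spearman {target:+.3f} for {name!r} exceeds the "
                f"attainable bound {ceiling:+.3f} for its margins"
            )
        rho = optimize.brentq(
            lambda r: sign * realized(sign * r) - abs(target),
            0.0,
            _MAX_LATENT_RHO,
            xtol=1e-4,
        )
        out[name] = float(sign * rho)

    _calibration_cache[key] = dict(out)
    return out


def latent_correlation_matrix(rhos: dict[str, float]) -> np.ndarray:
    """Full latent correlation matrix (factor + variables) implied by the
    one-factor loadings; checked positive definite before sampling."""
    names = list(rhos)
    loadings = np.array([rhos[n] for n in names])
    k = len(names) + 1
    mat = np.eye(k)
    mat[0, 1:] = loadings
    mat[1:, 0] = loadings
    mat[1:, 1:] = np.outer(loadings, loadings) + np.diag(1.0 - loadings**2)
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() <= 1e-12:
        bad = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(mat[i + 1, j + 1]) >= 1.0 - 1e-12
        ]
        raise CalibrationError(
            f"latent correlation matrix not positive definite; offending pairs: {bad}"
        )
    return mat


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort under the configured study conditions; deterministic
    for a given config (including its seed)."""
    rhos = calibrate_copula(config.target_correlations, config)
    latent_correlation_matrix(rhos)

    rng = np.random.default_rng(config.seed)
    z0 = rng.standard_normal(config.n)
    expo = rng.exponential(size=config.n)
    t_true = _survival_times(z0, expo, config)
    censor_at = rng.uniform(*config.censor_window, size=config.n)
    observed = np.minimum(t_true, censor_at)
    events = (t_true <= censor_at).astype(int)

    covariates = {}
    for name, probs in config.margins.items():
        rho = rhos.get(name, 0.0)
        eps = rng.standard_normal(config.n)
        z = rho * z0 + np.sqrt(1.0 - rho * rho) * eps
        covariates[name] = _discretize(z, probs, config._spec(name))

    specs = [s for s in config.specs if s.name in covariates]
    return cohort_from_arrays(observed, events, covariates, specs)


def expected_censoring_fraction(
    config: SimulationConfig, *, pilot_n: int = 200_000, pilot_seed: int = 7
) -> float:
    """Monte-Carlo expectation of the censored fraction under the config."""
    rng = np.random.default_rng(pilot_seed)
    z0 = rng.standard_normal(pilot_n)
    expo = rng.exponential(size=pilot_n)
    t = _survival_times(z0, expo, config)
    c = rng.uniform(*config.censor_window, size=pilot_n)
    return float((t > c).mean())
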