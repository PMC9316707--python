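"""Synthetic data generation for the selective-inference simulation study.

The simulation draws a latent Gaussian matrix ``Z`` with a blocked
correlation structure, transforms it column-wise to obtain mixed
continuous/binary predictors, standardizes the result, and generates a
linear outcome ``y = X beta + eps`` whose noise variance is calibrated so
that the *population* coefficient of determination of the linear predictor
equals a target R^2.  A validation outcome ``y'`` is drawn on the same
design with an independent error vector.

Two default scenario families are shipped:

* a *toy* grid — 4 Gaussian predictors, 7 blocked correlation matrices
  contrasting no with strong correlation, 10 coefficient structures
  spanning null / single-strong / mixed / dense-weak patterns, target
  R^2 in {0.2, 0.5, 0.8} and 5/10/50 observations per variable
  (full factorial: 630 scenarios);
* a *realistic-like* setup — 17 mixed continuous/binary predictors with a
  fixed blocked correlation, 13 coefficient structures (117 scenarios).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "CorrelationSpec",
    "TransformSpec",
    "Identity",
    "Affine",
    "Exponential",
    "Threshold",
    "ScenarioConfig",
    "SimulatedData",
    "build_correlation_matrix",
    "generate_design",
    "calibrate_noise",
    "generate_outcomes",
    "simulate_scenario",
    "toy_correlation_specs",
    "toy_beta_structures",
    "toy_grid",
    "realistic_correlation_spec",
    "realistic_transform_spec",
    "realistic_beta_structures",
    "realistic_grid",
]

# Internal seed and size of the calibration sample used to estimate the
# population covariance of transformed (non-Gaussian) predictors.
_CALIBRATION_SEED = 715_517
_CALIBRATION_ROWS = 1_000_000

_PD_TOL = 1e-10


# ---------------------------------------------------------------------------
# Correlation specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationSpec:
    """Blocked equicorrelation structure on ``p`` variables.

    ``blocks`` is a tuple of ``(member_indices, rho)`` pairs; every index may
    appear in at most one block.  Off-diagonal entries between variables not
    sharing a block equal ``cross_block_correlation`` (default 0).
    """

    p: int
    blocks: tuple = ()
    cross_block_correlation: float = 0.0

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("p must be a positive integer")
        norm_blocks = []
        seen: set[int] = set()
        for members, rho in self.blocks:
            members = tuple(sorted(int(i) for i in members))
            if any(i < 0 or i >= self.p for i in members):
                raise ValueError(f"block {members} has indices outside 0..{self.p - 1}")
            if len(set(members)) != len(members):
                raise ValueError(f"block {members} repeats an index")
            if seen & set(members):
                raise ValueError(f"block {members} overlaps another block")
            seen.update(members)
            rho = float(rho)
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"block correlation {rho} outside [-1, 1]")
            norm_blocks.append((members, rho))
        if not -1.0 <= self.cross_block_correlation <= 1.0:
            raise ValueError("cross_block_correlation outside [-1, 1]")
        object.__setattr__(self, "blocks", tuple(norm_blocks))


def build_correlation_matrix(spec: CorrelationSpec) -> np.ndarray:
    """Realize the ``p x p`` correlation matrix of a :class:`CorrelationSpec`.

    Raises :class:`ValueError` with a diagnostic naming the offending block
    when the specification is not positive definite (smallest eigenvalue
    below 1e-10).
    """
    p = spec.p
    r = np.full((p, p), float(spec.cross_block_correlation))
    for members, rho in spec.blocks:
        idx = np.array(members)
        r[np.ix_(idx, idx)] = rho
    np.fill_diagonal(r, 1.0)
    # Per-block check first: a k-variable equicorrelation block has
    # eigenvalues 1 + (k-1) rho and 1 - rho.
    for members, rho in spec.blocks:
        k = len(members)
        if k >= 2 and min(1.0 + (k - 1) * rho, 1.0 - rho) <= _PD_TOL:
            raise ValueError(
                f"block {members} with correlation {rho} is not positive "
                f"definite (equicorrelation eigenvalue "
                f"{min(1.0 + (k - 1) * rho, 1.0 - rho):.3g})"
            )
    lam_min = float(np.linalg.eigvalsh(r).min())
    if lam_min <= _PD_TOL:
        raise ValueError(
            f"correlation specification is not positive definite "
            f"(smallest eigenvalue {lam_min:.3g}); check block overlap with "
            f"cross_block_correlation={spec.cross_block_correlation}"
        )
    return r


# ---------------------------------------------------------------------------
# Column-wise transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Identity:
    def __call__(self, z: np.ndarray) -> np.ndarray:
        return z


@dataclass(frozen=True)
class Affine:
    """``a + b * z``."""

    a: float = 0.0
    b: float = 1.0

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.a + self.b * z


@dataclass(frozen=True)
class Exponential:
    """``exp(scale * z)`` — a log-normal margin."""

    scale: float = 1.0

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return np.exp(self.scale * z)


@dataclass(frozen=True)
class Threshold:
    """``1[z > cutpoint]`` — a binary margin with prevalence ``Phi(-cut)``."""

    cutpoint: float = 0.0

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return (z > self.cutpoint).astype(float)


@dataclass(frozen=True)
class TransformSpec:
    """Per-variable marginal transforms applied to the latent Gaussian."""

    transforms: tuple

    def __post_init__(self):
        object.__setattr__(self, "transforms", tuple(self.transforms))

    @classmethod
    def identity(cls, p: int) -> "TransformSpec":
        return cls(tuple(Identity() for _ in range(p)))

    @property
    def p(self) -> int:
        return len(self.transforms)

    @property
    def is_identity(self) -> bool:
        return all(isinstance(t, Identity) for t in self.transforms)

    def apply(self, z: np.ndarray) -> np.ndarray:
        if z.shape[1] != self.p:
            raise ValueError("transform count does not match number of columns")
        return np.column_stack([t(z[:, j]) for j, t in enumerate(self.transforms)])


def _check_degenerate(transforms: TransformSpec) -> None:
    for j, t in enumerate(transforms.transforms):
        if isinstance(t, Threshold):
            prev = norm.sf(t.cutpoint)
            if prev < 1e-6 or prev > 1 - 1e-6:
                raise ValueError(
                    f"threshold transform on column {j} (cutpoint {t.cutpoint}) "
                    f"produces an (almost) constant column"
                )
        if isinstance(t, Affine) and t.b == 0:
            raise ValueError(f"affine transform on column {j} has zero slope")


# ---------------------------------------------------------------------------
# Scenario configuration and simulated data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid."""

    correlation: CorrelationSpec
    transforms: TransformSpec
    beta: tuple
    target_r2: float
    obs_per_variable: int
    confidence_level: float = 0.90
    n_iterations: int = 900
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        p = self.correlation.p
        if len(self.beta) != p or self.transforms.p != p:
            raise ValueError("beta/transform lengths must equal correlation p")
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target_r2 must lie in (0, 1)")
        if not 0.0 < self.confidence_level < 1.0:
            raise ValueError("confidence_level must lie in (0, 1)")
        if self.obs_per_variable < 1 or self.n < p + 2:
            raise ValueError("need n = obs_per_variable * p >= p + 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")

    @property
    def p(self) -> int:
        return self.correlation.p

    @property
    def n(self) -> int:
        return self.obs_per_variable * self.correlation.p


@dataclass
class SimulatedData:
    """Design, outcomes and the population quantities they were drawn from."""

    X: np.ndarray
    y: np.ndarray
    y_valid: np.ndarray
    sigma_true: float
    Sigma_true: np.ndarray
    beta_true: np.ndarray


# ---------------------------------------------------------------------------
# Design generation
# ---------------------------------------------------------------------------

_sigma_cache: dict = {}


def _transformed_correlation(
    corr: np.ndarray, transforms: TransformSpec, rows: int = _CALIBRATION_ROWS
) -> np.ndarray:
    """Population correlation of the transformed predictors.

    Analytic for identity transforms; otherwise estimated on a large
    calibration sample drawn with a fixed internal seed (so that the target
    R^2 is a scenario property, independent of the realized design).
    """
    if transforms.is_identity:
        return corr.copy()
    key = (corr.tobytes(), corr.shape[0], transforms, rows)
    if key in _sigma_cache:
        return _sigma_cache[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    chol = np.linalg.cholesky(corr)
    p = corr.shape[0]
    # accumulate first/second moments in chunks to bound memory
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    done = 0
    chunk = 100_000
    while done < rows:
        m = min(chunk, rows - done)
        w = transforms.apply(rng.standard_normal((m, p)) @ chol.T)
        s1 += w.sum(axis=0)
        s2 += w.T @ w
        done += m
    mean = s1 / rows
    cov = s2 / rows - np.outer(mean, mean)
    sd = np.sqrt(np.diag(cov))
    sigma = cov / np.outer(sd, sd)
    np.fill_diagonal(sigma, 1.0)
    _sigma_cache[key] = sigma
    return sigma


def generate_design(
    corr_matrix: np.ndarray,
    transforms: TransformSpec,
    n: int,
    seed,
    calibration_rows: int = _CALIBRATION_ROWS,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``Z ~ N(0, corr)``, transform, and standardize.

    Returns ``(X, Sigma_true)`` where X has columns with mean 0 and unit
    SD (divisor n-1) and ``Sigma_true`` is the population correlation of
    the transformed predictors.
    """
    if n < 2:
        raise ValueError("need n >= 2 to standardize")
    _check_degenerate(transforms)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr_matrix)
    z = rng.standard_normal((n, corr_matrix.shape[0])) @ chol.T
    w = transforms.apply(z)
    sd = w.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.argmin(sd))
        raise ValueError(f"column {j} is constant after transformation")
    x = (w - w.mean(axis=0)) / sd
    sigma = _transformed_correlation(corr_matrix, transforms, calibration_rows)
    return x, sigma


def calibrate_noise(Sigma_true: np.ndarray, beta, target_r2: float) -> float:
    """Noise SD giving population R^2 = ``target_r2`` for ``y = X beta + eps``.

    Solves R^2 = b'Sb / (b'Sb + sigma^2) for sigma.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must lie in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    signal = float(beta @ Sigma_true @ beta)
    if signal <= 0.0:
        raise ValueError("beta carries no signal; cannot calibrate noise to a positive R^2")
    return math.sqrt(signal * (1.0 - target_r2) / target_r2)


def generate_outcomes(
    X: np.ndarray, beta, sigma: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Training and validation outcomes with independent N(0, sigma^2) errors."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.size:
        raise ValueError("beta length does not match design")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = X @ beta
    y = mu + sigma * rng.standard_normal(X.shape[0])
    y_valid = mu + sigma * rng.standard_normal(X.shape[0])
    return y, y_valid


def scenario_noise_sd(scenario: ScenarioConfig, Sigma_true: np.ndarray) -> float:
    """Noise SD for a scenario; a null coefficient vector yields sigma = 1."""
    if all(b == 0.0 for b in scenario.beta):
        return 1.0
    return calibrate_noise(Sigma_true, scenario.beta, scenario.target_r2)


def simulate_scenario(scenario: ScenarioConfig, seed=None) -> SimulatedData:
    """Generate one complete dataset for a scenario."""
    if seed is None:
        seed = scenario.seed
    ss = np.random.SeedSequence(seed)
    s_design, s_outcome = ss.spawn(2)
    corr = build_correlation_matrix(scenario.correlation)
    x, sigma_mat = generate_design(corr, scenario.transforms, scenario.n, np.random.default_rng(s_design))
    noise_sd = scenario_noise_sd(scenario, sigma_mat)
    y, y_valid = generate_outcomes(x, scenario.beta, noise_sd, np.random.default_rng(s_outcome))
    return SimulatedData(
        X=x,
        y=y,
        y_valid=y_valid,
        sigma_true=noise_sd,
        Sigma_true=sigma_mat,
        beta_true=np.asarray(scenario.beta, dtype=float),
    )


# ---------------------------------------------------------------------------
# Default scenario grids
# ---------------------------------------------------------------------------

def toy_correlation_specs() -> list[CorrelationSpec]:
    """Seven blocked 4-variable correlation structures (none to strong)."""
    return [
        CorrelationSpec(4),                                            # independent
        CorrelationSpec(4, blocks=(((0, 1), 0.8),)),                   # one strong pair
        CorrelationSpec(4, blocks=(((0, 1), 0.8), ((2, 3), 0.8))),     # two strong pairs
        CorrelationSpec(4, blocks=(((0, 1, 2), 0.8),)),                # strong triple
        CorrelationSpec(4, blocks=(((0, 1, 2, 3), 0.8),)),             # all strong
        CorrelationSpec(4, blocks=(((0, 1), 0.4),)),                   # one moderate pair
        CorrelationSpec(4, blocks=(((0, 1, 2, 3), 0.4),)),             # all moderate
    ]


def toy_beta_structures() -> list[tuple]:
    """Ten coefficient patterns: null, single strong, mixed, dense weak/strong."""
    return [
        (0.0, 0.0, 0.0, 0.0),
        (1.0, 0.0, 0.0, 0.0),
        (0.0, 0.0, 1.0, 0.0),
        (1.0, 1.0, 0.0, 0.0),
        (1.0, 0.5, 0.0, 0.0),
        (1.0, 0.0, 0.5, 0.0),
        (0.5, 0.5, 0.5, 0.5),
        (1.0, 0.5, 0.25, 0.0),
        (0.25, 0.25, 0.0, 0.0),
        (1.0, 1.0, 1.0, 1.0),
    ]


def toy_grid(
    r2_levels=(0.2, 0.5, 0.8),
    obs_per_variable=(5, 10, 50),
    n_iterations: int = 900,
    confidence_level: float = 0.90,
) -> list[ScenarioConfig]:
    """Full-factorial toy grid: 7 correlations x 10 betas x |R2| x |n/p|."""
    transforms = TransformSpec.identity(4)
    scenarios = []
    for (ci, corr), (bi, beta), r2, opv in itertools.product(
        enumerate(toy_correlation_specs()),
        enumerate(toy_beta_structures()),
        r2_levels,
        obs_per_variable,
    ):
        scenarios.append(
            ScenarioConfig(
                correlation=corr,
                transforms=transforms,
                beta=beta,
                target_r2=r2,
                obs_per_variable=opv,
                confidence_level=confidence_level,
                n_iterations=n_iterations,
                name=f"toy-c{ci}-b{bi}-r{r2:g}-m{opv}",
            )
        )
    return scenarios


def realistic_correlation_spec() -> CorrelationSpec:
    # 17 variables: a large strongly correlated anthropometric-like block,
    # a moderately correlated block, and four near-independent variables.
    return CorrelationSpec(
        17,
        blocks=(
            (tuple(range(0, 9)), 0.65),
            (tuple(range(9, 13)), 0.30),
        ),
        cross_block_correlation=0.05,
    )


def realistic_transform_spec() -> TransformSpec:
    # 9 affine continuous, 4 log-normal continuous, 4 binary.
    transforms = (
        [Affine(0.0, 1.0)] * 9
        + [Exponential(0.5)] * 4
        + [Threshold(0.0), Threshold(0.5), Threshold(-0.5), Threshold(1.0)]
    )
    return TransformSpec(tuple(transforms))


def realistic_beta_structures() -> list[tuple]:
    """Thirteen coefficient patterns over 17 mixed-type predictors."""
    p = 17
    def vec(pairs):
        b = [0.0] * p
        for j, v in pairs:
            b[j] = v
        return tuple(b)

    return [
        vec([]),                                               # null
        vec([(0, 1.0)]),                                       # single strong, in block
        vec([(13, 1.0)]),                                      # single strong binary
        vec([(0, 1.0), (9, 1.0)]),                             # two strong across blocks
        vec([(0, 1.0), (1, 0.5)]),                             # strong + weak in block
        vec([(0, 1.0), (13, 0.5)]),                            # strong + weak binary
        vec([(0, 0.5), (4, 0.5), (9, 0.5), (13, 0.5)]),        # spread moderate
        vec([(j, 0.25) for j in range(8)]),                    # dense weak in block
        vec([(0, 1.0), (1, 0.5), (9, 0.25), (13, 0.25)]),      # mixed decreasing
        vec([(9, 0.5), (10, 0.5)]),                            # moderate pair
        vec([(13, 0.5), (14, 0.5), (15, 0.5)]),                # binary trio
        vec([(j, 0.5) for j in range(0, 17, 2)]),              # alternating moderate
        vec([(j, 1.0) for j in (0, 4, 9, 13, 16)]),            # five strong
    ]


def realistic_grid(
    r2_levels=(0.2, 0.5, 0.8),
    obs_per_variable=(5, 10, 50),
    n_iterations: int = 900,
    confidence_level: float = 0.90,
) -> list[ScenarioConfig]:
    """Realistic-like grid: fixed correlation, 13 betas x |R2| x |n/p|."""
    corr = realistic_correlation_spec()
    transforms = realistic_transform_spec()
    scenarios = []
    for (bi, beta), r2, opv in itertools.product(
        enumerate(realistic_beta_structures()), r2_levels, obs_per_variable
    ):
        scenarios.append(
            ScenarioConfig(
                correlation=corr,
                transforms=transforms,
                beta=beta,
                target_r2=r2,
                obs_per_variable=opv,
                confidence_level=confidence_level,
                n_iterations=n_iterations,
                name=f"real-b{bi}-r{r2:g}-m{opv}",
            )
        )
    return scenarios
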