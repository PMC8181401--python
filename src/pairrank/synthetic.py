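"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the shape of multi-platform tumor-cohort data: a
latent per-gene log-expression matrix, a designated set of informative
gene pairs whose within-sample order drives the hazard through a
Cox-Weibull model, independent right censoring calibrated to a target
rate, clinical covariates with realistic missingness, and per-sample
strictly monotone "platform" distortions of the latent values so that the
observed matrices differ across platforms in everything except the
within-sample gene ordering. Truth records carry the informative pairs,
their coefficients and the latent indicators, so recovery metrics can be
computed without re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError
from .pair_engine import pair_id

DISTORTION_FAMILIES = ("none", "exp-affine", "power", "broken")


@dataclass
class CohortSpec:
    """Parameters of one synthetic survival cohort.

    ``pair_coefficients`` are the true log-hazard effects of the
    informative pair indicators (defaults to alternating +1/-1). The
    Weibull baseline (shape 1.2, scale 60 months) gives a median latent
    survival near 4 years; ``censoring_rate`` is the target fraction of
    censored subjects, achieved by an independent exponential censoring
    time whose rate is solved numerically. The ``broken`` distortion
    family is deliberately non-monotone and exists only to demonstrate
    when rank-based scoring fails.
    """

    n_samples: int = 300
    n_genes: int = 15
    n_informative_pairs: int = 5
    pair_coefficients: np.ndarray | None = None
    weibull_shape: float = 1.2
    weibull_scale: float = 60.0
    censoring_rate: float = 0.30
    distortion: str = "exp-affine"
    seed: int = 0

    def __post_init__(self) -> None:
        max_pairs = self.n_genes * (self.n_genes - 1) // 2
        if self.n_informative_pairs > max_pairs:
            raise ValidationError(
                f"{self.n_informative_pairs} informative pairs exceed the "
                f"{max_pairs} available for {self.n_genes} genes"
            )
        if not 0.0 < self.censoring_rate < 1.0:
            raise ValidationError("censoring_rate must lie in (0, 1)")
        if self.distortion not in DISTORTION_FAMILIES:
            raise ValidationError(f"unknown distortion family {self.distortion!r}")
        if self.pair_coefficients is None:
            signs = np.where(np.arange(self.n_informative_pairs) % 2 == 0, 1.0, -1.0)
            self.pair_coefficients = signs
        self.pair_coefficients = np.asarray(self.pair_coefficients, dtype=float)
        if len(self.pair_coefficients) != self.n_informative_pairs:
            raise ValidationError("one coefficient per informative pair required")


@dataclass
class ImmuneSpec:
    """Parameters of the synthetic immune-deconvolution problem."""

    n_cell_types: int = 5
    markers_per_type: int = 20
    noise_sigma: float = 0.05  # Gaussian noise sd as a fraction of mean signal
    dirichlet_concentration: float = 1.0
    planted_correlations: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _latent_matrix(rng: np.random.Generator, n_genes: int, n_samples: int,
                   prefix: str = "G") -> pd.DataFrame:
    means = rng.normal(5.0, 1.5, size=n_genes)
    sds = rng.uniform(0.8, 1.5, size=n_genes)
    z = means[:, None] + sds[:, None] * rng.standard_normal((n_genes, n_samples))
    genes = [f"{prefix}{i + 1:03d}" for i in range(n_genes)]
    return pd.DataFrame(z, index=genes)


def _pick_informative_pairs(
    latent: pd.DataFrame, n_pairs: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Prefer pairs with balanced indicator prevalence so filters keep them."""
    z = latent.to_numpy()
    mu, sd = z.mean(axis=1), z.std(axis=1)
    ii, jj = np.triu_indices(len(latent), k=1)
    balance = np.abs(mu[ii] - mu[jj]) / np.sqrt(sd[ii] ** 2 + sd[jj] ** 2)
    order = np.argsort(balance, kind="stable")
    # sample among the most balanced third, at least n_pairs candidates
    pool = order[: max(n_pairs, len(order) // 3)]
    chosen = rng.choice(pool, size=n_pairs, replace=False)
    return [(int(ii[k]), int(jj[k])) for k in chosen]


def pair_indicators_from_latent(
    latent: pd.DataFrame, pairs: list[tuple[int, int]]
) -> pd.DataFrame:
    z = latent.to_numpy()
    genes = latent.index.to_numpy()
    rows = [(z[i] > z[j]).astype(np.int8) for i, j in pairs]
    index = pd.Index([pair_id(genes[i], genes[j]) for i, j in pairs], name="pair")
    return pd.DataFrame(np.asarray(rows), index=index, columns=latent.columns)


def _solve_censoring_rate(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving the target censoring fraction."""

    def frac(rate: float) -> float:
        return float(np.mean(1.0 - np.exp(-rate * event_times)))

    lo, hi = 1e-10, 1e-6
    while frac(hi) < target:
        hi *= 10.0
        if hi > 1e8:
            raise ValidationError("censoring target infeasible for these event times")
    return float(optimize.brentq(lambda r: frac(r) - target, lo, hi))


def apply_distortion(
    latent: pd.DataFrame, family: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-sample strictly monotone map of latent values to an observed scale.

    ``exp-affine``: x -> exp(b x + c); ``power``: x -> a (x - xmin + 1)^p on
    globally shifted positive values; ``none``: global shift to >= 0 only.
    ``broken`` applies a non-monotone quadratic and violates the rank
    assumption on purpose.
    """
    z = latent.to_numpy(dtype=float)
    n = z.shape[1]
    if family == "none":
        obs = z - z.min() + 1.0
    elif family == "exp-affine":
        b = rng.uniform(0.3, 0.8, size=n)
        c = rng.uniform(-1.0, 1.0, size=n)
        obs = np.exp(b[None, :] * z + c[None, :])
    elif family == "power":
        w = z - z.min() + 1.0
        p = rng.uniform(1.5, 3.0, size=n)
        a = rng.uniform(0.5, 2.0, size=n)
        obs = a[None, :] * w ** p[None, :]
    elif family == "broken":
        center = np.median(z, axis=0)
        obs = (z - center[None, :]) ** 2
    else:  # pragma: no cover
        raise ValidationError(f"unknown distortion family {family!r}")
    return pd.DataFrame(obs, index=latent.index, columns=latent.columns)


def _clinical_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Prognosis-neutral clinical covariates with cohort-like missingness."""
    age = np.clip(np.round(rng.normal(61.0, 11.0, size=n)), 19, 90)
    frame = pd.DataFrame(
        {
            "age": age,
            "gender": rng.choice(["Male", "Female"], size=n, p=[0.73, 0.27]),
            "t_stage": rng.choice(["T1-2", "T3-4"], size=n, p=[0.4, 0.6]),
            "n_stage": rng.choice(["N-", "N+"], size=n, p=[0.43, 0.57]),
            "m_stage": rng.choice(["M0", "M1"], size=n, p=[0.97, 0.03]),
            "grade": rng.choice(["I-II", "III-IV"], size=n, p=[0.22, 0.78]),
        }
    )
    for col in ("t_stage", "n_stage", "m_stage"):
        miss = rng.random(n) < 0.02
        frame.loc[miss, col] = np.nan
    return frame


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """One cohort: observed expression, survival table and truth record."""
    rng = np.random.default_rng(spec.seed)
    latent = _latent_matrix(rng, spec.n_genes, spec.n_samples)
    latent.columns = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    pairs = _pick_informative_pairs(latent, spec.n_informative_pairs, rng)
    indicators = pair_indicators_from_latent(latent, pairs)
    eta = spec.pair_coefficients @ indicators.to_numpy(dtype=float)
    eta = eta - eta.mean()

    unit_exp = rng.exponential(size=spec.n_samples)
    event_times = spec.weibull_scale * (unit_exp / np.exp(eta)) ** (
        1.0 / spec.weibull_shape
    )
    rate = _solve_censoring_rate(event_times, spec.censoring_rate)
    censor_times = rng.exponential(1.0 / rate, size=spec.n_samples)
    observed = np.minimum(event_times, censor_times)
    status = (event_times <= censor_times).astype(int)

    clinical = _clinical_covariates(rng, spec.n_samples)
    surv = pd.DataFrame(
        {"time": observed, "status": status}, index=latent.columns
    ).join(clinical.set_index(latent.columns))
    surv.index.name = "sample_id"

    expr = apply_distortion(latent, spec.distortion, rng)
    truth = {
        "informative_pairs": indicators.index.tolist(),
        "coefficients": spec.pair_coefficients.copy(),
        "indicators": indicators,
        "latent": latent,
        "linear_predictor": pd.Series(eta, index=latent.columns),
        "censoring_rate_achieved": float(1 - status.mean()),
        "censoring_rate_target": spec.censoring_rate,
    }
    return expr, surv, truth


def simulate_two_platform(
    spec: CohortSpec,
    n_extra_genes: int = 10,
    split_frac: float = 0.5,
    distortions: tuple[str, str] = ("exp-affine", "power"),
) -> dict:
    """One latent cohort split into two differently distorted "platforms".

    The two observed matrices share the core genes (different platform-
    specific extra genes are appended) and receive distortions from
    different monotone families, so absolute values are incomparable
    across platforms while within-sample orderings of shared genes agree
    with the latent truth.
    """
    rng = np.random.default_rng(spec.seed)
    latent = _latent_matrix(rng, spec.n_genes, spec.n_samples)
    n_train = int(round(split_frac * spec.n_samples))
    if spec.n_samples - n_train < 2 or n_train < 2:
        raise ValidationError("split leaves a platform with fewer than 2 samples")
    cols = [f"TR{i + 1:04d}" for i in range(n_train)] + [
        f"VA{i + 1:04d}" for i in range(spec.n_samples - n_train)
    ]
    latent.columns = cols
    pairs = _pick_informative_pairs(latent, spec.n_informative_pairs, rng)
    indicators = pair_indicators_from_latent(latent, pairs)
    eta = spec.pair_coefficients @ indicators.to_numpy(dtype=float)
    eta = eta - eta.mean()

    unit_exp = rng.exponential(size=spec.n_samples)
    event_times = spec.weibull_scale * (unit_exp / np.exp(eta)) ** (
        1.0 / spec.weibull_shape
    )
    rate = _solve_censoring_rate(event_times, spec.censoring_rate)
    censor_times = rng.exponential(1.0 / rate, size=spec.n_samples)
    observed = np.minimum(event_times, censor_times)
    status = (event_times <= censor_times).astype(int)
    clinical = _clinical_covariates(rng, spec.n_samples)
    surv = pd.DataFrame({"time": observed, "status": status}, index=cols).join(
        clinical.set_index(pd.Index(cols))
    )
    surv.index.name = "sample_id"

    out = {}
    for half, (name, fam, prefix) in enumerate(
        [("train", distortions[0], "A"), ("valid", distortions[1], "B")]
    ):
        part = latent.iloc[:, :n_train] if half == 0 else latent.iloc[:, n_train:]
        extra = _latent_matrix(rng, n_extra_genes, part.shape[1],
                               prefix=f"{prefix}X")
        extra.columns = part.columns
        combined = pd.concat([part, extra])
        out[f"expr_{name}"] = apply_distortion(combined, fam, rng)
        out[f"surv_{name}"] = surv.loc[part.columns]
    out["truth"] = {
        "informative_pairs": indicators.index.tolist(),
        "coefficients": spec.pair_coefficients.copy(),
        "indicators": indicators,
        "latent": latent,
        "linear_predictor": pd.Series(eta, index=cols),
        "censoring_rate_achieved": float(1 - status.mean()),
    }
    return out


def _rank_reorder(values: np.ndarray, target_latent: np.ndarray) -> np.ndarray:
    """Iman-Conover style: reorder ``values`` to follow the ranks of a latent."""
    ranks = stats.rankdata(target_latent, method="ordinal").astype(int) - 1
    return np.sort(values)[ranks]


def simulate_immune(
    spec: ImmuneSpec, scores: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Mixtures, true fractions and a marker-block basis matrix.

    Fractions are Dirichlet draws, rank-tilted per cell type to induce the
    planted Pearson correlation with the risk score; mixtures are
    basis-weighted sums plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(scores)
    cell_types = [f"CellType{k + 1}" for k in range(spec.n_cell_types)]
    n_genes = spec.n_cell_types * spec.markers_per_type
    genes = [f"IMM{i + 1:04d}" for i in range(n_genes)]

    basis = 1.0 + np.abs(rng.normal(0.0, 0.2, size=(n_genes, spec.n_cell_types)))
    for k in range(spec.n_cell_types):
        block = slice(k * spec.markers_per_type, (k + 1) * spec.markers_per_type)
        basis[block, k] += 8.0 * (0.5 + rng.random(spec.markers_per_type))
    basis_df = pd.DataFrame(basis, index=genes, columns=cell_types)

    fractions = rng.dirichlet(
        np.full(spec.n_cell_types, spec.dirichlet_concentration), size=n
    )
    z_score = stats.zscore(scores.to_numpy(dtype=float))
    for cell, rho in spec.planted_correlations.items():
        if cell not in cell_types:
            raise ValidationError(f"unknown cell type {cell!r}")
        if abs(rho) > 0.9:
            raise ValidationError(
                f"|rho| = {abs(rho)} too large to induce on Dirichlet fractions"
            )
        k = cell_types.index(cell)
        # orthogonalized noise: in-sample correlation of the latent with the
        # score is exactly rho, not merely rho in expectation
        eps = rng.standard_normal(n)
        eps -= eps.mean() + z_score * (eps @ z_score) / (z_score @ z_score)
        eps /= eps.std()
        latent = rho * z_score + np.sqrt(1 - rho**2) * eps
        fractions[:, k] = _rank_reorder(fractions[:, k], latent)
    fractions /= fractions.sum(axis=1, keepdims=True)
    fractions_df = pd.DataFrame(fractions, index=scores.index, columns=cell_types)

    signal = basis @ fractions.T
    noise = spec.noise_sigma * signal.mean() * rng.standard_normal(signal.shape)
    mixture = np.clip(signal + noise, 0.0, None)
    mixture_df = pd.DataFrame(mixture, index=genes, columns=scores.index)
    return mixture_df, fractions_df, basis_df
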