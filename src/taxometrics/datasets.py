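"""Synthetic ordinal indicator data with known latent structure.

Two generators cover the hypotheses a taxometric analysis adjudicates
between:

* ``generate_dimensional`` — a single-factor continuum: each indicator is a
  monotone discretization of ``loading * latent + noise`` onto the 0-6 scale,
  with bin edges chosen so the marginals match a target mean/SD (right-skewed,
  as symptom inventories are) and the factor loading calibrated so the
  realized mean inter-indicator Pearson r hits a target.
* ``generate_taxonic`` — a two-group mixture: taxon and complement are
  discretized latent normals whose means differ by ``separation`` pooled-SD
  units per indicator, with controllable base rate and within-group
  (nuisance) correlation.

Discretization attenuates correlations and group separations, so both
generators run a short Monte-Carlo calibration loop on a large internal
sample to hit the *post-discretization* targets; exact matching of skewness
and kurtosis is not attempted (kurtosis above ~5 is unreachable with 7-point
support under a latent-normal model).

The marginal presets encode the indicator moments reported for large
adolescent community surveys of gaming symptoms (9 DSM-5 indicators /
4 ICD-11 indicators on the 0-6 scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from ._utils import ConfigurationError, InfeasibleTargetError, mean_offdiag, rng_from, safe_corr
from .indicators import DSM5_CRITERIA, ICD11_CRITERIA, IndicatorMatrix

INDICATOR_SUPPORT = np.arange(7)  # 0..6 summed two-item scale


@dataclass(frozen=True)
class MarginalTarget:
    """Target marginal moments for one indicator on the 0-6 scale.

    Mean and SD drive the discretization; skewness and kurtosis are recorded
    as descriptive targets (the maximum-entropy marginal matches the first
    two moments and is right-skewed whenever the mean is low).
    """

    label: str
    mean: float
    sd: float
    skewness: float | None = None
    kurtosis: float | None = None

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigurationError(f"marginal target {self.label!r} needs sd > 0")


#: Indicator calibration presets (means 0.31-0.92, SDs 0.84-1.52,
#: skewness 1.61-3.40, excess kurtosis 1.93-13.42).
DSM5_CALIBRATION = (
    MarginalTarget("Preoccupation", 0.89, 1.30, 1.61, 2.20),
    MarginalTarget("Withdrawal", 0.47, 1.03, 2.62, 7.38),
    MarginalTarget("Tolerance", 0.75, 1.22, 1.80, 3.09),
    MarginalTarget("Reduce/stop", 0.56, 1.06, 2.26, 5.42),
    MarginalTarget("Continue despite problems", 0.41, 0.97, 2.92, 9.36),
    MarginalTarget("Give up other activities", 0.53, 1.05, 2.32, 5.61),
    MarginalTarget("Escape adverse moods", 0.53, 1.12, 2.49, 6.33),
    MarginalTarget("Deceive/cover up", 0.92, 1.52, 1.68, 1.93),
    MarginalTarget("Risk/lose", 0.31, 0.84, 3.40, 13.42),
)
ICD11_CALIBRATION = tuple(t for t in DSM5_CALIBRATION if t.label in ICD11_CRITERIA)

#: Target mean inter-indicator correlations matching the presets.
DSM5_TARGET_MEAN_R = 0.59
ICD11_TARGET_MEAN_R = 0.61


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic dataset; the seed fixes the output."""

    structure: str  # "dimensional" | "taxonic"
    n_cases: int
    n_indicators: int
    base_rate: float | None = None
    separation: float | None = None
    within_group_r: float | None = None
    target_mean_r: float | None = None
    marginals: tuple[MarginalTarget, ...] | None = None
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self):
        if self.structure not in ("dimensional", "taxonic"):
            raise ConfigurationError(f"unknown structure {self.structure!r}")
        if self.n_indicators < 2:
            raise ConfigurationError("need at least 2 indicators")
        if self.marginals is not None:
            self.marginals = tuple(self.marginals)
            if len(self.marginals) != self.n_indicators:
                raise ConfigurationError("marginals must match n_indicators")
        if self.structure == "taxonic":
            if self.base_rate is None or self.separation is None or self.within_group_r is None:
                raise ConfigurationError("taxonic configs require base_rate, separation and within_group_r")
            if not 0 < self.base_rate < 1:
                raise ConfigurationError("base_rate must lie in (0, 1)")
        else:
            if self.target_mean_r is None:
                raise ConfigurationError("dimensional configs require target_mean_r")
            if not 0 <= self.target_mean_r < 1:
                raise ConfigurationError("target_mean_r must lie in [0, 1)")


@dataclass
class SyntheticSample:
    """A generated dataset plus its ground truth."""

    indicators: IndicatorMatrix
    config: SyntheticConfig
    latent_scores: np.ndarray | None = None  # dimensional: factor score per case
    labels: np.ndarray | None = None  # taxonic: True = taxon
    realized: dict = field(default_factory=dict)

    def to_frame(self, include_labels: bool = False) -> pd.DataFrame:
        df = self.indicators.to_frame()
        if include_labels and self.labels is not None:
            df["taxon"] = self.labels.astype(int)
        return df


def moment_matched_pmf(mean: float, sd: float, support: np.ndarray = INDICATOR_SUPPORT) -> np.ndarray:
    """Maximum-entropy pmf on an integer support with given mean and SD.

    Solves the convex dual of the two-moment maximum-entropy problem,
    p_k proportional to exp(a*k + b*k^2).  Low means on a 0-6 support give the
    strong right skew typical of symptom indicators.
    """
    k = np.asarray(support, dtype=float)
    m2 = mean**2 + sd**2
    lo, hi = k.min(), k.max()
    if not lo < mean < hi:
        raise ConfigurationError(f"target mean {mean} outside the open support range ({lo}, {hi})")
    max_var = (mean - lo) * (hi - mean)
    if sd**2 >= max_var:
        raise ConfigurationError(f"target sd {sd} infeasible for mean {mean} on support [{lo}, {hi}]")

    def dual(theta):
        a, b = theta
        return logsumexp(a * k + b * k**2) - a * mean - b * m2

    def moments(theta):
        a, b = theta
        logp = a * k + b * k**2
        p = np.exp(logp - logsumexp(logp))
        return [p @ k - mean, p @ k**2 - m2]

    start = optimize.minimize(dual, x0=np.zeros(2), method="BFGS").x
    sol = optimize.root(moments, x0=start, method="hybr")
    a, b = sol.x if sol.success else start
    logp = a * k + b * k**2
    p = np.exp(logp - logsumexp(logp))
    return p / p.sum()


def _normal_thresholds(pmf: np.ndarray) -> np.ndarray:
    """Standard-normal cut points whose cells carry the pmf's probabilities."""
    cum = np.cumsum(pmf)[:-1]
    cum = np.clip(cum, 1e-12, 1 - 1e-12)
    return stats.norm.ppf(cum)


def _discretize(cont: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Monotone binning: value = number of thresholds below the score."""
    return np.searchsorted(thresholds, cont, side="left").astype(np.int64)


_CAL_N = 20_000  # internal calibration sample size
_CAL_ITER = 4


def _dimensional_continuous(rng, n, k, rho):
    z = rng.standard_normal(n)
    eps = rng.standard_normal((n, k))
    lam = np.sqrt(rho)
    return lam * z[:, None] + np.sqrt(1 - rho) * eps, z


def generate_dimensional(config: SyntheticConfig) -> SyntheticSample:
    """Single-factor ordinal data with calibrated mean inter-indicator r."""
    if config.structure != "dimensional":
        raise ConfigurationError("config.structure must be 'dimensional'")
    rng = rng_from(config.seed)
    cal_rng, out_rng = rng.spawn(2)
    k = config.n_indicators
    marginals = config.marginals or _default_marginals(k)
    thresholds = [_normal_thresholds(moment_matched_pmf(t.mean, t.sd)) for t in marginals]
    target = float(config.target_mean_r)

    rho = min(max(target, 1e-6), 0.95)
    attained = 0.0
    if target > 0:
        for _ in range(_CAL_ITER):
            cont, _ = _dimensional_continuous(cal_rng, _CAL_N, k, rho)
            disc = np.column_stack([_discretize(cont[:, j], thresholds[j]) for j in range(k)])
            attained = mean_offdiag(safe_corr(disc))
            if attained <= 1e-4:
                break
            rho = float(np.clip(rho * target / attained, 1e-6, 0.995))
        if attained < target - 0.05 and rho >= 0.995:
            raise InfeasibleTargetError(
                f"target mean r={target:.3f} unattainable under discretization "
                f"(attained {attained:.3f} at latent rho 0.995)",
                attained=attained,
            )
    else:
        rho = 0.0

    cont, z = _dimensional_continuous(out_rng, config.n_cases, k, rho)
    values = np.column_stack([_discretize(cont[:, j], thresholds[j]) for j in range(k)])
    mat = IndicatorMatrix(values, [t.label for t in marginals], set_name="synthetic-dimensional")
    realized = {
        "latent_rho": rho,
        "calibration_mean_r": attained,
        "mean_r": mean_offdiag(safe_corr(values)) if k >= 2 else np.nan,
    }
    return SyntheticSample(indicators=mat, config=config, latent_scores=z, realized=realized)


def _default_marginals(k: int) -> tuple[MarginalTarget, ...]:
    """Mildly right-skewed default marginal (symptom-scale-like)."""
    return tuple(MarginalTarget(f"ind{j + 1}", 1.5, 1.5) for j in range(k))


def _equicorr(k: int, r: float) -> np.ndarray:
    return np.full((k, k), r) + (1 - r) * np.eye(k)


def _taxonic_continuous(rng, n_taxon, n_comp, k, rho_wg, delta):
    R = _equicorr(k, rho_wg)
    L = np.linalg.cholesky(R)
    comp = rng.standard_normal((n_comp, k)) @ L.T
    tax = rng.standard_normal((n_taxon, k)) @ L.T + delta
    return tax, comp


def _taxonic_thresholds(pooled: np.ndarray, marginals) -> list[np.ndarray]:
    """Bin edges per indicator, applied to the pooled continuous scores.

    With explicit marginal targets, edges sit at pooled quantiles of the
    target pmf (the marginal then matches the pmf); otherwise edges are
    equally spaced over mean +/- 2.5 SD, preserving the mixture's shape.
    """
    k = pooled.shape[1]
    out = []
    for j in range(k):
        col = pooled[:, j]
        if marginals is not None:
            pmf = moment_matched_pmf(marginals[j].mean, marginals[j].sd)
            cum = np.clip(np.cumsum(pmf)[:-1], 1e-12, 1 - 1e-12)
            out.append(np.quantile(col, cum))
        else:
            m, s = col.mean(), col.std()
            edges = np.linspace(m - 2.5 * s, m + 2.5 * s, len(INDICATOR_SUPPORT) + 1)
            out.append(edges[1:-1])
    return out


def _pooled_d(values: np.ndarray, taxon: np.ndarray) -> float:
    g1, g0 = values[taxon], values[~taxon]
    n1, n0 = len(g1), len(g0)
    sp = np.sqrt(
        ((n1 - 1) * g1.var(axis=0, ddof=1) + (n0 - 1) * g0.var(axis=0, ddof=1)) / (n1 + n0 - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (g1.mean(axis=0) - g0.mean(axis=0)) / sp
    return float(np.nanmean(d))


def _within_r(values: np.ndarray, taxon: np.ndarray) -> float:
    rs = []
    for mask in (taxon, ~taxon):
        if mask.sum() >= 3:
            rs.append(mean_offdiag(safe_corr(values[mask])))
    return float(np.mean(rs)) if rs else np.nan


def generate_taxonic(config: SyntheticConfig) -> SyntheticSample:
    """Two-group ordinal mixture with calibrated post-discretization d and r_wg."""
    if config.structure != "taxonic":
        raise ConfigurationError("config.structure must be 'taxonic'")
    rng = rng_from(config.seed)
    cal_rng, out_rng, perm_rng = rng.spawn(3)
    k = config.n_indicators
    p, d_target, r_target = config.base_rate, config.separation, config.within_group_r
    n = config.n_cases
    n_taxon = int(round(p * n))
    if n_taxon < 1 or n - n_taxon < 1:
        raise ConfigurationError("base_rate leaves an empty group at this n")
    if n_taxon < 20:
        warnings.warn(f"taxon group has only {n_taxon} cases; curves will be unstable", stacklevel=2)

    delta = max(float(d_target), 0.0)
    rho_wg = float(np.clip(r_target, 0.0, 0.95))
    n_cal_t = max(int(round(p * _CAL_N)), 50)
    n_cal_c = max(_CAL_N - n_cal_t, 50)
    thresholds = None
    for _ in range(_CAL_ITER):
        tax, comp = _taxonic_continuous(cal_rng, n_cal_t, n_cal_c, k, rho_wg, delta)
        pooled = np.vstack([tax, comp])
        labels = np.zeros(len(pooled), dtype=bool)
        labels[: len(tax)] = True
        thresholds = _taxonic_thresholds(pooled, config.marginals)
        disc = np.column_stack([_discretize(pooled[:, j], thresholds[j]) for j in range(k)])
        if d_target > 0:
            d_att = _pooled_d(disc, labels)
            delta = float(np.clip(delta * d_target / max(d_att, 0.05), 0.0, 10.0))
        if r_target > 0:
            r_att = _within_r(disc, labels)
            if np.isfinite(r_att) and r_att > 1e-4:
                rho_wg = float(np.clip(rho_wg * r_target / r_att, 0.0, 0.95))

    tax, comp = _taxonic_continuous(out_rng, n_taxon, n - n_taxon, k, rho_wg, delta)
    pooled = np.vstack([tax, comp])
    labels = np.zeros(n, dtype=bool)
    labels[:n_taxon] = True
    order = perm_rng.permutation(n)
    pooled, labels = pooled[order], labels[order]
    values = np.column_stack([_discretize(pooled[:, j], thresholds[j]) for j in range(k)])
    names = [t.label for t in config.marginals] if config.marginals else [f"ind{j + 1}" for j in range(k)]
    mat = IndicatorMatrix(values, names, set_name="synthetic-taxonic")
    realized = {
        "latent_delta": delta,
        "latent_rho_wg": rho_wg,
        "d": _pooled_d(values, labels),
        "within_r": _within_r(values, labels),
        "n_taxon": n_taxon,
    }
    return SyntheticSample(indicators=mat, config=config, labels=labels, realized=realized)


def make_dimensional(
    n_cases: int,
    n_indicators: int = 9,
    target_mean_r: float = DSM5_TARGET_MEAN_R,
    marginals=None,
    seed=None,
) -> SyntheticSample:
    """Convenience wrapper around :func:`generate_dimensional`."""
    cfg = SyntheticConfig(
        structure="dimensional",
        n_cases=n_cases,
        n_indicators=n_indicators,
        target_mean_r=target_mean_r,
        marginals=marginals,
        seed=seed,
    )
    return generate_dimensional(cfg)


def make_taxonic(
    n_cases: int,
    n_indicators: int = 9,
    base_rate: float = 0.25,
    separation: float = 2.0,
    within_group_r: float = 0.2,
    marginals=None,
    seed=None,
) -> SyntheticSample:
    """Convenience wrapper around :func:`generate_taxonic`."""
    cfg = SyntheticConfig(
        structure="taxonic",
        n_cases=n_cases,
        n_indicators=n_indicators,
        base_rate=base_rate,
        separation=separation,
        within_group_r=within_group_r,
        marginals=marginals,
        seed=seed,
    )
    return generate_taxonic(cfg)


def indicators_to_items(indicators: IndicatorMatrix, coding: str = "1-4") -> pd.DataFrame:
    """Split each 0-6 indicator into a consistent pair of 0-3 items.

    The split is the balanced one (ceil/floor halves), so summing the pair
    reproduces the indicator exactly; useful for writing item-level CSV
    fixtures in the survey's raw coding.
    """
    vals = np.asarray(indicators.values)
    hi = np.ceil(vals / 2).astype(np.int64)
    lo = vals - hi
    offset = 1 if coding == "1-4" else 0
    data = {}
    for j in range(vals.shape[1]):
        data[f"csas{2 * j + 1:02d}"] = hi[:, j] + offset
        data[f"csas{2 * j + 2:02d}"] = lo[:, j] + offset
    return pd.DataFrame(data)


#: Named presets for the CLI and benchmarks.
PRESETS = {
    "csas-dsm5": dict(n_indicators=9, marginals=DSM5_CALIBRATION, target_mean_r=DSM5_TARGET_MEAN_R),
    "csas-icd11": dict(n_indicators=4, marginals=ICD11_CALIBRATION, target_mean_r=ICD11_TARGET_MEAN_R),
}


def preset_sample(
    preset: str,
    structure: str,
    n_cases: int,
    seed=None,
    base_rate: float = 0.25,
    separation: float = 2.0,
    within_group_r: float = 0.2,
) -> SyntheticSample:
    """Generate a dataset from a named calibration preset."""
    if preset not in PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    info = PRESETS[preset]
    if structure == "dimensional":
        return make_dimensional(
            n_cases,
            n_indicators=info["n_indicators"],
            target_mean_r=info["target_mean_r"],
            marginals=info["marginals"],
            seed=seed,
        )
    return make_taxonic(
        n_cases,
        n_indicators=info["n_indicators"],
        base_rate=base_rate,
        separation=separation,
        within_group_r=within_group_r,
        marginals=info["marginals"],
        seed=seed,
    )
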