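"""Simulated comparison populations for curve-fit comparison.

The CCFI machinery judges an empirical curve against curves from two finite
populations (default N = 100,000) that both reproduce the empirical data's
marginal distributions and correlation matrix but differ in latent structure:

* dimensional — one population matching the full-sample correlations;
* categorical — the sample is split into putative taxon and complement by
  ranking on the total indicator score at an assumed base rate, each stratum
  is reproduced separately (its own marginals and within-stratum
  correlations), and the strata are stacked in proportion.

Reproduction uses iterative rank remapping: bootstrap each column's marginal,
generate multivariate normal deviates under an intermediate correlation
matrix, remap each normal column onto the sorted bootstrap values, measure
the achieved Pearson correlations, and add the residual (target - achieved)
to the intermediate matrix; the iteration with the smallest residual RMSR
wins.  Non-normality and skew survive because only ranks of the normal
deviates are used.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import PreconditionError, array_digest, as_values, rng_from, safe_corr

DEFAULT_N_POP = 100_000
DEFAULT_TOL = 0.01
DEFAULT_MAX_ITER = 10
_EIG_FLOOR = 1e-6


@dataclass
class ComparisonPopulation:
    """A finite simulated population plus its reproduction diagnostics."""

    structure: str  # "categorical" | "dimensional"
    values: np.ndarray
    rmsr: float
    source_digest: str
    base_rate: float | None = None
    n_taxon: int | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_pop(self) -> int:
        return self.values.shape[0]

    def to_parquet(self, path) -> None:
        """Cache the population to a compressed columnar file + JSON sidecar."""
        path = Path(path)
        pd.DataFrame(self.values).to_parquet(path)
        meta = {
            "structure": self.structure,
            "rmsr": self.rmsr,
            "source_digest": self.source_digest,
            "base_rate": self.base_rate,
            "n_taxon": self.n_taxon,
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_parquet(cls, path) -> "ComparisonPopulation":
        path = Path(path)
        values = pd.read_parquet(path).to_numpy()
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(values=values, **meta)


@dataclass
class SampleSet:
    """K equally sized samples drawn from one population."""

    indices: np.ndarray  # (K, n) row indices into the population
    population: ComparisonPopulation

    @property
    def k(self) -> int:
        return self.indices.shape[0]

    @property
    def n(self) -> int:
        return self.indices.shape[1]

    def __iter__(self):
        for idx in self.indices:
            yield self.population.values[idx]


def _repair_pd(corr: np.ndarray) -> np.ndarray:
    """Eigenvalue-floor a symmetric matrix and rescale to unit diagonal."""
    sym = (corr + corr.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() < _EIG_FLOOR:
        vals = np.maximum(vals, _EIG_FLOOR)
        sym = vecs @ np.diag(vals) @ vecs.T
        scale = np.sqrt(np.diag(sym))
        sym = sym / np.outer(scale, scale)
    np.fill_diagonal(sym, 1.0)
    return sym


def _rmsr(resid: np.ndarray, active: np.ndarray) -> float:
    iu = np.tril_indices_from(resid, k=-1)
    mask = active[iu[0]] & active[iu[1]]
    if not mask.any():
        return 0.0
    return float(np.sqrt(np.mean(resid[iu][mask] ** 2)))


def reproduce_population(
    source,
    target_corr: np.ndarray | None = None,
    n_pop: int = DEFAULT_N_POP,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed=None,
) -> tuple[np.ndarray, float, list[float]]:
    """Iterative marginal-preserving correlation matching.

    Returns ``(values, best_rmsr, rmsr_history)``.  Every population value is
    bootstrapped from the corresponding source column, so marginal multisets
    are subsets of the observed values by construction.
    """
    src = as_values(source)
    n_src, k = src.shape
    if k < 2:
        raise PreconditionError("need at least 2 indicators")
    if n_src < 2:
        raise PreconditionError("source has too few cases")
    rng = rng_from(seed)
    target = safe_corr(src) if target_corr is None else np.asarray(target_corr, dtype=float)
    if target.shape != (k, k) or not np.allclose(target, target.T) or not np.allclose(np.diag(target), 1):
        raise PreconditionError("target_corr must be symmetric with unit diagonal")

    boot = np.sort(
        np.column_stack([rng.choice(src[:, j], size=n_pop, replace=True) for j in range(k)]),
        axis=0,
    )
    active = boot[0] < boot[-1]  # columns with any variation
    intermediate = target.copy()
    best = (np.inf, None)
    history: list[float] = []
    for _ in range(max_iter):
        L = np.linalg.cholesky(_repair_pd(intermediate))
        z = rng.standard_normal((n_pop, k)) @ L.T
        out = np.empty_like(z)
        order = np.argsort(z, axis=0)
        for j in range(k):
            out[order[:, j], j] = boot[:, j]
        achieved = safe_corr(out)
        resid = np.where(np.outer(active, active), target - achieved, 0.0)
        np.fill_diagonal(resid, 0.0)
        r = _rmsr(resid, active)
        history.append(r)
        if r < best[0]:
            best = (r, out)
        intermediate = intermediate + resid
    if best[0] > tol:
        warnings.warn(
            f"correlation RMSR {best[0]:.4f} above tolerance {tol} after {max_iter} iterations; "
            "returning best effort",
            stacklevel=2,
        )
    return best[1], best[0], history


def build_dimensional_population(
    source,
    n_pop: int = DEFAULT_N_POP,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed=None,
) -> ComparisonPopulation:
    """One population matching the full-sample correlation matrix."""
    src = as_values(source)
    if src.shape[0] <= 50:
        warnings.warn(
            f"source has only {src.shape[0]} cases; bootstrap marginals will be coarse",
            stacklevel=2,
        )
    values, rmsr, history = reproduce_population(src, None, n_pop, tol, max_iter, seed)
    return ComparisonPopulation(
        structure="dimensional",
        values=values,
        rmsr=rmsr,
        source_digest=array_digest(src),
        provenance={"rmsr_history": history, "n_source": src.shape[0]},
    )


def build_categorical_population(
    source,
    base_rate: float,
    n_pop: int = DEFAULT_N_POP,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed=None,
) -> ComparisonPopulation:
    """Two-stratum population at an assumed taxon base rate.

    Source cases are ranked on the unweighted total indicator score (ties
    broken by a seeded jitter); the top round(p*n) form the putative taxon
    stratum.  Each stratum is reproduced separately and the strata are
    stacked at round(p*N_pop) taxon rows.
    """
    src = as_values(source)
    n_src = src.shape[0]
    if not 0 < base_rate < 1:
        raise PreconditionError("base_rate must lie in (0, 1)")
    n_taxon_src = int(round(base_rate * n_src))
    if n_taxon_src < 2 or n_src - n_taxon_src < 2:
        raise PreconditionError(
            f"base rate {base_rate} leaves a stratum with <2 source cases (n={n_src})"
        )
    rng = rng_from(seed)
    jitter_rng, taxon_rng, comp_rng = rng.spawn(3)
    total = src.sum(axis=1) + jitter_rng.random(n_src) * 1e-9
    order = np.argsort(-total, kind="stable")
    taxon_rows = src[order[:n_taxon_src]]
    comp_rows = src[order[n_taxon_src:]]

    n_taxon_pop = int(round(base_rate * n_pop))
    tax_vals, tax_rmsr, tax_hist = reproduce_population(
        taxon_rows, None, n_taxon_pop, tol, max_iter, taxon_rng
    )
    comp_vals, comp_rmsr, comp_hist = reproduce_population(
        comp_rows, None, n_pop - n_taxon_pop, tol, max_iter, comp_rng
    )
    return ComparisonPopulation(
        structure="categorical",
        values=np.vstack([tax_vals, comp_vals]),
        rmsr=max(tax_rmsr, comp_rmsr),
        source_digest=array_digest(src),
        base_rate=base_rate,
        n_taxon=n_taxon_pop,
        provenance={
            "taxon_rmsr": tax_rmsr,
            "complement_rmsr": comp_rmsr,
            "taxon_rmsr_history": tax_hist,
            "complement_rmsr_history": comp_hist,
            "n_taxon_source": n_taxon_src,
        },
    )


def cached_population(
    cache_dir,
    source,
    structure: str,
    base_rate: float | None = None,
    n_pop: int = DEFAULT_N_POP,
    seed: int | None = None,
    **kwargs,
) -> ComparisonPopulation:
    """Build a population, or reuse a cached one keyed by its recipe.

    The cache key is (source digest, structure, base rate, N, seed), so a hit
    is guaranteed to be the population the same call would rebuild.  Requires
    an integer seed (generator state is not a stable key).
    """
    if not isinstance(seed, (int, np.integer)):
        raise PreconditionError("population caching requires an integer seed")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    digest = array_digest(as_values(source))
    tag = "" if base_rate is None else f"-p{base_rate:g}"
    path = cache_dir / f"{digest}-{structure}{tag}-N{n_pop}-s{seed}.parquet"
    if path.exists():
        logging.getLogger(__name__).info("population cache hit: %s", path.name)
        return ComparisonPopulation.from_parquet(path)
    if structure == "dimensional":
        pop = build_dimensional_population(source, n_pop=n_pop, seed=seed, **kwargs)
    elif structure == "categorical":
        if base_rate is None:
            raise PreconditionError("categorical populations need a base_rate")
        pop = build_categorical_population(source, base_rate, n_pop=n_pop, seed=seed, **kwargs)
    else:
        raise PreconditionError(f"unknown structure {structure!r}")
    pop.to_parquet(path)
    return pop


def draw_samples(
    pop: ComparisonPopulation,
    n: int,
    k_samples: int = 100,
    seed=None,
    replace: bool = False,
) -> SampleSet:
    """K independent samples of size n (without replacement within a sample)."""
    if n > pop.n_pop:
        raise PreconditionError(f"sample size {n} exceeds population size {pop.n_pop}")
    rng = rng_from(seed)
    indices = np.stack(
        [rng.choice(pop.n_pop, size=n, replace=replace) for _ in range(k_samples)]
    )
    return SampleSet(indices=indices, population=pop)
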