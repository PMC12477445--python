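"""Shared helpers: RNG plumbing, digests, validation, errors."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """A requested configuration is internally inconsistent."""


class PreconditionError(ValueError):
    """Input data violate a documented precondition."""


class InfeasibleTargetError(RuntimeError):
    """A generator target cannot be attained; carries the attained value."""

    def __init__(self, message: str, attained: float | None = None):
        super().__init__(message)
        self.attained = attained


def rng_from(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, Generator or None to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_rngs(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    """Deterministic independent child streams of a parent generator."""
    return rng.spawn(n)


def array_digest(values: np.ndarray) -> str:
    """Stable short content hash of an array (provenance tagging)."""
    arr = np.ascontiguousarray(values)
    h = hashlib.sha1(arr.tobytes())
    h.update(str(arr.shape).encode())
    return h.hexdigest()[:12]


def as_values(data) -> np.ndarray:
    """Extract a 2-D float array from an IndicatorMatrix, DataFrame or array."""
    values = getattr(data, "values", data)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise PreconditionError(f"expected a 2-D cases x indicators array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = np.unique(np.nonzero(~np.isfinite(arr))[0])
        raise PreconditionError(f"non-finite entries in rows {bad.tolist()[:10]}")
    return arr


def safe_corr(values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix with zero-variance columns mapped to r=0.

    Constant columns carry no correlation information (they can occur in
    small putative-taxon strata); treating their entries as 0 keeps the
    iterative correlation-matching loop finite instead of propagating NaN.
    """
    arr = np.asarray(values, dtype=float)
    k = arr.shape[1]
    sd = arr.std(axis=0)
    ok = sd > 0
    corr = np.eye(k)
    if ok.sum() >= 2:
        sub = np.corrcoef(arr[:, ok], rowvar=False)
        idx = np.nonzero(ok)[0]
        corr[np.ix_(idx, idx)] = sub
    return corr


def mean_offdiag(corr: np.ndarray) -> float:
    """Mean of the lower-triangle (pairwise) correlations."""
    iu = np.tril_indices_from(corr, k=-1)
    return float(np.mean(corr[iu]))


def to_frame(values: np.ndarray, columns) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(values), columns=list(columns))
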