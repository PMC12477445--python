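"""The three non-redundant taxometric curve procedures.

* MAMBAC (mean above minus below a cut): sort cases on an input indicator and,
  at each candidate cut, record the output indicator's mean above minus mean
  at-or-below the cut.  Taxonic structure peaks; dimensional structure dishes.
* MAXEIG (maximum eigenvalue): slide overlapping windows along the sorted
  input indicator and record the largest eigenvalue of the zero-diagonal
  covariance matrix of the remaining indicators within each window.
* L-Mode (latent-mode factor analysis): kernel density of one-factor
  (principal-axis) regression scores; multimodality indicates a taxon.

Coordinate convention: MAMBAC cut positions and MAXEIG window centres are
reported in 1-based case-rank space, so curves from equal-n samples share a
grid exactly.  Ordinal indicators produce heavy ties; tie order is randomized
per replication and the y values averaged.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._utils import ConfigurationError, PreconditionError, as_values, rng_from

MAMBAC = "MAMBAC"
MAXEIG = "MAXEIG"
LMODE = "LMODE"


@dataclass
class TaxometricCurve:
    """One procedure's (x, y) curve; the unit the CCFI compares."""

    procedure: str
    x: np.ndarray
    y: np.ndarray
    grid_key: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise PreconditionError("x and y must be 1-D and equally long")
        if np.any(np.diff(self.x) <= 0):
            raise PreconditionError("x must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "procedure": self.procedure,
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "grid_key": self.grid_key,
            "meta": {k: v for k, v in self.meta.items() if _json_safe(v)},
        }


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _grid_key(**kwargs) -> str:
    payload = json.dumps(kwargs, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def _ranked_order(col: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sort order on one indicator with random tie-breaking."""
    return np.lexsort((rng.random(col.shape[0]), col))


def _cut_positions(n: int, n_cuts: int, end_margin: int) -> np.ndarray:
    if end_margin < 1:
        raise ConfigurationError("end_margin must leave at least one case beyond each extreme cut")
    if n - 2 * end_margin < n_cuts - 1:
        raise PreconditionError(
            f"need n >= 2*end_margin + n_cuts - 1 = {2 * end_margin + n_cuts - 1}, got {n}"
        )
    return np.round(np.linspace(end_margin, n - end_margin, n_cuts)).astype(int)


def mambac_curve(
    data,
    input_idx: int,
    output_idx: int,
    n_cuts: int = 50,
    end_margin: int = 25,
    replications: int = 10,
    seed=None,
) -> TaxometricCurve:
    """Mean-above-minus-below-a-cut curve for one (input, output) indicator pair."""
    x = as_values(data)
    n = x.shape[0]
    if input_idx == output_idx:
        raise ConfigurationError("input and output indicators must differ")
    cuts = _cut_positions(n, n_cuts, end_margin)
    inp, out = x[:, input_idx], x[:, output_idx]
    if out.std() == 0:
        warnings.warn("constant output indicator; MAMBAC curve is identically zero", stacklevel=2)
    rng = rng_from(seed)
    total = out.sum()
    ys = np.zeros((replications, len(cuts)))
    for rep in range(replications):
        order = _ranked_order(inp, rng)
        csum = np.cumsum(out[order])
        below = csum[cuts - 1] / cuts  # mean of ranks 1..c
        above = (total - csum[cuts - 1]) / (n - cuts)
        ys[rep] = above - below
    key = _grid_key(proc=MAMBAC, n=n, n_cuts=n_cuts, end_margin=end_margin)
    return TaxometricCurve(
        MAMBAC,
        cuts.astype(float),
        ys.mean(axis=0),
        grid_key=key,
        meta={"input": int(input_idx), "output": int(output_idx), "replications": replications, "n": n},
    )


def _pointwise_mean(curves: list[TaxometricCurve], procedure: str) -> TaxometricCurve:
    keys = {c.grid_key for c in curves}
    if len(keys) != 1:
        raise PreconditionError("panel members are on different grids")
    y = np.mean([c.y for c in curves], axis=0)
    return TaxometricCurve(
        procedure,
        curves[0].x,
        y,
        grid_key=curves[0].grid_key,
        meta={"panel_size": len(curves), "n": curves[0].meta.get("n")},
    )


def mambac_panel(
    data,
    n_cuts: int = 50,
    end_margin: int = 25,
    replications: int = 10,
    seed=None,
) -> tuple[list[TaxometricCurve], TaxometricCurve]:
    """All ordered indicator pairs (k indicators -> k*(k-1) curves) + panel mean."""
    x = as_values(data)
    k = x.shape[1]
    if k < 2:
        raise PreconditionError("MAMBAC needs at least 2 indicators")
    rng = rng_from(seed)
    curves = []
    for i in range(k):
        for j in range(k):
            if i != j:
                curves.append(
                    mambac_curve(x, i, j, n_cuts, end_margin, replications, seed=rng.spawn(1)[0])
                )
    return curves, _pointwise_mean(curves, MAMBAC)


def _window_slices(n: int, n_windows: int, overlap: float) -> tuple[np.ndarray, int]:
    """Equal-length overlapping windows tiling ranks 0..n-1."""
    if not 0 <= overlap < 1:
        raise ConfigurationError("overlap must lie in [0, 1)")
    length = int(round(n / (1 + (n_windows - 1) * (1 - overlap))))
    length = max(length, 2)
    if n_windows == 1:
        return np.array([0]), n
    step = (n - length) / (n_windows - 1)
    if step < 1:
        raise PreconditionError(
            f"{n_windows} windows at overlap {overlap} do not fit n={n}; use fewer windows"
        )
    starts = np.round(np.arange(n_windows) * step).astype(int)
    return starts, length


def maxeig_curve(
    data,
    input_idx: int,
    n_windows: int = 50,
    overlap: float = 0.90,
    replications: int = 10,
    seed=None,
) -> TaxometricCurve:
    """Largest zero-diagonal covariance eigenvalue in windows along one input."""
    x = as_values(data)
    n, k = x.shape
    if k < 3:
        raise PreconditionError("MAXEIG needs >= 3 indicators (>= 2 outputs)")
    starts, length = _window_slices(n, n_windows, overlap)
    n_out = k - 1
    if length < n_out + 1:
        raise PreconditionError(
            f"windows of {length} cases cannot estimate a {n_out}x{n_out} covariance; use fewer windows"
        )
    out_cols = [j for j in range(k) if j != input_idx]
    inp = x[:, input_idx]
    rng = rng_from(seed)
    win_rows = starts[:, None] + np.arange(length)[None, :]
    ys = np.zeros((replications, len(starts)))
    mean_inputs = np.zeros((replications, len(starts)))
    for rep in range(replications):
        order = _ranked_order(inp, rng)
        sorted_out = x[order][:, out_cols]
        sorted_in = inp[order]
        win = sorted_out[win_rows]  # (w, L, k-1)
        centered = win - win.mean(axis=1, keepdims=True)
        cov = np.einsum("wlk,wlm->wkm", centered, centered) / (length - 1)
        idx = np.arange(n_out)
        cov[:, idx, idx] = 0.0
        ys[rep] = np.linalg.eigvalsh(cov)[:, -1]
        mean_inputs[rep] = sorted_in[win_rows].mean(axis=1)
    centres = starts + (length + 1) / 2  # 1-based mid-rank of each window
    key = _grid_key(proc=MAXEIG, n=n, n_windows=n_windows, overlap=overlap, k=k)
    return TaxometricCurve(
        MAXEIG,
        centres,
        ys.mean(axis=0),
        grid_key=key,
        meta={
            "input": int(input_idx),
            "window_length": length,
            "replications": replications,
            "mean_input": mean_inputs.mean(axis=0).tolist(),
            "n": n,
        },
    )


def maxeig_panel(
    data,
    n_windows: int = 50,
    overlap: float = 0.90,
    replications: int = 10,
    seed=None,
) -> tuple[list[TaxometricCurve], TaxometricCurve]:
    """Each indicator as input in turn (k curves) + panel mean."""
    x = as_values(data)
    k = x.shape[1]
    rng = rng_from(seed)
    curves = [
        maxeig_curve(x, i, n_windows, overlap, replications, seed=rng.spawn(1)[0]) for i in range(k)
    ]
    return curves, _pointwise_mean(curves, MAXEIG)


def principal_axis_loadings(
    corr: np.ndarray, max_iter: int = 100, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """One-factor principal-axis loadings and final communalities.

    Initial communalities are squared multiple correlations; Heywood cases
    (communality >= 1) are clamped with a warning.  Loadings are sign-fixed so
    their sum is positive.
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        raise PreconditionError("singular correlation matrix; drop redundant indicators") from None
    h = 1 - 1 / np.diag(inv)  # SMC initial communalities
    loadings = np.zeros(k)
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h)
        vals, vecs = np.linalg.eigh(reduced)
        e1, v1 = vals[-1], vecs[:, -1]
        loadings = v1 * np.sqrt(max(e1, 0.0))
        h_new = loadings**2
        if np.any(h_new >= 1):
            warnings.warn("Heywood case: communality clamped to 0.995", stacklevel=3)
            h_new = np.minimum(h_new, 0.995)
            loadings = np.sign(loadings) * np.sqrt(h_new)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    if loadings.sum() < 0:
        loadings = -loadings
    return loadings, h


def factor_scores(data, loadings: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Regression-method factor scores, standardized to unit variance."""
    x = as_values(data)
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    weights = np.linalg.solve(corr, loadings)
    scores = z @ weights
    sd = scores.std()
    if sd == 0:
        raise PreconditionError("degenerate factor scores (zero variance)")
    return scores / sd


def lmode_curve(
    data,
    grid: np.ndarray | None = None,
    grid_size: int = 512,
    bandwidth: str | float = "silverman",
    mode_floor: float = 0.01,
) -> TaxometricCurve:
    """Kernel density of one-factor scores; modes flag latent classes.

    A Gaussian KDE with the Silverman rule is evaluated on an even grid
    spanning the scores +/- 4 bandwidths (so the density integrates to ~1 on
    the grid).  Pass ``grid`` explicitly to evaluate comparison-sample curves
    on the empirical curve's grid.  Local maxima below ``mode_floor`` of the
    global peak are ignored as numerical ripple.  With >= 2 modes the meta
    carries a base-rate estimate: the share of cases nearer the rightmost
    mode than the leftmost.
    """
    x = as_values(data)
    n, k = x.shape
    if k < 2:
        raise PreconditionError("L-Mode needs at least 2 indicators")
    if n < 50:
        raise PreconditionError("L-Mode needs at least 50 cases")
    if np.any(x.std(axis=0) == 0):
        raise PreconditionError("constant indicator column; L-Mode correlation matrix is singular")
    corr = np.corrcoef(x, rowvar=False)
    loadings, communalities = principal_axis_loadings(corr)
    scores = factor_scores(x, loadings, corr)
    kde = stats.gaussian_kde(scores, bw_method=bandwidth)
    h = kde.factor * scores.std(ddof=1)
    if grid is None:
        grid = np.linspace(scores.min() - 4 * h, scores.max() + 4 * h, grid_size)
    else:
        grid = np.asarray(grid, dtype=float)
    dens = kde(grid)

    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    mode_idx = np.nonzero(interior)[0] + 1
    mode_idx = mode_idx[dens[mode_idx] >= mode_floor * dens.max()]
    modes = grid[mode_idx]
    meta = {
        "loadings": loadings.tolist(),
        "communalities": communalities.tolist(),
        "modes": modes.tolist(),
        "n_modes": int(len(modes)),
        "n": n,
    }
    if len(modes) >= 2:
        cut = (modes[0] + modes[-1]) / 2
        meta["base_rate_estimate"] = float(np.mean(scores > cut))
    key = _grid_key(proc=LMODE, grid=hashlib.sha1(grid.tobytes()).hexdigest())
    return TaxometricCurve(LMODE, grid, dens, grid_key=key, meta=meta)
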