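"""Indicator construction and pre-taxometric suitability diagnostics.

Symptom questionnaires such as the Video Game Dependency Scale (CSAS) measure
each diagnostic criterion with two 4-point ordinal items.  This module turns a
cases x items matrix into a cases x indicators matrix (one indicator per
criterion, the sum of its two items), assigns putative taxon/complement labels
by a criterion-count rule, and checks the classical prerequisites for
taxometric analysis: indicator validity (Cohen's d between the putative
groups), substantial full-sample inter-indicator correlation, and small
within-group ("nuisance") correlation.

Item coding: raw responses are 1 = disagree at all ... 4 = agree fully and are
recoded internally to 0-3, so each two-item indicator ranges 0-6.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import ConfigurationError, PreconditionError, as_values, mean_offdiag

MIN_CODE = 0
MAX_CODE = 3

#: Criterion labels in instrument order, two consecutive items per criterion.
DSM5_CRITERIA = (
    "Preoccupation",
    "Withdrawal",
    "Tolerance",
    "Reduce/stop",
    "Continue despite problems",
    "Give up other activities",
    "Escape adverse moods",
    "Deceive/cover up",
    "Risk/lose",
)

#: The four criteria with direct ICD-11 gaming-disorder counterparts.
ICD11_CRITERIA = (
    "Reduce/stop",
    "Continue despite problems",
    "Give up other activities",
    "Risk/lose",
)

#: Minimum number of criteria met for a putative diagnosis under each rule.
DIAGNOSTIC_RULES = {"DSM5": 5, "ICD11": 4}

#: An indicator sum of >= 4 on the 0-6 scale (both items at least "agree
#: somewhat") counts its criterion as met.  Configurable in
#: :func:`diagnostic_assignment`.
DEFAULT_MET_CUT = 4

#: Suitability thresholds from taxometric practice.
D_THRESHOLD = 1.25
INTER_R_THRESHOLD = 0.30
WITHIN_R_THRESHOLD = 0.30


def _default_item_ids() -> list[str]:
    return [f"csas{i:02d}" for i in range(1, 19)]


@dataclass(frozen=True)
class IndicatorSetSpec:
    """Named indicator set: ordered (criterion label, item-id pair) entries."""

    name: str
    criteria: tuple[tuple[str, tuple[str, str]], ...]

    def __post_init__(self):
        seen: set[str] = set()
        for _, pair in self.criteria:
            for item in pair:
                if item in seen:
                    raise ConfigurationError(f"item {item!r} assigned to more than one criterion")
                seen.add(item)
        if self.name == "DSM5" and len(self.criteria) != 9:
            raise ConfigurationError("a DSM5 set requires 9 criteria")
        if self.name == "ICD11":
            labels = tuple(label for label, _ in self.criteria)
            if labels != ICD11_CRITERIA:
                raise ConfigurationError(f"an ICD11 set requires exactly the criteria {ICD11_CRITERIA}")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.criteria]

    @classmethod
    def from_schema(cls, schema: dict) -> "IndicatorSetSpec":
        """Build from a JSON-style schema: {"name": ..., "criteria": {label: [a, b]}}."""
        criteria = tuple((label, tuple(pair)) for label, pair in schema["criteria"].items())
        return cls(name=schema.get("name", "custom"), criteria=criteria)

    @classmethod
    def from_json(cls, path) -> "IndicatorSetSpec":
        with open(path) as fh:
            return cls.from_schema(json.load(fh))


def _csas_pairs(criteria) -> tuple:
    items = _default_item_ids()
    by_label = {label: (items[2 * i], items[2 * i + 1]) for i, label in enumerate(DSM5_CRITERIA)}
    return tuple((label, by_label[label]) for label in criteria)


#: Default CSAS layout: items csas01..csas18, two consecutive per criterion.
DSM5_SPEC = IndicatorSetSpec("DSM5", _csas_pairs(DSM5_CRITERIA))
ICD11_SPEC = IndicatorSetSpec("ICD11", _csas_pairs(ICD11_CRITERIA))


@dataclass
class ItemMatrix:
    """Cases x items ordinal responses on the internal 0-3 coding."""

    values: np.ndarray
    item_ids: list[str]

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[1] != len(self.item_ids):
            raise PreconditionError("values must be cases x items matching item_ids")
        if np.issubdtype(arr.dtype, np.floating):
            if not np.all(np.isfinite(arr)):
                bad = np.unique(np.nonzero(~np.isfinite(arr))[0]).tolist()
                raise PreconditionError(f"missing/non-finite item responses in rows {bad[:10]}")
            if not np.all(arr == np.round(arr)):
                raise PreconditionError("item responses must be integers")
        arr = arr.astype(np.int64)
        if arr.min() < MIN_CODE or arr.max() > MAX_CODE:
            raise PreconditionError(
                f"item codes must lie in [{MIN_CODE}, {MAX_CODE}] after recoding; "
                f"got range [{arr.min()}, {arr.max()}]"
            )
        if arr.shape[1] % 2:
            raise PreconditionError("item count must be even (two items per criterion)")
        self.values = arr

    @classmethod
    def from_raw(cls, values, item_ids, coding: str = "1-4") -> "ItemMatrix":
        """Accept raw 1-4 survey coding (recoded to 0-3) or already-0-based codes."""
        arr = np.asarray(values)
        if coding == "1-4":
            arr = arr - 1
        elif coding != "0-3":
            raise ConfigurationError(f"unknown coding {coding!r}; use '1-4' or '0-3'")
        return cls(arr, list(item_ids))

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]


@dataclass
class IndicatorMatrix:
    """Cases x indicators, each indicator the sum of its two parent items (0-6)."""

    values: np.ndarray
    indicator_ids: list[str]
    set_name: str = "custom"

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[1] != len(self.indicator_ids):
            raise PreconditionError("values must be cases x indicators matching indicator_ids")
        self.values = arr

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.indicator_ids)


def read_items(path, schema: dict | None = None) -> ItemMatrix:
    """Read an item-level CSV (header = item ids, one case per row).

    ``schema`` may carry ``coding`` ('1-4', the survey default, or '0-3') and
    an ``items`` list selecting/ordering columns.
    """
    df = pd.read_csv(path)
    schema = schema or {}
    item_ids = schema.get("items", list(df.columns))
    missing = [c for c in item_ids if c not in df.columns]
    if missing:
        raise ConfigurationError(f"items not found in CSV: {missing}")
    sub = df[item_ids]
    if sub.isna().any().any():
        rows = sub.index[sub.isna().any(axis=1)].tolist()
        raise PreconditionError(f"missing item responses in rows {rows[:10]} (imputation is out of scope)")
    return ItemMatrix.from_raw(sub.to_numpy(), item_ids, coding=schema.get("coding", "1-4"))


def build_indicators(items: ItemMatrix, spec: IndicatorSetSpec = DSM5_SPEC) -> IndicatorMatrix:
    """Sum each criterion's two items row-wise into one indicator column."""
    index = {item: j for j, item in enumerate(items.item_ids)}
    cols = []
    for label, (a, b) in spec.criteria:
        try:
            ja, jb = index[a], index[b]
        except KeyError as err:
            raise ConfigurationError(f"criterion {label!r} references unknown item {err.args[0]!r}") from None
        cols.append(items.values[:, ja] + items.values[:, jb])
    return IndicatorMatrix(np.column_stack(cols), [label for label, _ in spec.criteria], set_name=spec.name)


def diagnostic_assignment(
    indicators: IndicatorMatrix,
    spec: IndicatorSetSpec | None = None,
    min_met: int | None = None,
    met_cut: int = DEFAULT_MET_CUT,
) -> np.ndarray:
    """Putative taxon/complement labels from a criterion-count rule.

    A criterion is met when its indicator sum >= ``met_cut`` (default 4 on the
    0-6 scale, i.e. both items at least "agree somewhat").  A case joins the
    putative taxon when it meets at least ``min_met`` criteria (DSM5: 5 of 9;
    ICD11: 4 of 4).  Returns a boolean array, True = taxon.
    """
    set_name = spec.name if spec is not None else indicators.set_name
    if min_met is None:
        if set_name not in DIAGNOSTIC_RULES:
            raise ConfigurationError(f"no diagnostic rule for indicator set {set_name!r}; pass min_met")
        min_met = DIAGNOSTIC_RULES[set_name]
    if spec is not None and spec.labels != indicators.indicator_ids:
        raise ConfigurationError("indicator set does not match the supplied spec")
    if min_met > indicators.n_indicators:
        raise ConfigurationError(
            f"rule requires {min_met} criteria but the set has {indicators.n_indicators}"
        )
    met = np.asarray(indicators.values) >= met_cut
    return met.sum(axis=1) >= min_met


def _pooled_cohens_d(x: np.ndarray, taxon: np.ndarray) -> np.ndarray:
    """Per-column pooled-SD Cohen's d between taxon and complement rows."""
    g1, g0 = x[taxon], x[~taxon]
    n1, n0 = len(g1), len(g0)
    if n1 < 2 or n0 < 2:
        return np.full(x.shape[1], np.nan)
    v1 = g1.var(axis=0, ddof=1)
    v0 = g0.var(axis=0, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (g1.mean(axis=0) - g0.mean(axis=0)) / sp
    return np.where(sp > 0, d, np.nan)


@dataclass
class SuitabilityReport:
    """Pre-taxometric diagnostics and their pass flags.

    Thresholds follow taxometric practice: every indicator's validity
    d > 1.25, full-sample mean pairwise r > .30, and mean within-group
    (nuisance) r <= .30 in both putative groups.
    """

    indicator_ids: list[str]
    cohens_d: np.ndarray
    mean_inter_r: float
    r_within_taxon: float
    r_within_complement: float
    taxon_n: int
    complement_n: int
    validity_ok: bool
    inter_r_ok: bool
    within_r_ok: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.validity_ok and self.inter_r_ok and self.within_r_ok

    def to_dict(self) -> dict:
        return {
            "indicator_ids": list(self.indicator_ids),
            "cohens_d": [None if not np.isfinite(v) else float(v) for v in self.cohens_d],
            "mean_inter_r": float(self.mean_inter_r),
            "r_within_taxon": float(self.r_within_taxon),
            "r_within_complement": float(self.r_within_complement),
            "taxon_n": int(self.taxon_n),
            "complement_n": int(self.complement_n),
            "validity_ok": bool(self.validity_ok),
            "inter_r_ok": bool(self.inter_r_ok),
            "within_r_ok": bool(self.within_r_ok),
            "passed": bool(self.passed),
            "warnings": list(self.warnings),
        }


def suitability_report(indicators: IndicatorMatrix | np.ndarray, labels: np.ndarray) -> SuitabilityReport:
    """Check indicator validity and nuisance correlations against thresholds."""
    x = as_values(indicators)
    ids = getattr(indicators, "indicator_ids", [f"ind{j}" for j in range(x.shape[1])])
    taxon = np.asarray(labels)
    if taxon.dtype.kind in "US":
        taxon = taxon == "taxon"
    taxon = taxon.astype(bool)
    if taxon.shape[0] != x.shape[0]:
        raise PreconditionError("labels length must match the number of cases")
    n1, n0 = int(taxon.sum()), int((~taxon).sum())
    if n1 == 0 or n0 == 0:
        raise PreconditionError("both putative groups must be non-empty")

    notes: list[str] = []
    d = _pooled_cohens_d(x, taxon)
    if n1 < 2 or n0 < 2:
        notes.append("a putative group has <2 cases; indicator validity is undefined")
    if np.any(~np.isfinite(d)) and n1 >= 2 and n0 >= 2:
        notes.append("zero pooled variance for some indicator; its validity is undefined")

    def _mean_r(rows: np.ndarray) -> float:
        if rows.shape[0] < 3:
            return float("nan")
        return mean_offdiag(np.corrcoef(rows, rowvar=False))

    mean_r = _mean_r(x)
    r_t, r_c = _mean_r(x[taxon]), _mean_r(x[~taxon])
    validity_ok = bool(np.all(np.isfinite(d)) and np.all(d > D_THRESHOLD))
    inter_r_ok = bool(np.isfinite(mean_r) and mean_r > INTER_R_THRESHOLD)
    within_r_ok = bool(
        np.isfinite(r_t) and np.isfinite(r_c)
        and r_t <= WITHIN_R_THRESHOLD and r_c <= WITHIN_R_THRESHOLD
    )
    report = SuitabilityReport(
        indicator_ids=list(ids),
        cohens_d=d,
        mean_inter_r=mean_r,
        r_within_taxon=r_t,
        r_within_complement=r_c,
        taxon_n=n1,
        complement_n=n0,
        validity_ok=validity_ok,
        inter_r_ok=inter_r_ok,
        within_r_ok=within_r_ok,
        warnings=notes,
    )
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return report


class IndicatorBuilder(BaseEstimator, TransformerMixin):
    """Transformer from item-level data to summed criterion indicators.

    Parameters
    ----------
    spec : IndicatorSetSpec, default DSM5_SPEC
        Which criteria to build and from which item columns.
    coding : {'1-4', '0-3'}
        Coding of the incoming items; '1-4' is recoded to 0-3.
    """

    def __init__(self, spec: IndicatorSetSpec = DSM5_SPEC, coding: str = "1-4"):
        self.spec = spec
        self.coding = coding

    def fit(self, X, y=None):
        item_ids = list(X.columns) if hasattr(X, "columns") else _default_item_ids()[: np.asarray(X).shape[1]]
        self.item_ids_ = item_ids
        self.indicator_ids_ = self.spec.labels
        return self

    def transform(self, X) -> pd.DataFrame:
        values = X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X)
        items = ItemMatrix.from_raw(values, self.item_ids_, coding=self.coding)
        return build_indicators(items, self.spec).to_frame()

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.indicator_ids_, dtype=object)
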