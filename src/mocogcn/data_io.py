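"""Feature-table I/O, cohort alignment and differential-abundance selection.

The cohort is observed through two views sharing a sample index: a species
relative-abundance table (real-valued, non-negative rows) and an exposome
table (strictly binary 0/1 variables). Tables are delimited text with
samples in rows, a header row of feature identifiers, and ``sample_id`` as
the first column. Feature selection follows the two-sided Wilcoxon
rank-sum test at an unadjusted ``p < alpha`` cut, with the generalized
fold change (mean case-minus-control quantile difference) as the signed
effect size: positive means enrichment in cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VIEW_NAMES = ("species", "exposome")

#: Quantile grid for the generalized fold change: 0.05 .. 0.95 in steps
#: of 0.05, evaluated with the linear-interpolation quantile rule.
GFC_QUANTILES = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass
class OmicsView:
    """One view's sample-by-feature matrix with ordered identifiers."""

    view_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.view_name not in VIEW_NAMES:
            raise ValueError(f"view_name must be one of {VIEW_NAMES}, got {self.view_name!r}")
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (samples x features)")
        n, d = self.X.shape
        if n != len(self.sample_ids) or d != len(self.feature_ids):
            raise ValueError(
                f"shape {self.X.shape} inconsistent with {len(self.sample_ids)} "
                f"sample ids / {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if np.isnan(self.X).any():
            i, j = np.argwhere(np.isnan(self.X))[0]
            raise ValueError(
                f"missing value at sample {self.sample_ids[i]!r}, feature "
                f"{self.feature_ids[j]!r}; impute upstream before loading"
            )
        if self.view_name == "exposome":
            bad = ~np.isin(self.X, (0.0, 1.0))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-binary exposome entry {self.X[i, j]!r} at sample "
                    f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
                )
        elif (self.X < 0).any():
            i, j = np.argwhere(self.X < 0)[0]
            raise ValueError(
                f"negative species abundance at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_features(self, feature_ids: Sequence[str]) -> "OmicsView":
        """Restrict to the given features, preserving this view's order."""
        keep = set(feature_ids)
        idx = [j for j, f in enumerate(self.feature_ids) if f in keep]
        missing = keep - set(self.feature_ids)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)}")
        return OmicsView(
            self.view_name,
            list(self.sample_ids),
            [self.feature_ids[j] for j in idx],
            self.X[:, idx].copy(),
        )


@dataclass
class CohortLabels:
    """Per-sample binary class labels (0=control, 1=case) with a visibility mask.

    ``labeled_mask`` marks the samples whose labels training may see; the
    rest form the unlabeled pool for co-training / transductive evaluation.
    """

    sample_ids: list[str]
    y: np.ndarray
    labeled_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if self.labeled_mask is None:
            self.labeled_mask = np.ones(len(self.y), dtype=bool)
        self.labeled_mask = np.asarray(self.labeled_mask, dtype=bool)
        _check_unique(self.sample_ids, "sample")
        if len(self.y) != len(self.sample_ids) or len(self.labeled_mask) != len(self.y):
            raise ValueError("sample_ids, y and labeled_mask must have equal length")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0 (control) or 1 (case)")
        visible = self.y[self.labeled_mask]
        if visible.size and len(np.unique(visible)) < 2:
            raise ValueError("both classes must be present among labeled samples")

    @property
    def n_samples(self) -> int:
        return len(self.y)


@dataclass
class SelectionResult:
    """Outcome of differential-abundance feature selection."""

    feature_ids: list[str]
    p_values: np.ndarray
    gfc: np.ndarray
    alpha: float
    retained_feature_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.gfc = np.asarray(self.gfc, dtype=float)
        self.retained_feature_ids = [
            f for f, p in zip(self.feature_ids, self.p_values) if p < self.alpha
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "p_value": self.p_values,
                "gfc": self.gfc,
                "retained": self.p_values < self.alpha,
            }
        )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Delimited-text readers / writers (TSV default, samples in rows)

def load_view(path: str | Path, view_name: str, delimiter: str = "\t") -> OmicsView:
    """Read a sample-by-feature table into a validated :class:`OmicsView`.

    The file must have a header row of feature identifiers and sample
    identifiers in the first column (named ``sample_id`` by convention).
    Missing values, duplicate identifiers, and non-binary exposome entries
    are rejected with an error naming the offending sample/feature.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype={0: str},
                     float_precision="round_trip")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(
            f"missing value at sample {row!r}, feature {col!r} in {path}; "
            "metadata imputation is an upstream preprocessing step"
        )
    return OmicsView(
        view_name=view_name,
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(f) for f in df.columns],
        X=df.to_numpy(dtype=float),
    )


def write_view(view: OmicsView, path: str | Path, delimiter: str = "\t") -> None:
    """Write a view back as delimited text in the same dialect as the loader."""
    df = pd.DataFrame(view.X, index=view.sample_ids, columns=view.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter, float_format="%.17g")  # lossless round-trip


def load_labels(path: str | Path, delimiter: str = "\t") -> CohortLabels:
    """Read a two-column ``sample_id, label`` file (label in {0,1})."""
    df = pd.read_csv(path, sep=delimiter, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("labels file needs columns: sample_id, label")
    return CohortLabels(
        sample_ids=[str(s) for s in df.iloc[:, 0]],
        y=df.iloc[:, 1].to_numpy(dtype=int),
    )


def write_labels(labels: CohortLabels, path: str | Path, delimiter: str = "\t") -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.y}).to_csv(
        path, sep=delimiter, index=False
    )


def align_cohort(
    view_a: OmicsView, view_b: OmicsView, labels: CohortLabels
) -> tuple[OmicsView, OmicsView, CohortLabels]:
    """Restrict both views and the labels to their common samples, same order.

    The common order is the order of ``view_a``'s identifiers. The number of
    dropped samples is logged.
    """
    common = set(view_a.sample_ids) & set(view_b.sample_ids) & set(labels.sample_ids)
    if not common:
        raise ValueError("no samples shared by both views and the labels")
    order = [s for s in view_a.sample_ids if s in common]
    n_drop = (
        (len(view_a.sample_ids) - len(order))
        + (len(view_b.sample_ids) - len(order))
        + (len(labels.sample_ids) - len(order))
    )
    if n_drop:
        logger.info("align_cohort: dropped %d non-shared sample entries", n_drop)

    def take(view: OmicsView) -> OmicsView:
        pos = {s: i for i, s in enumerate(view.sample_ids)}
        idx = [pos[s] for s in order]
        return OmicsView(view.view_name, list(order), list(view.feature_ids), view.X[idx])

    pos = {s: i for i, s in enumerate(labels.sample_ids)}
    idx = [pos[s] for s in order]
    lab = CohortLabels(list(order), labels.y[idx], labels.labeled_mask[idx])
    return take(view_a), take(view_b), lab


# ---------------------------------------------------------------------------
# Differential abundance

def wilcoxon_select(view: OmicsView, labels: CohortLabels, alpha: float = 0.05) -> SelectionResult:
    """Two-sided Wilcoxon rank-sum feature screen at raw ``p < alpha``.

    Each feature is tested for a location difference between cases and
    controls; p-values are unadjusted, matching a plain ``p < 0.05``
    screen. The exact null distribution is used for small groups (< 20 per
    group, no ties), the tie-corrected normal approximation otherwise.
    The generalized fold change is reported alongside as the signed effect.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if view.sample_ids != labels.sample_ids:
        raise ValueError("view and labels must share the same sample order")
    case = view.X[labels.y == 1]
    ctrl = view.X[labels.y == 0]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both classes need at least one sample")
    method = "exact" if min(len(case), len(ctrl)) < 20 else "asymptotic"
    p_values = np.empty(view.n_features)
    gfc = np.empty(view.n_features)
    for j in range(view.n_features):
        a, b = case[:, j], ctrl[:, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p_values[j] = 1.0  # identical constant in both groups: no rank signal
        else:
            try:
                p_values[j] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
            except ValueError:
                p_values[j] = stats.mannwhitneyu(
                    a, b, alternative="two-sided", method="asymptotic"
                ).pvalue
        gfc[j] = generalized_fold_change(a, b)
    return SelectionResult(list(view.feature_ids), p_values, gfc, alpha)


def generalized_fold_change(case_values: np.ndarray, control_values: np.ndarray) -> float:
    """Mean case-minus-control difference over the fixed quantile grid.

    A robust location effect: the mean of ``Q_case(q) - Q_control(q)`` for
    q on :data:`GFC_QUANTILES`. Positive values indicate enrichment in
    cases; the measure is antisymmetric under swapping the two groups.
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise ValueError("both groups must be non-empty")
    qc = np.quantile(case_values, GFC_QUANTILES)
    q0 = np.quantile(control_values, GFC_QUANTILES)
    return float(np.mean(qc - q0))
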