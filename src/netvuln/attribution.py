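"""Discriminant-analysis attribution of robustness to topological indicators.

The attribution stage asks which indicators (transitivity, modularity,
density, assortativity, efficiency, diameter, average shortest path) explain
why some networks survive link-depletion attacks longer than others:

1. each indicator column is discretised to quartile codes
   {0.25, 0.5, 0.75, 1.0} across networks,
2. each network's *label* is a median split of the number of single-link
   removals needed to halve its largest connected component under a given
   failure model (0 = fragments with fewer-than-median removals),
3. a single-response partial least squares regression of the labels on the
   coded features yields one signed coefficient per indicator; positive
   coefficients mark indicators whose (relatively) high values accompany
   robustness.

PLS handles the strong collinearity between indicators that would make
ordinary regression coefficients uninterpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cross_decomposition import PLSRegression

from .attacks import EDGE_CRITERIA, score_edges
from .graphcore import IndicatorProfile, indicator_profile
from .trajectories import links_to_half_lcc

__all__ = [
    "INDICATOR_NAMES",
    "CRITERION_COLUMN",
    "LabelAssignment",
    "QuartileDiscretizer",
    "PLSDAAttribution",
    "discretize_quartile",
    "make_labels",
    "plsda_coefficients",
    "attribution_pipeline",
    "coefficient_table",
    "indicator_robustness_correlation",
]

#: Table-row order of the indicator coefficients.
INDICATOR_NAMES = (
    "transitivity",
    "modularity",
    "density",
    "assortativity",
    "efficiency",
    "diameter",
    "asp",
)

#: Failure-model column name per edge-scoring criterion.
CRITERION_COLUMN = {
    "degree": "DPA",
    "betweenness": "BPA",
    "closeness": "CPA",
    "clustering": "CcPA",
    "random": "RND",
    "ipa": "iPA",
}

_CODES = (0.25, 0.5, 0.75, 1.0)


def discretize_quartile(values: Sequence[float]) -> np.ndarray:
    """Quartile codes for one indicator column.

    A value strictly above Q3 codes 1.0; above the median 0.75; above Q1
    0.5; otherwise 0.25.  Quartiles use the linear-interpolation convention.
    Missing values are excluded from the quartiles and coded 0.25.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 4:
        raise ValueError("quartile coding needs at least 4 finite values")
    if np.all(finite == finite[0]):
        warnings.warn("constant indicator column; all codes 0.25", stacklevel=2)
        return np.full(v.shape, 0.25)
    q1, med, q3 = np.percentile(finite, [25, 50, 75])
    codes = np.full(v.shape, 0.25)
    with np.errstate(invalid="ignore"):
        codes[np.isfinite(v) & (v > q1)] = 0.5
        codes[np.isfinite(v) & (v > med)] = 0.75
        codes[np.isfinite(v) & (v > q3)] = 1.0
    return codes


class QuartileDiscretizer(TransformerMixin, BaseEstimator):
    """Column-wise quartile coder with the sklearn transformer interface.

    ``fit`` learns Q1/median/Q3 per column (ignoring non-finite entries);
    ``transform`` maps values to {0.25, 0.5, 0.75, 1.0} by the
    strictly-greater rule.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array")
        qs = []
        for j in range(X.shape[1]):
            col = X[:, j][np.isfinite(X[:, j])]
            if col.size < 4:
                raise ValueError("quartile coding needs at least 4 finite values per column")
            qs.append(np.percentile(col, [25, 50, 75]))
        self.quartiles_ = np.asarray(qs)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature-count mismatch")
        out = np.full(X.shape, 0.25)
        for j in range(X.shape[1]):
            q1, med, q3 = self.quartiles_[j]
            col = X[:, j]
            with np.errstate(invalid="ignore"):
                out[np.isfinite(col) & (col > q1), j] = 0.5
                out[np.isfinite(col) & (col > med), j] = 0.75
                out[np.isfinite(col) & (col > q3), j] = 1.0
        return out


@dataclass(frozen=True)
class LabelAssignment:
    """Median-split binary labels of per-network removal counts
    (0 = strictly below the median, i.e. fragments easily)."""

    counts: tuple[float, ...]
    labels: tuple[int, ...]
    median: float


def make_labels(counts: Sequence[float]) -> LabelAssignment:
    """Binary labels by the strict-below-median rule (ties with the median
    label 1)."""
    c = tuple(float(x) for x in counts)
    if len(c) < 2:
        raise ValueError("need at least two networks to split on the median")
    med = float(np.median(c))
    labels = tuple(0 if x < med else 1 for x in c)
    return LabelAssignment(counts=c, labels=labels, median=med)


class PLSDAAttribution(BaseEstimator):
    """Single-response PLS regression of a binary label on coded features.

    Features are centred and unit-variance scaled internally; the response is
    centred.  ``coef_`` holds the regression coefficients back-projected from
    the latent space, on the standardised-feature scale.  Zero-variance
    columns are dropped with a warning and report coefficient 0.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y shapes do not match")
        if np.ptp(y) == 0:
            raise ValueError("labels are constant; the median split is degenerate")
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=1)
        keep = std > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature column(s); "
                "their coefficients are reported as 0",
                stacklevel=2,
            )
        Xs = (X[:, keep] - mean[keep]) / std[keep]
        yc = y - y.mean()
        k = min(self.n_components, Xs.shape[1], Xs.shape[0] - 1)
        pls = PLSRegression(n_components=k, scale=False)
        pls.fit(Xs, yc)
        coef = np.zeros(X.shape[1])
        coef[keep] = pls.coef_.ravel()
        self.coef_ = coef
        self.kept_ = keep
        self.x_mean_ = mean
        self.x_std_ = std
        self.n_components_ = k
        return self

    def get_feature_coefficients(self) -> np.ndarray:
        return self.coef_


def plsda_coefficients(X, y, n_components: int = 2) -> np.ndarray:
    """Per-feature PLS regression coefficients of ``y`` on ``X`` (thin
    wrapper over :class:`PLSDAAttribution`)."""
    return PLSDAAttribution(n_components=n_components).fit(X, y).coef_


def _feature_matrix(profiles: Sequence[IndicatorProfile]) -> np.ndarray:
    raw = np.array(
        [
            [p.transitivity, p.modularity, p.density, p.assortativity,
             p.efficiency, p.diameter, p.asp]
            for p in profiles
        ],
        dtype=float,
    )
    coded = np.column_stack([discretize_quartile(raw[:, j]) for j in range(raw.shape[1])])
    return coded


def attribution_pipeline(
    networks: Sequence[nx.Graph],
    criterion: str,
    n_components: int = 2,
    seed: int = 0,
    profiles: Sequence[IndicatorProfile] | None = None,
) -> pd.Series:
    """One coefficient per indicator for a single failure model.

    Composes: indicator profiles -> quartile coding -> links-to-half-LCC
    counts under ``criterion`` -> median-split labels -> PLS coefficients.
    Precomputed ``profiles`` may be passed to amortise profiling across
    failure models.
    """
    if criterion not in EDGE_CRITERIA:
        raise ValueError(f"unknown failure criterion: {criterion!r}")
    if len(networks) < 4:
        raise ValueError("attribution needs at least 4 networks")
    if profiles is None:
        profiles = [indicator_profile(g, seed=seed) for g in networks]
    X = _feature_matrix(profiles)
    counts = [
        links_to_half_lcc(g, score_edges(g, criterion, seed=seed)) for g in networks
    ]
    y = np.asarray(make_labels(counts).labels, dtype=float)
    coef = plsda_coefficients(X, y, n_components=n_components)
    return pd.Series(coef, index=list(INDICATOR_NAMES), name=CRITERION_COLUMN[criterion])


def coefficient_table(
    networks: Sequence[nx.Graph],
    criteria: Iterable[str] = ("degree", "betweenness", "closeness", "clustering", "random", "ipa"),
    n_components: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Coefficient matrix: rows = indicators, one column per failure model."""
    profiles = [indicator_profile(g, seed=seed) for g in networks]
    cols = [
        attribution_pipeline(
            networks, c, n_components=n_components, seed=seed, profiles=profiles
        )
        for c in criteria
    ]
    return pd.concat(cols, axis=1)


def indicator_robustness_correlation(
    profiles: Mapping[str, IndicatorProfile] | Sequence[IndicatorProfile],
    indices: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman rank correlation of each indicator with the R_n and R_e
    robustness indices across networks.

    ``indices`` must provide columns ``R_n`` and ``R_e`` aligned with the
    profile order.  Constant indicator columns yield NaN correlations.
    """
    plist = list(profiles.values()) if isinstance(profiles, Mapping) else list(profiles)
    if len(plist) < 3:
        raise ValueError("need at least 3 networks for rank correlations")
    if len(plist) != len(indices):
        raise ValueError("profiles and indices are not aligned")
    raw = pd.DataFrame([p.as_dict() for p in plist])
    rows = []
    for name in INDICATOR_NAMES:
        col = raw[name].to_numpy()
        row = {"indicator": name}
        for target in ("R_n", "R_e"):
            t = indices[target].to_numpy(dtype=float)
            ok = np.isfinite(col) & np.isfinite(t)
            if ok.sum() < 3 or np.ptp(col[ok]) == 0 or np.ptp(t[ok]) == 0:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(col[ok], t[ok])
            row[f"rho_{target}"] = float(rho)
            row[f"p_{target}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("indicator")
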