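"""PCA of the object feature table, score-space gating, group comparisons.

The feature table rows (one per segmented object) are standardized and
decomposed by covariance eigendecomposition. Cluster sub-selection is done
with declarative axis-aligned rectangular gates on a pair of principal
component scores, optionally restricted to one treatment, replacing any
interactive selection with a serializable, reproducible description.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .features import ATTRIBUTE_COLUMNS, FeatureTable

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Principal component decomposition of a standardized attribute matrix.

    ``loadings`` has one column per component (orthonormal); ``scores`` one
    row per retained table row, aligned with ``rows`` (the metadata of the
    rows that survived sentinel filtering).
    """

    attributes: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    rows: pd.DataFrame
    standardized: bool
    n_dropped: int

    def score_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.rows.index, columns=cols)


@dataclass(frozen=True)
class ScoreGate:
    """Axis-aligned rectangle in (PCi, PCj) score space.

    Components are 1-based; ``treatment`` restricts the selection to one
    condition when set. Bounds are half-open on neither side (inclusive).
    """

    pc_x: int
    pc_y: int
    x_bounds: tuple[float, float]
    y_bounds: tuple[float, float]
    treatment: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.x_bounds[0] >= self.x_bounds[1] or self.y_bounds[0] >= self.y_bounds[1]:
            raise ValueError("gate bounds must satisfy lower < upper on both axes")


def run_pca(
    table: FeatureTable | pd.DataFrame,
    attributes: tuple[str, ...] | list[str] | None = None,
    standardize: bool = True,
) -> PcaResult:
    """PCA of selected attributes of the object feature table.

    Rows containing NaN sentinels in the selected attributes are dropped
    (count logged). With ``standardize`` each attribute is z-scored first;
    a constant attribute then has no defined z-score and raises. The sign
    of each loading vector is fixed by making its largest-magnitude element
    positive, so results are fully deterministic.
    """
    df = table.table if isinstance(table, FeatureTable) else table
    attrs = tuple(attributes) if attributes is not None else ATTRIBUTE_COLUMNS
    missing = [a for a in attrs if a not in df.columns]
    if missing:
        raise KeyError(f"attributes not in table: {missing}")
    sub = df.loc[:, list(attrs)].astype(float)
    ok = ~sub.isna().any(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("run_pca: dropped %d rows with undefined attributes", n_dropped)
    sub = sub.loc[ok]
    if len(sub) < 2:
        raise ValueError("need >=2 rows after sentinel filtering")
    x = sub.to_numpy()
    mean = x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [attrs[i] for i in zero]
            raise ValueError(f"constant attribute(s) cannot be standardized: {names}")
        z = (x - mean) / sd
    else:
        sd = np.ones_like(mean)
        z = x - mean
    cov = np.cov(z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    # deterministic sign convention
    for j in range(evecs.shape[1]):
        i_max = np.argmax(np.abs(evecs[:, j]))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    scores = z @ evecs
    meta_cols = [c for c in df.columns if c not in attrs]
    return PcaResult(
        attributes=attrs,
        mean=mean,
        sd=sd,
        eigenvalues=evals,
        variance_fractions=fractions,
        loadings=evecs,
        scores=scores,
        rows=df.loc[ok, meta_cols].copy(),
        standardized=standardize,
        n_dropped=n_dropped,
    )


def gate_scores(pca: PcaResult, gate: ScoreGate) -> pd.DataFrame:
    """Rows whose gated-component scores fall inside the gate rectangle."""
    k = pca.scores.shape[1]
    for pc in (gate.pc_x, gate.pc_y):
        if not 1 <= pc <= k:
            raise KeyError(f"PC{pc} does not exist (result has {k} components)")
    sx = pca.scores[:, gate.pc_x - 1]
    sy = pca.scores[:, gate.pc_y - 1]
    inside = (
        (sx >= gate.x_bounds[0]) & (sx <= gate.x_bounds[1])
        & (sy >= gate.y_bounds[0]) & (sy <= gate.y_bounds[1])
    )
    sel = pca.rows.loc[inside].copy()
    sel[f"PC{gate.pc_x}"] = sx[inside]
    sel[f"PC{gate.pc_y}"] = sy[inside]
    if gate.treatment is not None:
        sel = sel.loc[sel["treatment"] == gate.treatment]
    return sel


def cluster_summary(
    subset: pd.DataFrame, table: pd.DataFrame,
    attributes: tuple[str, ...] = ("pct_voxels_coloc", "n_coloc_objects",
                                   "intensity_sum"),
) -> pd.DataFrame:
    """Per-class mean +- SD of selected attributes over a gated subset."""
    if len(subset) == 0:
        raise ValueError("empty subset: nothing to summarize")
    joined = table.loc[subset.index]
    out = joined.groupby("cls")[list(attributes)].agg(["mean", "std", "count"])
    return out


@dataclass
class GroupComparison:
    """Per-group summary plus one-way ANOVA and adjusted pairwise tests."""

    summary: pd.DataFrame  # index group, columns mean/std/count
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, p_raw, p_adjusted, significant
    method: str
    alpha: float


def condition_summary_and_test(
    table: pd.DataFrame,
    attribute: str,
    grouping: str = "treatment",
    method: str = "holm-sidak",
    alpha: float = 0.01,
) -> GroupComparison:
    """Group means +- SD of one attribute with one-way ANOVA and post-tests.

    ``method`` is "holm-sidak" (default) or "tukey". The significance flag
    uses alpha = 0.01.
    """
    vals = table[[grouping, attribute]].dropna()
    groups = {g: v[attribute].to_numpy() for g, v in vals.groupby(grouping)}
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    small = [g for g, v in groups.items() if v.size < 2]
    if small:
        raise ValueError(f"groups with <2 observations: {small}")
    names = sorted(groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p = stats.f_oneway(*(groups[g] for g in names))
    if not np.isfinite(p):
        # degenerate cases: no between-group signal -> p = 1; no
        # within-group variance with distinct means -> p = 0
        p = 0.0 if (np.isfinite(f_stat) and f_stat > 1.0) or np.isinf(f_stat) else 1.0
        f_stat = 0.0 if p == 1.0 else f_stat
    summary = vals.groupby(grouping)[attribute].agg(["mean", "std", "count"])

    pairs, p_raw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            pairs.append((a, b))
            p_raw.append(stats.ttest_ind(groups[a], groups[b]).pvalue)
    if method == "holm-sidak":
        _, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="holm-sidak")
    elif method == "tukey":
        res = pairwise_tukeyhsd(vals[attribute].to_numpy(),
                                vals[grouping].to_numpy(), alpha=alpha)
        tuk = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        lookup = {
            tuple(sorted((row["group1"], row["group2"]))): float(row["p-adj"])
            for _, row in tuk.iterrows()
        }
        p_adj = [lookup[tuple(sorted(pair))] for pair in pairs]
    else:
        raise ValueError(f"unknown method {method!r}")
    pairwise = pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "p_raw": p_raw,
        "p_adjusted": p_adj,
    })
    pairwise["significant"] = pairwise["p_adjusted"] < alpha
    return GroupComparison(summary=summary, f_statistic=float(f_stat),
                           p_value=float(p), pairwise=pairwise, method=method,
                           alpha=alpha)
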