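"""Label-free proteomics processing: normalization, differential expression.

The chain applied to a protein x sample intensity matrix, in order:
column-sum normalization, log2 transform with zeros imputed as 1 (so
missing values land at log2 = 0), optional LOESS bias correction against
the median reference profile, one-way ANOVA per protein across treatment
groups, and Benjamini-Hochberg FDR adjustment. Zero intensities are treated
as missing-at-acquisition, the convention of label-free MS software.

A seeded synthetic generator plants a known fraction of differentially
expressed proteins with intensity-dependent missingness, giving the
pipeline a ground truth for sensitivity / false-discovery checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class LfqMatrix:
    """Protein x sample label-free intensity matrix.

    ``intensities`` is a DataFrame (rows = proteins, columns = samples),
    non-negative, with 0 meaning "not observed". ``groups`` maps each sample
    column to its treatment group.
    """

    intensities: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be >= 0")
        missing = set(self.intensities.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if not self.intensities.index.is_unique:
            raise ValueError("protein ids must be unique")
        counts = pd.Series(list(self.groups.values())).value_counts()
        if (counts < 2).any():
            raise ValueError("each group needs >=2 samples")

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups.values()))


@dataclass
class DEResult:
    """Per-protein differential expression summary.

    ``table`` columns: mean log2 intensity per group, log2 fold change of
    each non-control group vs control, ANOVA p, BH q, testable flag,
    significant flag (q < threshold over testable proteins).
    """

    table: pd.DataFrame
    control: str
    q_threshold: float

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def generate_lfq(
    n_proteins: int = 2000,
    groups: tuple[str, ...] = ("control", "LPS", "iE-DAP"),
    n_per_group: int = 3,
    de_fraction: float = 0.05,
    effect_log2: float = 2.0,
    missing_rate: float = 0.1,
    seed: int = 0,
) -> tuple[LfqMatrix, pd.Series]:
    """Synthetic LFQ matrix with planted differential expression.

    Baseline log2 intensities are drawn per protein from N(23, 2) with
    N(0, 0.25) sample noise. A ``de_fraction`` of proteins receives a
    +-``effect_log2`` shift in one random non-control group. Missingness is
    intensity-dependent: the per-cell dropout probability decreases linearly
    with the cell's intensity rank while averaging ``missing_rate``.
    Returns the matrix and a boolean ground-truth DE label per protein.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0,1]")
    if effect_log2 < 0:
        raise ValueError("effect_log2 must be >= 0")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    samples, group_of = [], {}
    for g in groups:
        for r in range(n_per_group):
            s = f"{g}_{r + 1}"
            samples.append(s)
            group_of[s] = g
    base = rng.normal(23.0, 2.0, size=n_proteins)
    log2_mat = base[:, None] + rng.normal(0.0, 0.25,
                                          size=(n_proteins, len(samples)))
    n_de = int(round(de_fraction * n_proteins))
    de_idx = rng.choice(n_proteins, size=n_de, replace=False)
    non_control = [g for g in groups if g != groups[0]]
    for i in de_idx:
        g = non_control[rng.integers(len(non_control))] if non_control else groups[0]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        cols = [j for j, s in enumerate(samples) if group_of[s] == g]
        log2_mat[i, cols] += sign * effect_log2
    intensities = 2.0 ** log2_mat
    if missing_rate > 0:
        flat = intensities.ravel()
        ranks = stats.rankdata(flat) / flat.size  # in (0, 1]
        p_missing = np.clip(2.0 * missing_rate * (1.0 - ranks), 0.0, 1.0)
        drop = rng.random(flat.size) < p_missing
        flat = flat.copy()
        flat[drop] = 0.0
        intensities = flat.reshape(intensities.shape)
    mat = LfqMatrix(
        intensities=pd.DataFrame(intensities, index=proteins, columns=samples),
        groups=group_of,
    )
    truth = pd.Series(False, index=proteins, name="is_de")
    truth.iloc[de_idx] = True
    return mat, truth


def sum_normalize(matrix: LfqMatrix) -> LfqMatrix:
    """Scale each sample column so all column sums equal the mean raw sum."""
    df = matrix.intensities
    sums = df.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample column(s): {list(zero.index)}")
    scaled = df * (sums.mean() / sums)
    return LfqMatrix(intensities=scaled, groups=dict(matrix.groups))


def log2_with_zero_imputation(matrix: LfqMatrix) -> pd.DataFrame:
    """log2 transform after imputing zeros with 1 (imputed cells become 0)."""
    df = matrix.intensities
    if (df.to_numpy() < 0).any():
        raise ValueError("negative intensities")
    return np.log2(df.where(df > 0, 1.0))


def loess_normalize(
    log2_df: pd.DataFrame,
    span: float = 0.4,
    imputed_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample LOESS bias correction against the median reference profile.

    For each sample, fits a LOESS curve of M = sample - reference against
    A = (sample + reference) / 2, where the reference is the per-protein
    median over samples, and subtracts the fitted bias. Cells flagged as
    imputed (default: log2 value == 0) are excluded from both the reference
    and the fit, and are left unchanged.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if len(log2_df) < 50:
        raise ValueError("need >=50 proteins for a stable LOESS fit")
    if imputed_mask is None:
        imputed_mask = log2_df == 0
    observed = log2_df.where(~imputed_mask)
    reference = observed.median(axis=1)
    out = log2_df.copy()
    for col in log2_df.columns:
        ok = (~imputed_mask[col]) & reference.notna()
        if ok.sum() < 10:
            log.warning("loess_normalize: sample %s has <10 usable proteins", col)
            continue
        m = (log2_df[col] - reference)[ok]
        a = ((log2_df[col] + reference) / 2.0)[ok]
        fitted = lowess(m.to_numpy(), a.to_numpy(), frac=span,
                        xvals=a.to_numpy())
        out.loc[ok, col] = log2_df.loc[ok, col] - fitted
    return out


def anova_fdr(
    log2_df: pd.DataFrame,
    groups: dict[str, str],
    control: str | None = None,
    q_threshold: float = 0.001,
    imputed_mask: pd.DataFrame | None = None,
) -> DEResult:
    """One-way ANOVA per protein with Benjamini-Hochberg FDR adjustment.

    A protein is testable when every group retains >=2 non-imputed
    observations; others get NaN p/q and are flagged not testable. q-values
    are computed across testable proteins only; the significant set is
    q < ``q_threshold``.
    """
    group_names = sorted(set(groups.values()))
    if len(group_names) < 2:
        raise ValueError("need >=2 groups")
    if control is None:
        control = group_names[0]
    if imputed_mask is None:
        imputed_mask = log2_df == 0
    values = log2_df.to_numpy(dtype=float)
    keep = ~imputed_mask.loc[log2_df.index, log2_df.columns].to_numpy(dtype=bool)
    # vectorized one-way ANOVA from per-group sufficient statistics
    n_g, sum_g, sumsq_g = {}, {}, {}
    for g in group_names:
        cols = np.array([groups[s] == g for s in log2_df.columns])
        k_gm = keep[:, cols]
        v_gm = np.where(k_gm, values[:, cols], 0.0)
        n_g[g] = k_gm.sum(axis=1)
        sum_g[g] = v_gm.sum(axis=1)
        sumsq_g[g] = (v_gm**2).sum(axis=1)
    testable = np.all([n_g[g] >= 2 for g in group_names], axis=0)
    n_tot = sum(n_g[g] for g in group_names)
    sum_tot = sum(sum_g[g] for g in group_names)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = sum_tot / n_tot
        ssb = sum(
            n_g[g] * (sum_g[g] / np.maximum(n_g[g], 1) - grand) ** 2
            for g in group_names
        )
        ssw = sum(
            sumsq_g[g] - (sum_g[g] ** 2) / np.maximum(n_g[g], 1)
            for g in group_names
        )
        ssw = np.maximum(ssw, 0.0)
        df1 = len(group_names) - 1
        df2 = n_tot - len(group_names)
        f = (ssb / df1) / (ssw / np.maximum(df2, 1))
        p = stats.f.sf(f, df1, np.maximum(df2, 1))
    # degenerate cases: no within-group variance
    p = np.where(ssw == 0, np.where(ssb <= 1e-24, 1.0, 0.0), p)
    p = np.where(np.isfinite(p), p, 1.0)
    table = pd.DataFrame(index=log2_df.index)
    table["testable"] = testable
    means = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for g in group_names:
            means[g] = np.where(n_g[g] > 0, sum_g[g] / np.maximum(n_g[g], 1),
                                np.nan)
            table[f"mean_log2_{g}"] = means[g]
    for g in group_names:
        if g != control:
            table[f"log2fc_{g}"] = means[g] - means[control]
    table["p"] = np.where(testable, p, np.nan)
    table["q"] = np.nan
    testable_idx = table.index[table["testable"]]
    if len(testable_idx):
        _, q, _, _ = multipletests(table.loc[testable_idx, "p"], method="fdr_bh")
        table.loc[testable_idx, "q"] = q
    table["significant"] = table["q"] < q_threshold
    return DEResult(table=table, control=control, q_threshold=q_threshold)


@dataclass
class ClusterResult:
    """Hierarchical clustering of samples and proteins.

    Distance = 1 - Pearson correlation; samples use complete linkage,
    proteins median linkage. ``sample_order`` / ``protein_order`` are the
    dendrogram leaf orders.
    """

    sample_linkage: np.ndarray
    protein_linkage: np.ndarray
    sample_order: list[str]
    protein_order: list[str]


def _correlation_condensed(data: np.ndarray, names, what: str) -> np.ndarray:
    sd = data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant {what} (correlation distance undefined): "
            f"{[names[i] for i in bad[:5]]}"
        )
    corr = np.corrcoef(data)
    d = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def hierarchical_cluster(log2_df: pd.DataFrame) -> ClusterResult:
    """Two-way hierarchical clustering of a log2 expression matrix."""
    if log2_df.shape[0] < 2 or log2_df.shape[1] < 2:
        raise ValueError("need >=2 proteins and >=2 samples")
    samp_d = _correlation_condensed(log2_df.to_numpy().T,
                                    list(log2_df.columns), "sample")
    prot_d = _correlation_condensed(log2_df.to_numpy(),
                                    list(log2_df.index), "protein")
    zs = linkage(samp_d, method="complete")
    zp = linkage(prot_d, method="median")
    return ClusterResult(
        sample_linkage=zs,
        protein_linkage=zp,
        sample_order=[log2_df.columns[i] for i in leaves_list(zs)],
        protein_order=[log2_df.index[i] for i in leaves_list(zp)],
    )


def de_pipeline(
    matrix: LfqMatrix,
    loess: bool = True,
    span: float = 0.4,
    control: str | None = None,
    q_threshold: float = 0.001,
) -> DEResult:
    """Full chain: sum-normalize -> log2 + impute -> (LOESS) -> ANOVA + BH."""
    normed = sum_normalize(matrix)
    log2_df = log2_with_zero_imputation(normed)
    imputed = matrix.intensities == 0
    if loess:
        log2_df = loess_normalize(log2_df, span=span, imputed_mask=imputed)
    return anova_fdr(log2_df, normed.groups, control=control,
                     q_threshold=q_threshold, imputed_mask=imputed)
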