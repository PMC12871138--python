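"""Differential abundance between conditions within Cre+ channels.

Per protein, the contrast is the difference of mean log2 reporter
intensities between two conditions, tested with Welch's two-sample t-test
(unequal variances).  Significance follows the two printed gates used
throughout this kind of resource: raw p < alpha and fold change above
``fc_min`` in either direction.  Benjamini-Hochberg q-values are reported
alongside but do not gate protein-level calls; term-level enrichment
downstream gates on FDR instead.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from ._errors import ConfigError, ValidationError
from .io_tables import QuantExperiment

logger = logging.getLogger(__name__)

DIFF_COLUMNS = ("protein", "contrast", "log2fc", "p", "q", "significant", "n_a", "n_b")


def contrast_label(condition_a: str, condition_b: str) -> str:
    return f"{condition_a}_vs_{condition_b}"


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Input p-values must lie in (0, 1]; output is clipped at 1 and
    satisfies q >= p elementwise.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(q: QuantExperiment, passing, contrast: tuple[str, str],
                           alpha: float = 0.05, fc_min: float = 1.5,
                           genotype: str = "cre_pos") -> pd.DataFrame:
    """Welch-t differential abundance for ROC-passing proteins.

    ``contrast = (condition_a, condition_b)`` gives
    ``log2fc = mean log2(a) - mean log2(b)`` over the Cre+ channels of
    each condition.  Proteins with fewer than two quantified values in
    either group get an absent p/q and ``significant = False``.  q is BH
    within the contrast over the proteins that were actually tested.
    """
    cond_a, cond_b = contrast
    conditions = set(q.conditions())
    for cond in contrast:
        if cond not in conditions:
            raise ConfigError(f"contrast condition {cond!r} not in design "
                              f"(have {sorted(conditions)})")
    cols_a = q.channel_ids(genotype=genotype, condition=cond_a)
    cols_b = q.channel_ids(genotype=genotype, condition=cond_b)
    if not cols_a or not cols_b:
        raise ConfigError(f"no {genotype} channels for contrast {cond_a} vs {cond_b}")
    label = contrast_label(cond_a, cond_b)
    proteins = sorted(set(passing) & set(q.proteins))
    with np.errstate(divide="ignore"):
        mat_a = np.log2(q.intensities.loc[proteins, cols_a]
                        .where(q.intensities.loc[proteins, cols_a] > 0)).to_numpy()
        mat_b = np.log2(q.intensities.loc[proteins, cols_b]
                        .where(q.intensities.loc[proteins, cols_b] > 0)).to_numpy()

    n_a = np.isfinite(mat_a).sum(axis=1)
    n_b = np.isfinite(mat_b).sum(axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a, mean_b = np.nanmean(mat_a, axis=1), np.nanmean(mat_b, axis=1)
        var_a, var_b = np.nanvar(mat_a, axis=1, ddof=1), np.nanvar(mat_b, axis=1, ddof=1)
    log2fc = np.where((n_a > 0) & (n_b > 0), mean_a - mean_b, np.nan)

    # Welch's t with Welch-Satterthwaite df, vectorized over proteins
    testable = (n_a >= 2) & (n_b >= 2)
    p = np.full(len(proteins), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = var_a / n_a + var_b / n_b
        t = log2fc / np.sqrt(se2)
        df_w = se2 ** 2 / ((var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1))
        p_all = 2.0 * stats.t.sf(np.abs(t), df_w)
    p[testable] = p_all[testable]
    # zero variance in both groups: no evidence against equality when the
    # means agree, certain difference otherwise
    degenerate = testable & ~np.isfinite(p)
    p[degenerate & np.isclose(log2fc, 0.0)] = 1.0
    p[degenerate & ~np.isclose(log2fc, 0.0)] = np.finfo(float).tiny

    log2fc_abs_min = np.log2(fc_min)
    df = pd.DataFrame({"protein": proteins, "contrast": label, "log2fc": log2fc,
                       "p": p, "q": np.nan, "significant": False,
                       "n_a": n_a, "n_b": n_b}, columns=list(DIFF_COLUMNS))
    tested = df["p"].notna()
    if tested.any():
        df.loc[tested, "q"] = bh_adjust(df.loc[tested, "p"].to_numpy())
        df.loc[tested, "significant"] = ((df.loc[tested, "p"] < alpha)
                                         & (df.loc[tested, "log2fc"].abs() > log2fc_abs_min))
    df["significant"] = df["significant"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# clustering of regulated proteins
# ---------------------------------------------------------------------------

@dataclass
class ClusteredHeatmap:
    """Hierarchically clustered log2FC matrix of regulated proteins.

    ``proteins`` is the dendrogram leaf order (a permutation of the
    eligible proteins); ``values`` is the log2FC matrix reordered to it;
    ``imputed`` flags (protein, contrast) cells that were absent from the
    input and set to 0 for clustering only.
    """

    proteins: list[str]
    contrasts: list[str]
    values: pd.DataFrame
    linkage: np.ndarray
    imputed: frozenset[tuple[str, str]]


def cluster_regulated(records: pd.DataFrame, contrasts: list[str] | None = None
                      ) -> ClusteredHeatmap:
    """Cluster proteins significant in >=1 contrast on their log2FC vectors.

    Agglomerative, average linkage, Euclidean distance.  Input rows are
    sorted by protein ID before linkage so the leaf order is deterministic
    under input permutation.
    """
    if contrasts is None:
        contrasts = sorted(records["contrast"].unique())
    eligible = sorted(records.loc[records["significant"], "protein"].unique())
    if len(eligible) < 2:
        raise ValidationError("need >=2 proteins significant in >=1 contrast to cluster")
    wide = (records[records["protein"].isin(eligible)]
            .pivot_table(index="protein", columns="contrast", values="log2fc",
                         aggfunc="first")
            .reindex(index=eligible, columns=contrasts))
    imputed = frozenset((pid, c) for pid in eligible for c in contrasts
                        if pd.isna(wide.at[pid, c]))
    if imputed:
        logger.info("cluster_regulated: %d missing log2fc cells set to 0 for clustering",
                    len(imputed))
    wide = wide.fillna(0.0)
    linkage = hierarchy.linkage(wide.to_numpy(), method="average", metric="euclidean")
    order = hierarchy.leaves_list(linkage)
    leaf_proteins = [eligible[i] for i in order]
    return ClusteredHeatmap(proteins=leaf_proteins, contrasts=list(contrasts),
                            values=wide.loc[leaf_proteins], linkage=linkage,
                            imputed=imputed)


# ---------------------------------------------------------------------------
# cross-dataset fold-change comparison
# ---------------------------------------------------------------------------

def _quadrant(x: float, y: float) -> str:
    if x == 0 or y == 0:
        return "on_axis"
    return f"x_{'up' if x > 0 else 'down'}_y_{'up' if y > 0 else 'down'}"


def cross_comparison(records_x: pd.DataFrame, records_y: pd.DataFrame) -> pd.DataFrame:
    """Full outer join of two fold-change tables for a comparison scatter.

    Proteins present in only one dataset are flagged ``only_in`` x or y
    (margin placement in the figure); shared proteins get a quadrant label
    from their fold-change signs.
    """
    x = records_x[["protein", "log2fc"]].rename(columns={"log2fc": "log2fc_x"})
    y = records_y[["protein", "log2fc"]].rename(columns={"log2fc": "log2fc_y"})
    merged = x.merge(y, on="protein", how="outer", sort=True)
    def row_flags(row):
        has_x, has_y = pd.notna(row["log2fc_x"]), pd.notna(row["log2fc_y"])
        if has_x and has_y:
            return pd.Series({"quadrant": _quadrant(row["log2fc_x"], row["log2fc_y"]),
                              "only_in": "both"})
        return pd.Series({"quadrant": "", "only_in": "x" if has_x else "y"})
    flags = merged.apply(row_flags, axis=1)
    return pd.concat([merged, flags], axis=1)
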