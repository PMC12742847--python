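"""Omics validation of candidate genes.

Two stages mirror the validation design: (1) differential abundance in
case/control proteomics-style matrices — per-feature ordinary least squares
of (log-scale) abundance on a group indicator plus nuisance covariates, with
Benjamini–Hochberg correction across features and a q <= 0.05 significance
flag; cross-dataset consensus is the intersection of the two significant
sets.  (2) per-cell-type differential expression on single-cell-style data —
log fold change (case minus control mean), two-sample t-test, BH across the
full gene x cell-type grid, z-scoring of fold changes within each cell type,
and average-linkage hierarchical clustering of the gene z-profiles.

The regression is solved once for all features: the design matrix is shared,
so the coefficient matrix comes from a single pseudoinverse product and the
per-feature t-statistics from the residual sums of squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage

from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    pass


@dataclass
class DEResult:
    feature: str
    coefficient: float  # group effect on the log scale (case - control)
    p: float
    q: float
    significant: bool


def _group_indicator(groups: pd.Series) -> np.ndarray:
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    if set(levels) == {"case", "control"}:
        case_level = "case"
    else:
        case_level = levels[1]
    g = (groups == case_level).to_numpy(dtype=float)
    if g.sum() < 2 or (len(g) - g.sum()) < 2:
        raise ValueError("each group needs at least 2 samples")
    return g


def differential_abundance(
    matrix: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-feature group-contrast regression with BH correction.

    ``matrix`` is samples x features on a log scale; ``groups`` labels each
    sample case/control; ``covariates`` (optional) adds nuisance columns to
    the design.  Returns a DataFrame (feature, coefficient, p, q,
    significant) in the input feature order.  A rank-deficient design (e.g.
    a covariate fully confounded with group) raises
    :class:`SingularDesignError`; a constant feature gets p = 1 with a
    warning.
    """
    groups = groups.loc[matrix.index]
    g = _group_indicator(groups)
    n = len(matrix)
    cols = [np.ones(n), g]
    if covariates is not None:
        cov = covariates.loc[matrix.index]
        for name in cov.columns:
            cols.append(cov[name].to_numpy(dtype=float))
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
            "a covariate may be confounded with group"
        )
    dof = n - design.shape[1]
    if dof < 1:
        raise ValueError("not enough samples for the design")

    y = matrix.to_numpy(dtype=float)
    pinv = np.linalg.pinv(design)
    beta = pinv @ y  # (n_params, n_features)
    resid = y - design @ beta
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])

    coef = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)

    constant = y.std(axis=0) == 0
    if constant.any():
        logger.warning("%d constant feature(s); p set to 1", int(constant.sum()))
        pvals = np.where(constant, 1.0, pvals)

    q = benjamini_hochberg(pvals)
    return pd.DataFrame(
        {
            "feature": matrix.columns,
            "coefficient": coef,
            "p": pvals,
            "q": q,
            "significant": q <= q_threshold,
        }
    )


def consensus_features(results_a: pd.DataFrame, results_b: pd.DataFrame) -> list[str]:
    """Features flagged significant in both result tables, sorted canonically."""
    sig_a = set(results_a.loc[results_a["significant"], "feature"])
    sig_b = set(results_b.loc[results_b["significant"], "feature"])
    return sorted(sig_a & sig_b)


# ---------------------------------------------------------------------------
# per-cell-type differential expression
# ---------------------------------------------------------------------------

@dataclass
class CellTypeDEProfile:
    """Gene x cell-type DE grid with z-scored fold changes and leaf order."""

    table: pd.DataFrame  # long format: gene, cell_type, lfc, p, q, z
    leaf_order: list[str] = field(default_factory=list)

    def z_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="gene", columns="cell_type", values="z")


def celltype_differential(
    expression: dict[str, pd.DataFrame],
    condition_labels: dict[str, pd.Series],
    q_threshold: float = 0.05,
) -> CellTypeDEProfile:
    """Differential expression per (gene, cell type) with z-score profiles.

    ``expression`` maps cell type -> samples x genes matrix of log-normalized
    expression; ``condition_labels`` maps cell type -> per-sample case/control
    labels.  Per cell: log fold change = mean(case) - mean(control) and a
    two-sample t-test p; BH runs across the full grid; fold changes are
    z-scored within each cell type; genes are clustered on their z-profiles
    (Euclidean distance, average linkage) and returned in dendrogram leaf
    order.  Cell types with fewer than 2 samples in either condition are
    excluded with a warning.
    """
    rows: list[dict] = []
    for cell_type in sorted(expression):
        mat = expression[cell_type]
        labels = condition_labels[cell_type].loc[mat.index]
        case = mat.loc[labels == "case"]
        ctrl = mat.loc[labels == "control"]
        if len(case) < 2 or len(ctrl) < 2 or mat.shape[1] == 0:
            logger.warning("cell type %r excluded: too few samples", cell_type)
            continue
        lfc = case.mean(axis=0) - ctrl.mean(axis=0)
        res = sps.ttest_ind(case.to_numpy(), ctrl.to_numpy(), axis=0)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        for j, gene in enumerate(mat.columns):
            rows.append(
                {"gene": gene, "cell_type": cell_type,
                 "lfc": float(lfc.iloc[j]), "p": float(pvals[j])}
            )
    if not rows:
        raise ValueError("no cell type has enough samples in both conditions")
    table = pd.DataFrame(rows)

    genes = sorted(table["gene"].unique())
    cell_types = sorted(table["cell_type"].unique())
    if len(table) != len(genes) * len(cell_types):
        raise ValueError("grid is incomplete: every cell type must cover every gene")

    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    table["significant"] = table["q"] <= q_threshold

    # z-score fold changes within each cell type
    def _z(group: pd.Series) -> pd.Series:
        if len(group) < 2 or group.std(ddof=0) == 0:
            return pd.Series(0.0, index=group.index)
        return (group - group.mean()) / group.std(ddof=0)

    table["z"] = table.groupby("cell_type")["lfc"].transform(_z)

    z_mat = table.pivot(index="gene", columns="cell_type", values="z")
    if len(z_mat) >= 2:
        lnk = linkage(z_mat.to_numpy(), method="average", metric="euclidean")
        leaf_order = [z_mat.index[i] for i in leaves_list(lnk)]
    else:
        leaf_order = list(z_mat.index)
    return CellTypeDEProfile(table=table, leaf_order=leaf_order)


def log1p_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Convenience log1p transform for raw count matrices (never applied
    silently by the DE functions)."""
    return np.log1p(counts)
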