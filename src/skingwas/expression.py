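"""Expression-level analyses: module scores, group fold changes, and the
paired stimulation-response contrast between donor groups.

The module score is the binned-control scheme used throughout single-cell
work: genes are cut into ``n_bins`` bins of average expression, each module
gene is matched with ``n_ctrl`` control genes drawn from its own bin, and the
score of a column (cell or sample) is the mean expression of the module genes
minus the mean expression of the controls. A module of uninformative genes
therefore scores ~0 regardless of cell depth or gene baseline.

The stimulation contrast takes a paired stimulated/unstimulated count table
for two donor groups, computes per-gene per-donor log2 fold changes (with a
pseudocount), calls a gene "induced" when its geometric-mean fold change
exceeds ``fc_min`` and its Benjamini-Hochberg FDR (paired t-test on log2
values) is at most ``fdr_max``, and then correlates the between-group
difference in mean log2 fold change with the average fold change across the
induced genes (Pearson).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr, ttest_rel
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, DomainError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StimContrastResult:
    """Per-gene stimulation responses plus the diff-vs-avg correlation over
    the induced gene set."""

    table: pd.DataFrame          # gene, mean_log2fc, fc, p, fdr, induced, mu_a, mu_b, avg, diff
    pearson_r: float             # NaN when the induced set is too small
    pearson_p: float
    n_induced: int


def module_score(matrix: pd.DataFrame,
                 module_genes: list[str],
                 n_bins: int = 24,
                 n_ctrl: int = 100,
                 rng: np.random.Generator | int | None = 0) -> pd.Series:
    """Binned-control module score per column of a genes x columns matrix.

    Control genes are sampled from the module gene's expression bin,
    excluding module genes themselves (with replacement when the bin holds
    fewer than ``n_ctrl`` candidates; module genes are used as a last resort
    if a bin contains nothing else).
    """
    if (matrix.values < 0).any():
        raise DomainError("expression matrix contains negative values")
    present = [g for g in module_genes if g in matrix.index]
    if not present:
        raise DegenerateInputError("no module gene is present in the matrix")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    avg = matrix.mean(axis=1)
    n_bins_eff = min(n_bins, max(1, matrix.shape[0]))
    # rank-based cut so ties/skew cannot empty bins
    bins = pd.qcut(avg.rank(method="first"), n_bins_eff, labels=False)
    module_set = set(present)

    control_values = np.zeros(matrix.shape[1])
    n_drawn = 0
    for gene in present:
        in_bin = bins.index[bins == bins[gene]]
        # sorted so the draw is invariant to the matrix's row order
        candidates = sorted(g for g in in_bin if g not in module_set)
        if not candidates:
            candidates = sorted(g for g in in_bin if g != gene) or [gene]
        replace = len(candidates) < n_ctrl
        chosen = rng.choice(np.array(candidates, dtype=object), size=n_ctrl,
                            replace=replace)
        control_values += matrix.loc[list(chosen)].mean(axis=0).to_numpy()
        n_drawn += 1
    control_mean = control_values / n_drawn
    score = matrix.loc[present].mean(axis=0).to_numpy() - control_mean
    return pd.Series(score, index=matrix.columns, name="module_score")


def group_fold_change(matrix: pd.DataFrame,
                      labels: pd.Series,
                      gene: str,
                      label_a: str,
                      label_b: str,
                      pseudocount: float = 1.0) -> tuple[float, float]:
    """Fold change mean(a)/mean(b) of one gene on pseudocounted values, with a
    two-sided Wilcoxon rank-sum p-value across columns."""
    if gene not in matrix.index:
        raise DegenerateInputError(f"gene {gene!r} not in the matrix")
    a = matrix.loc[gene, labels.index[labels == label_a]].to_numpy() + pseudocount
    b = matrix.loc[gene, labels.index[labels == label_b]].to_numpy() + pseudocount
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError(f"empty group: {label_a}={len(a)}, {label_b}={len(b)}")
    fc = float(a.mean() / b.mean())
    p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return fc, p


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone q-values)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def per_donor_log2fc(paired: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Wide table of log2((stimulated + pc)/(unstimulated + pc)) per
    (gene, donor), with the donor group carried along.

    ``paired`` is a long table with columns gene, donor, group, condition,
    count and exactly one stimulated and one unstimulated row per
    (gene, donor).
    """
    need = {"gene", "donor", "group", "condition", "count"}
    if not need.issubset(paired.columns):
        raise DomainError(f"paired table needs columns {sorted(need)}")
    wide = paired.pivot_table(index=["gene", "donor", "group"],
                              columns="condition", values="count",
                              aggfunc="first")
    if wide[["stimulated", "unstimulated"]].isna().any().any():
        raise DegenerateInputError("unpaired rows: every (gene, donor) needs one "
                                   "stimulated and one unstimulated count")
    wide = wide.reset_index()
    wide["log2fc"] = np.log2((wide["stimulated"] + pseudocount)
                             / (wide["unstimulated"] + pseudocount))
    return wide


def stimulation_contrast(paired: pd.DataFrame,
                         fc_min: float = 1.5,
                         fdr_max: float = 0.10,
                         pseudocount: float = 1.0,
                         log_scale: bool = True) -> StimContrastResult:
    """Ancestry contrast of the stimulation response.

    Induced genes have geometric-mean fold change strictly above ``fc_min``
    and BH FDR at most ``fdr_max`` (paired t-test of log2 stimulated vs
    unstimulated values across all donors). Over the induced set, Pearson
    correlation is computed between the group difference of mean log2 fold
    change and the average response ((mu_A + mu_B)/2); ``log_scale=False``
    switches both axes to raw fold changes.
    """
    fcs = per_donor_log2fc(paired, pseudocount)
    groups = sorted(fcs["group"].unique())
    if len(groups) != 2:
        raise DomainError(f"expected exactly 2 donor groups, got {groups}")
    g_a, g_b = groups
    n_donors = fcs.groupby("group")["donor"].nunique()
    if (n_donors < 2).any():
        raise DegenerateInputError(f"need >= 2 donors per group, got {dict(n_donors)}")

    rows = []
    for gene, sub in fcs.groupby("gene", sort=True):
        l2 = np.log2(sub["stimulated"] + pseudocount), np.log2(sub["unstimulated"] + pseudocount)
        t = ttest_rel(l2[0], l2[1])
        mean_l2 = float(sub["log2fc"].mean())
        mu_a = float(sub.loc[sub["group"] == g_a, "log2fc"].mean())
        mu_b = float(sub.loc[sub["group"] == g_b, "log2fc"].mean())
        rows.append({"gene": gene, "mean_log2fc": mean_l2, "fc": 2.0 ** mean_l2,
                     "p": float(t.pvalue), "mu_a": mu_a, "mu_b": mu_b,
                     "avg": (mu_a + mu_b) / 2, "diff": mu_a - mu_b})
    table = pd.DataFrame(rows)
    table["fdr"] = benjamini_hochberg(table["p"])
    table["induced"] = (table["fc"] > fc_min) & (table["fdr"] <= fdr_max)

    induced = table[table["induced"]]
    if len(induced) < 3:
        warnings.warn(f"only {len(induced)} induced genes; diff-vs-avg correlation "
                      "is undefined", stacklevel=2)
        r, rp = float("nan"), float("nan")
    else:
        if log_scale:
            x, y = induced["avg"], induced["diff"]
        else:
            x = 2.0 ** induced["avg"]
            y = 2.0 ** induced["mu_a"] - 2.0 ** induced["mu_b"]
        res = pearsonr(x, y)
        r, rp = float(res.statistic), float(res.pvalue)
    return StimContrastResult(table=table, pearson_r=r, pearson_p=rp,
                              n_induced=int(table["induced"].sum()))


def read_expression_matrix(path, labels_path=None) -> tuple[pd.DataFrame, pd.Series | None]:
    """Genes x samples TSV (first column gene ids) plus an optional per-column
    label TSV (column id, label)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if matrix.index.duplicated().any():
        raise DomainError(f"{path}: duplicate gene ids")
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", index_col=0, comment="#")
        labels = lab.iloc[:, 0]
        labels = labels.reindex(matrix.columns)
        if labels.isna().any():
            raise DomainError(f"{labels_path}: labels missing for some columns")
    return matrix, labels
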