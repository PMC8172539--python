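"""Differential GPCR expression screen for layer-5 pyramidal cell targets.

The screen contrasts a target set of cells (Set-T: either reporter-pulled
glutamatergic cells or cells from L4/5 intratelencephalic clusters) against a
contrast set (Set-C) assembled at one of three conservatism levels, and for
every gene computes four measures:

1. ``GE`` — mean CPM over each set, and ``expr = log2(1 + GE)`` (the
   pseudocount makes a silent gene score exactly 0);
2. ``diff_mean`` — the log2 fold-change ``expr_T - expr_C``;
3. ``beta`` — the signed separation of detection fractions,
   ``sign(diff_mean) * |pct_T - pct_C|`` with detection at CPM >= 1;
4. a two-sided Wilcoxon rank-sum p-value on per-cell expression,
   Bonferroni-corrected over the number of genes tested.

A gene passes the primary criteria when the corrected p-value is below alpha,
the fold-change is positive, and mean expression is at least ``fold_min``-fold
higher in the target set (evaluated on the pseudocounted means, see
:func:`screen_comparison`).  Candidates are then ranked across comparisons
with a G-protein-coupling filter (Gi by default, matching the search for
receptors that inhibit their host cell when activated).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigurationError, ValidationError
from .io_formats import ExpressionDataset

__all__ = [
    "ComparisonDefinition",
    "LAYER_PATTERNS",
    "build_comparison",
    "build_comparison_grid",
    "set_mean_expression",
    "diff_mean",
    "detection_fraction",
    "beta_statistic",
    "wilcoxon_de",
    "bonferroni",
    "screen_comparison",
    "rank_candidates",
]

#: Regular expressions mapping free-text cluster labels to the layer groups
#: the contrast levels are built from.  The human-cortex variant of the
#: screen only needs a different pattern set (deep-layer cluster names), not
#: different code.
LAYER_PATTERNS = {
    "L2/3": r"\bL2[-/ ]?3\b",
    "L4/5-IT": r"\bL4[-/ ]?5\b.*\bIT\b",
    "L6": r"\bL6",
}


@dataclass(frozen=True)
class ComparisonDefinition:
    """Named target/contrast cell sets for one screen comparison.

    ``target_mode`` selects how Set-T is defined (``"reporter"``: cells pulled
    by the fluorescent reporter line; ``"cluster"``: cells in L4/5-IT
    transcriptomic clusters).  ``contrast_level`` grows Set-C from GABAergic
    cells only (1) through + non-neuronal + L6 glutamatergic (2) to
    + L2/3 glutamatergic (3, most conservative).
    """

    name: str
    target_mode: str
    contrast_level: int
    set_T: tuple[str, ...]
    set_C: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.target_mode not in ("reporter", "cluster"):
            raise ConfigurationError(f"unknown target_mode {self.target_mode!r}")
        if self.contrast_level not in (1, 2, 3):
            raise ConfigurationError(f"contrast_level must be 1-3, got {self.contrast_level}")
        if not self.set_T:
            raise ConfigurationError(f"comparison {self.name!r}: empty target set")
        if not self.set_C:
            raise ConfigurationError(f"comparison {self.name!r}: empty contrast set")
        if set(self.set_T) & set(self.set_C):
            raise ConfigurationError(
                f"comparison {self.name!r}: target and contrast sets overlap"
            )


def _match(labels: pd.Series, pattern: str) -> pd.Series:
    return labels.astype(str).str.contains(pattern, regex=True, flags=re.IGNORECASE)


def build_comparison(
    cells: pd.DataFrame,
    target_mode: str,
    contrast_level: int,
    name: str | None = None,
    layer_patterns: dict[str, str] | None = None,
) -> ComparisonDefinition:
    """Assemble Set-T and Set-C from the cell annotation table.

    Cells eligible for both pools (e.g. an L4/5-IT reporter-positive cell when
    the contrast reaches L2/3) are assigned to Set-T and removed from Set-C so
    the sets stay disjoint.
    """
    pat = dict(LAYER_PATTERNS)
    if layer_patterns:
        pat.update(layer_patterns)
    cls = cells["cell_class"]
    glut = cls == "glutamatergic"
    if target_mode == "reporter":
        t_mask = cells["reporter_positive"].astype(bool) & glut
        if not t_mask.any():
            raise ConfigurationError(
                "reporter target mode: no reporter-positive glutamatergic cells"
            )
    elif target_mode == "cluster":
        t_mask = _match(cells["cluster"], pat["L4/5-IT"]) & glut
        if not t_mask.any():
            raise ConfigurationError(
                "cluster target mode: no cluster label matches the L4/5-IT pattern"
            )
    else:
        raise ConfigurationError(f"unknown target_mode {target_mode!r}")

    c_mask = cls == "GABAergic"
    if contrast_level >= 2:
        c_mask = c_mask | (cls == "non-neuronal")
        c_mask = c_mask | (glut & _match(cells["cluster"], pat["L6"]))
    if contrast_level >= 3:
        c_mask = c_mask | (glut & _match(cells["cluster"], pat["L2/3"]))
    if contrast_level not in (1, 2, 3):
        raise ConfigurationError(f"contrast_level must be 1-3, got {contrast_level}")
    c_mask = c_mask & ~t_mask  # disjointness: dual-eligible cells go to Set-T
    if not c_mask.any():
        raise ConfigurationError(
            f"contrast level {contrast_level}: contrast set is empty"
        )
    return ComparisonDefinition(
        name=name or f"{target_mode}-L{contrast_level}",
        target_mode=target_mode,
        contrast_level=contrast_level,
        set_T=tuple(cells.index[t_mask]),
        set_C=tuple(cells.index[c_mask]),
    )


def build_comparison_grid(
    cells: pd.DataFrame,
    target_modes: Sequence[str] = ("reporter", "cluster"),
    contrast_levels: Sequence[int] = (1, 2, 3),
    layer_patterns: dict[str, str] | None = None,
) -> list[ComparisonDefinition]:
    """The full target-mode x contrast-level grid (six comparisons by default)."""
    return [
        build_comparison(cells, mode, level, layer_patterns=layer_patterns)
        for mode in target_modes
        for level in contrast_levels
    ]


def set_mean_expression(
    ds: ExpressionDataset, cell_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean CPM (``GE``) and ``expr = log2(1 + GE)`` over a cell set."""
    if len(cell_ids) == 0:
        raise ValueError("cell set is empty")
    pos = ds.cell_positions(cell_ids)
    ge = np.asarray(ds.matrix[:, pos].mean(axis=1)).ravel()
    return ge, np.log2(1.0 + ge)


def diff_mean(expr_T: np.ndarray | float, expr_C: np.ndarray | float):
    """Log2 fold-change of per-set mean expression, on the pseudocount scale.

    Defined as ``log2(1+GE_T) - log2(1+GE_C)``; identical to the ratio of raw
    means for well-expressed genes and finite when the contrast mean is 0.
    """
    return np.asarray(expr_T) - np.asarray(expr_C) if np.ndim(expr_T) else expr_T - expr_C


def detection_fraction(
    ds: ExpressionDataset, cell_ids: Sequence[str], threshold: float = 1.0
) -> np.ndarray:
    """Fraction of the set's cells with CPM >= ``threshold``, per gene."""
    if len(cell_ids) == 0:
        raise ValueError("cell set is empty")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    pos = ds.cell_positions(cell_ids)
    sub = ds.matrix[:, pos]
    if threshold == 0:
        return np.ones(ds.n_genes)
    detected = sub >= threshold
    return np.asarray(detected.sum(axis=1)).ravel() / len(pos)


def beta_statistic(pct_T, pct_C, diff_mean_value):
    """Signed detection-fraction separation: ``sign(diff) * |pct_T - pct_C|``.

    The sign is taken from the fold-change so a gene *depleted* in the target
    set gets a negative Beta; ``sign(0)`` is 0 by convention.
    """
    return np.sign(diff_mean_value) * np.abs(np.asarray(pct_T) - np.asarray(pct_C))


def _exact_possible(x: np.ndarray, y: np.ndarray) -> bool:
    combined = np.concatenate([x, y])
    return len(np.unique(combined)) == len(combined)


def wilcoxon_de(
    ds: ExpressionDataset,
    comparison: ComparisonDefinition,
    exact_limit: int = 8,
    force_asymptotic: bool = False,
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per gene on per-cell expression.

    The test is rank-based, so raw CPM and log2(1+CPM) give identical
    p-values; raw CPM is used.  When the smaller set has at most
    ``exact_limit`` cells and the gene's values are all distinct the exact
    null distribution is enumerated; otherwise the normal approximation with
    midranks, tie-corrected variance and continuity correction is used.
    Genes constant across both sets get p = 1 without computing a degenerate
    statistic.
    """
    if len(comparison.set_T) < 2 or len(comparison.set_C) < 2:
        raise ValueError("both cell sets must contain at least 2 cells")
    xt = ds.dense_submatrix(comparison.set_T)
    xc = ds.dense_submatrix(comparison.set_C)
    n_min = min(xt.shape[1], xc.shape[1])

    constant = (xt.min(axis=1) == xt.max(axis=1)) & (
        xc.min(axis=1) == xc.max(axis=1)
    ) & (xt[:, 0] == xc[:, 0])
    p = np.ones(ds.n_genes)
    todo = ~constant
    if not todo.any():
        return p
    if n_min <= exact_limit and not force_asymptotic:
        for g in np.flatnonzero(todo):
            method = "exact" if _exact_possible(xt[g], xc[g]) else "asymptotic"
            res = scipy.stats.mannwhitneyu(
                xt[g], xc[g], alternative="two-sided", method=method
            )
            p[g] = res.pvalue
    else:
        res = scipy.stats.mannwhitneyu(
            xt[todo], xc[todo], alternative="two-sided", method="asymptotic", axis=1
        )
        p[todo] = res.pvalue
    return np.minimum(p, 1.0)


def bonferroni(p_raw: np.ndarray | float, m: int):
    """Bonferroni correction: ``min(1, m * p)``."""
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * m)


def screen_comparison(
    ds: ExpressionDataset,
    comparison: ComparisonDefinition,
    alpha: float = 0.05,
    fold_min: float = 3.0,
    tenfold: float = 10.0,
    bonferroni_m: int | None = None,
    detection_threshold: float = 1.0,
) -> pd.DataFrame:
    """Compute all four screen measures for every gene in one comparison.

    Returns a DataFrame with one row per gene and columns ``comparison, gene,
    ge_T, ge_C, expr_T, expr_C, diff_mean, pct_T, pct_C, beta, p_raw, p_bonf,
    passes_primary, tenfold_flag``.

    ``passes_primary`` requires (a) Bonferroni-corrected p < ``alpha``,
    (b) positive fold-change, and (c) ``(1+GE_T)/(1+GE_C) >= fold_min``
    (the at-least-threefold criterion, log2(3) ~ 1.58, on the pseudocounted
    means).  ``tenfold_flag`` is the same ratio criterion at factor
    ``tenfold``.  ``bonferroni_m`` defaults to the number of genes tested.
    """
    ge_t, expr_t = set_mean_expression(ds, comparison.set_T)
    ge_c, expr_c = set_mean_expression(ds, comparison.set_C)
    dm = expr_t - expr_c
    pct_t = detection_fraction(ds, comparison.set_T, detection_threshold)
    pct_c = detection_fraction(ds, comparison.set_C, detection_threshold)
    beta = beta_statistic(pct_t, pct_c, dm)
    p_raw = wilcoxon_de(ds, comparison)
    m = bonferroni_m if bonferroni_m is not None else ds.n_genes
    p_bonf = bonferroni(p_raw, m)
    ratio = (1.0 + ge_t) / (1.0 + ge_c)
    passes = (p_bonf < alpha) & (dm > 0) & (ratio >= fold_min)
    ten = (p_bonf < alpha) & (dm > 0) & (ratio >= tenfold)
    return pd.DataFrame(
        {
            "comparison": comparison.name,
            "gene": ds.gene_ids,
            "ge_T": ge_t,
            "ge_C": ge_c,
            "expr_T": expr_t,
            "expr_C": expr_c,
            "diff_mean": dm,
            "pct_T": pct_t,
            "pct_C": pct_c,
            "beta": beta,
            "p_raw": p_raw,
            "p_bonf": p_bonf,
            "passes_primary": passes,
            "tenfold_flag": ten,
        }
    )


def rank_candidates(
    records: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    coupling_filter: str = "Gi",
    require_all: Iterable[str] | None = None,
    exclude_sensory: bool = False,
) -> pd.DataFrame:
    """Rank GPCR genes that pass the primary criteria in every required comparison.

    Keeps genes annotated ``is_gpcr`` (optionally excluding sensory GPCRs)
    whose coupling matches ``coupling_filter`` (``"any"`` disables the filter)
    and that pass in each comparison named in ``require_all`` (default: every
    comparison present in ``records``).  The candidate table carries, per
    gene, the worst-case strength over the required comparisons — minimum
    fold-change, minimum Beta, maximum contrast-set expression — and is sorted
    by descending minimum fold-change, descending minimum Beta, ascending
    maximum contrast expression, gene symbol.
    """
    present = list(pd.unique(records["comparison"]))
    required = list(require_all) if require_all is not None else present
    unknown = [c for c in required if c not in present]
    if unknown:
        raise ValueError(f"comparisons not present in records: {unknown}")

    sub = records[records["comparison"].isin(required)]
    counts = sub.groupby("gene")["passes_primary"].agg(["sum", "count"])
    passers = counts.index[
        (counts["sum"] == len(required)) & (counts["count"] == len(required))
    ]
    annotated = passers[pd.Index(passers).isin(gene_annotation.index)]
    annot = gene_annotation.loc[annotated]
    keep = annot["is_gpcr"].astype(bool)
    if exclude_sensory:
        keep &= ~annot["is_sensory"].astype(bool)
    if coupling_filter != "any":
        keep &= annot["coupling"] == coupling_filter
    genes = annot.index[keep]
    if len(genes) == 0:
        return pd.DataFrame(
            columns=[
                "gene",
                "coupling",
                "n_comparisons_passed",
                "min_diff_mean",
                "min_beta",
                "max_expr_C",
                "tenfold_in_all",
                "rank",
            ]
        )
    sub = sub[sub["gene"].isin(genes)]
    agg = sub.groupby("gene").agg(
        min_diff_mean=("diff_mean", "min"),
        min_beta=("beta", "min"),
        max_expr_C=("expr_C", "max"),
        tenfold_in_all=("tenfold_flag", "all"),
        n_comparisons_passed=("passes_primary", "sum"),
    )
    agg["coupling"] = gene_annotation.loc[agg.index, "coupling"]
    agg = agg.reset_index().sort_values(
        ["min_diff_mean", "min_beta", "max_expr_C", "gene"],
        ascending=[False, False, True, True],
        kind="stable",
    )
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg[
        [
            "gene",
            "coupling",
            "n_comparisons_passed",
            "min_diff_mean",
            "min_beta",
            "max_expr_C",
            "tenfold_in_all",
            "rank",
        ]
    ].reset_index(drop=True)
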