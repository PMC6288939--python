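"""Per-exon differential-expression model for the 2x2 sex-by-treatment design.

The model fits each detected exonic region's ln-RPKM values as four cell
means and tests the four pairwise contrasts (two within-sex, two
between-sex).  Because the sexes can differ in expression variance, each
contrast is a Welch unequal-variance two-sample comparison with
Welch-Satterthwaite degrees of freedom — the one-way specialisation of
small-sample-adjusted (Kenward-Roger-style) F-tests, to which it is
equivalent here since every contrast has one numerator degree of freedom
(F = t^2).  P-values are Benjamini-Hochberg adjusted within each contrast
family; significance is flagged at FDR 0.0001, 0.01 and 0.05, and a
two-fold-change flag (|ln-fold change| >= ln 2) is carried alongside.

Usage follows the model/results convention::

    model = ExonDEModel(expression_matrix)
    results = model.fit()
    results.summary()
    landscape = results.landscape_summary(fdr=0.01)
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import landscape as _landscape
from .design import CONTRASTS, ContrastSpec
from .quantify import ExpressionMatrix

DEFAULT_FDR_LEVELS: tuple[float, ...] = (0.0001, 0.01, 0.05)


def welch_contrast(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch two-sample contrast, rows = regions.

    Returns ``(estimate, statistic, df, p, degenerate)`` where the estimate
    is ``mean(a) - mean(b)`` (the ln-fold change when inputs are ln-RPKM),
    the statistic is Welch's t, and df is Welch-Satterthwaite.  Rows where
    both groups are constant are degenerate: p = 1 if the constants agree,
    p = 0 (flagged) if they differ.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates")

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    est = mean_a - mean_b

    se2 = var_a / na + var_b / nb
    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = est / np.sqrt(se2)
        df = se2**2 / (
            (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
        )
    df = np.where(zero, float(na + nb - 2), df)
    with np.errstate(invalid="ignore"):
        stat = np.where(zero, np.where(est == 0, 0.0, np.sign(est) * np.inf), stat)
    p = 2.0 * stats.t.sf(np.abs(stat), df)
    degenerate = zero & (est != 0)
    p = np.where(zero, np.where(est == 0, 1.0, 0.0), p)
    return est, stat, df, p, degenerate


def _residual_variance(cells: list[np.ndarray]) -> tuple[np.ndarray, int]:
    """Pooled residual variance across design cells (rows = regions).

    Each cell is centred at its own mean; the pooled estimate has
    ``sum(n_c) - n_cells`` degrees of freedom.
    """
    ss = np.zeros(cells[0].shape[0])
    n_total = 0
    for cell in cells:
        ss += ((cell - cell.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        n_total += cell.shape[1]
    df = n_total - len(cells)
    return ss / df, df


def stratified_contrast(
    a: np.ndarray,
    b: np.ndarray,
    a_stratum: list[np.ndarray],
    b_stratum: list[np.ndarray],
    same_stratum: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-cell contrast with variances pooled within variance strata.

    The model assumes a common error variance within each stratum (here: a
    sex), estimated from all of the stratum's cells.  When both cells share
    a stratum this is the classic pooled two-sample t restricted to the
    stratum; across strata the two independent pooled variances combine via
    Welch-Satterthwaite degrees of freedom — the one-way analogue of a
    small-sample-adjusted contrast in a linear model with sex-specific
    residual variance.  Returns ``(estimate, t, df, p, degenerate)``.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates")
    est = a.mean(axis=1) - b.mean(axis=1)

    va, dfa = _residual_variance(a_stratum)
    if same_stratum:
        se2 = va * (1.0 / na + 1.0 / nb)
        df = np.full(a.shape[0], float(dfa))
    else:
        vb, dfb = _residual_variance(b_stratum)
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((va / na) ** 2 / dfa + (vb / nb) ** 2 / dfb)
        df = np.where(se2 == 0, float(dfa + dfb), df)

    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = est / np.sqrt(se2)
        stat = np.where(zero, np.where(est == 0, 0.0, np.sign(est) * np.inf), stat)
    p = 2.0 * stats.t.sf(np.abs(stat), df)
    degenerate = zero & (est != 0)
    p = np.where(zero, np.where(est == 0, 1.0, 0.0), p)
    return est, stat, df, p, degenerate


def adjust_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sig_col(level: float) -> str:
    return f"sig_{level:g}"


class ExonDEModel:
    """Pairwise-contrast differential expression over detected exonic regions.

    Parameters
    ----------
    expr
        Quantified :class:`~exonde.quantify.ExpressionMatrix`; only detected
        regions enter the fit.
    """

    def __init__(self, expr: ExpressionMatrix):
        self.expr = expr
        self.design = expr.design
        self.contrasts: tuple[ContrastSpec, ...] = CONTRASTS

    def fit(
        self,
        fdr_levels: Sequence[float] = DEFAULT_FDR_LEVELS,
        fold_threshold: float = 2.0,
        pool_fdr: bool = False,
        variance: str = "by_sex",
    ) -> "ExonDEResults":
        """Run all four contrasts for every detected region.

        ``variance="by_sex"`` (default) pools residual variance within each
        sex across treatments (the linear-model view with sex-specific error
        variance, small-sample df by Welch-Satterthwaite across sexes);
        ``"by_cell"`` uses the plain per-cell Welch test instead.
        ``pool_fdr=False`` (default) adjusts p-values within each contrast
        family separately; ``True`` pools all contrasts into one family.
        """
        fdr_levels = tuple(sorted(float(f) for f in fdr_levels))
        if any(f <= 0 or f >= 1 for f in fdr_levels):
            raise ValueError("FDR levels must lie in (0, 1)")
        if fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if variance not in ("by_sex", "by_cell"):
            raise ValueError("variance must be 'by_sex' or 'by_cell'")
        expr = self.expr.ln_rpkm
        ln_thresh = math.log(fold_threshold)

        from .design import TREATMENTS

        def sex_cells(sex: str) -> list[np.ndarray]:
            return [
                expr[self.design.group_samples((sex, t))].to_numpy()
                for t in TREATMENTS
            ]

        frames = []
        for spec in self.contrasts:
            cols_a = self.design.group_samples(spec.group_a)
            cols_b = self.design.group_samples(spec.group_b)
            if variance == "by_cell":
                est, stat, df, p, degen = welch_contrast(
                    expr[cols_a].to_numpy(), expr[cols_b].to_numpy()
                )
            else:
                est, stat, df, p, degen = stratified_contrast(
                    expr[cols_a].to_numpy(),
                    expr[cols_b].to_numpy(),
                    sex_cells(spec.group_a[0]),
                    sex_cells(spec.group_b[0]),
                    same_stratum=spec.group_a[0] == spec.group_b[0],
                )
            frames.append(
                pd.DataFrame(
                    {
                        "region_id": expr.index,
                        "contrast": spec.name,
                        "ln_fc": est,
                        "statistic": stat,
                        "df": df,
                        "p": p,
                        "degenerate": degen,
                        "twofold": np.abs(est) >= ln_thresh,
                    }
                )
            )
        table = pd.concat(frames, ignore_index=True)

        if pool_fdr:
            table["p_adj"] = adjust_fdr(table["p"].to_numpy())
        else:
            table["p_adj"] = np.nan
            for spec in self.contrasts:
                mask = table["contrast"] == spec.name
                table.loc[mask, "p_adj"] = adjust_fdr(table.loc[mask, "p"].to_numpy())
        for level in fdr_levels:
            table[_sig_col(level)] = table["p_adj"] < level

        meta = self.expr.region_meta
        table.insert(1, "gene_id", meta.loc[table["region_id"], "gene_id"].to_numpy())
        return ExonDEResults(self, table, fdr_levels, fold_threshold)


class ExonDEResults:
    """Results of :meth:`ExonDEModel.fit`.

    ``table`` is tidy: one row per region x contrast with the ln-fold
    change, Welch statistic, Satterthwaite df, raw and BH-adjusted
    p-values, significance flags per FDR level and the two-fold flag.
    """

    def __init__(
        self,
        model: ExonDEModel,
        table: pd.DataFrame,
        fdr_levels: tuple[float, ...],
        fold_threshold: float,
    ):
        self.model = model
        self.table = table
        self.fdr_levels = fdr_levels
        self.fold_threshold = fold_threshold

    # -- access helpers ---------------------------------------------------

    def contrast(self, name: str) -> pd.DataFrame:
        """One contrast's results, indexed by region."""
        sub = self.table[self.table["contrast"] == name]
        if sub.empty:
            raise KeyError(f"no such contrast: {name!r}")
        return sub.set_index("region_id")

    def to_wide(self) -> pd.DataFrame:
        """One row per region, a column block per contrast."""
        blocks = []
        for spec in self.model.contrasts:
            sub = self.contrast(spec.name).drop(columns=["contrast", "gene_id"])
            sub.columns = [f"{spec.name}.{c}" for c in sub.columns]
            blocks.append(sub)
        wide = pd.concat(blocks, axis=1)
        wide.insert(
            0, "gene_id", self.model.expr.region_meta.loc[wide.index, "gene_id"]
        )
        return wide

    @property
    def n_tested_regions(self) -> int:
        return self.table["region_id"].nunique()

    @property
    def tested_genes(self) -> list[str]:
        return sorted(self.table["gene_id"].unique())

    # -- summaries --------------------------------------------------------

    def summary(self, fdr: float | None = None) -> pd.DataFrame:
        """Per-contrast counts of tested and significant regions.

        One row per contrast with the number tested, the number significant
        at each FDR level, and the number both significant (headline level)
        and two-fold changed.
        """
        headline = self._check_fdr(fdr)
        rows = []
        for spec in self.model.contrasts:
            sub = self.contrast(spec.name)
            row = {"contrast": spec.name, "kind": spec.kind, "n_tested": len(sub)}
            for level in self.fdr_levels:
                row[f"n_sig_fdr{level:g}"] = int(sub[_sig_col(level)].sum())
            row["n_sig_twofold"] = int(
                (sub[_sig_col(headline)] & sub["twofold"]).sum()
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def _check_fdr(self, fdr: float | None) -> float:
        if fdr is None:
            return 0.01 if 0.01 in self.fdr_levels else self.fdr_levels[0]
        fdr = float(fdr)
        if fdr not in self.fdr_levels:
            raise ValueError(f"fdr {fdr} not among fitted levels {self.fdr_levels}")
        return fdr

    # -- landscape classification -----------------------------------------

    def classify_between_sex(self, fdr: float | None = None) -> pd.DataFrame:
        """Per-region sex-bias landscape labels at the given FDR level."""
        fdr = self._check_fdr(fdr)
        ctrl = self.contrast("F_ctrl_vs_M_ctrl")
        pert = self.contrast("F_pert_vs_M_pert").loc[ctrl.index]
        labels = _landscape.classify_between_sex(
            ctrl["ln_fc"].to_numpy(),
            ctrl[_sig_col(fdr)].to_numpy(),
            pert["ln_fc"].to_numpy(),
            pert[_sig_col(fdr)].to_numpy(),
        )
        twofold = (ctrl[_sig_col(fdr)] & ctrl["twofold"]) | (
            pert[_sig_col(fdr)] & pert["twofold"]
        )
        return pd.DataFrame(
            {
                "gene_id": self.model.expr.region_meta.loc[ctrl.index, "gene_id"],
                "label": labels,
                "twofold": twofold.to_numpy(),
            },
            index=ctrl.index,
        )

    def classify_within_sex(self, fdr: float | None = None) -> pd.DataFrame:
        """Per-region within-sex response labels at the given FDR level."""
        fdr = self._check_fdr(fdr)
        male = self.contrast("M_ctrl_vs_M_pert")
        female = self.contrast("F_ctrl_vs_F_pert").loc[male.index]
        labels = _landscape.classify_within_sex(
            male["ln_fc"].to_numpy(),
            male[_sig_col(fdr)].to_numpy(),
            female["ln_fc"].to_numpy(),
            female[_sig_col(fdr)].to_numpy(),
        )
        twofold = (male[_sig_col(fdr)] & male["twofold"]) | (
            female[_sig_col(fdr)] & female["twofold"]
        )
        return pd.DataFrame(
            {
                "gene_id": self.model.expr.region_meta.loc[male.index, "gene_id"],
                "label": labels,
                "twofold": twofold.to_numpy(),
            },
            index=male.index,
        )

    def _rollup(self, classified: pd.DataFrame, null_label: str):
        assignments = _landscape.rollup_gene(
            classified["label"], classified["gene_id"], null_label=null_label
        )
        twofold_genes = set(
            classified.loc[classified["twofold"], "gene_id"].unique()
        )
        return assignments, twofold_genes

    def landscape_summary(self, fdr: float | None = None) -> pd.DataFrame:
        """Gene-level between-sex landscape table (counts and percentages)."""
        classified = self.classify_between_sex(fdr)
        assignments, twofold_genes = self._rollup(classified, "unbiased")
        return _landscape.tabulate_landscape(
            assignments, n_tested_genes=len(self.tested_genes),
            twofold_genes=twofold_genes,
        )

    def within_sex_summary(self, fdr: float | None = None) -> pd.DataFrame:
        """Gene-level within-sex response table (counts and percentages)."""
        classified = self.classify_within_sex(fdr)
        assignments, twofold_genes = self._rollup(classified, "null")
        within_labels = tuple(l for l in _landscape.WITHIN_LABELS if l != "null")
        return _landscape.tabulate_landscape(
            assignments,
            n_tested_genes=len(self.tested_genes),
            twofold_genes=twofold_genes,
            labels=within_labels,
            priority=within_labels,
        )

    def gene_assignments(
        self, which: str = "between", fdr: float | None = None
    ) -> pd.DataFrame:
        """Gene-level label sets as a tidy table (gene, label, n_exons)."""
        if which == "between":
            classified = self.classify_between_sex(fdr)
            null_label = "unbiased"
        elif which == "within":
            classified = self.classify_within_sex(fdr)
            null_label = "null"
        else:
            raise ValueError("which must be 'between' or 'within'")
        assignments, _ = self._rollup(classified, null_label)
        rows = [
            {"gene_id": g, "label": lab, "n_exons": n}
            for g, a in assignments.items()
            for lab, n in sorted(a.n_exons_per_label.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "label", "n_exons"])

    def de_genes(
        self, contrast: str, fdr: float | None = None, twofold_only: bool = False
    ) -> list[str]:
        """Genes with >= 1 significant exon in a contrast (for enrichment)."""
        fdr = self._check_fdr(fdr)
        sub = self.contrast(contrast)
        mask = sub[_sig_col(fdr)]
        if twofold_only:
            mask &= sub["twofold"]
        genes = self.model.expr.region_meta.loc[sub.index[mask], "gene_id"]
        return sorted(genes.unique())

    # -- plotting ----------------------------------------------------------

    def fold_change_table(
        self, which: str = "within", fdr: float | None = None
    ) -> pd.DataFrame:
        """Scatter data for the paired fold-change comparison plots.

        ``which="within"``: x = male response, y = female response (both
        control minus perturbed).  ``which="between"``: x = perturbed F-M,
        y = control F-M.  One row per region with its landscape label.
        """
        if which == "within":
            x = self.contrast("M_ctrl_vs_M_pert")
            y = self.contrast("F_ctrl_vs_F_pert")
            labels = self.classify_within_sex(fdr)["label"]
        elif which == "between":
            x = self.contrast("F_pert_vs_M_pert")
            y = self.contrast("F_ctrl_vs_M_ctrl")
            labels = self.classify_between_sex(fdr)["label"]
        else:
            raise ValueError("which must be 'within' or 'between'")
        return _landscape.fold_change_table(x, y.loc[x.index], labels)

    def plot_fold_change(self, which: str = "within", fdr: float | None = None):
        """Scatter of paired ln-fold changes with marginal histograms."""
        from .plotting import fold_change_scatter

        return fold_change_scatter(self.fold_change_table(which, fdr), which)
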