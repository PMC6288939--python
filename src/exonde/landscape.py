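"""Classify exons and genes into sex-bias and within-sex response categories.

The "landscape of sex-differential expression" is a 9-cell classification
of each exon (and, by rollup, each gene) by its bias status in the two
between-sex comparisons: control F-vs-M and perturbed F-vs-M.  A region is
F-biased in a condition if the F-M contrast is significant with a positive
ln-fold change, M-biased if significant and negative, otherwise NS.  The
status pair maps bijectively to one of nine labels: bias can be maintained,
gained, lost or reversed in either direction, or absent (unbiased).

The analogous within-sex classification crosses the male and female
responses to the perturbation (up / down / NS per sex), giving nine cells:
concordant responses, opposing responses, single-sex responses, or null.

A gene is considered differentially expressed if at least one of its exons
is, so gene-level assignment is the set of non-null labels supported by
>= 1 exon; multi-exon genes may carry several labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

#: between-sex status pair (control, perturbed) -> landscape label
BETWEEN_SEX_LABELS: dict[tuple[str, str], str] = {
    ("NS", "NS"): "unbiased",
    ("F_biased", "F_biased"): "maintained_F",
    ("M_biased", "M_biased"): "maintained_M",
    ("NS", "F_biased"): "gained_F",
    ("NS", "M_biased"): "gained_M",
    ("F_biased", "NS"): "lost_F",
    ("M_biased", "NS"): "lost_M",
    ("F_biased", "M_biased"): "reversed_F_to_M",
    ("M_biased", "F_biased"): "reversed_M_to_F",
}

BIAS_LABELS: tuple[str, ...] = tuple(BETWEEN_SEX_LABELS.values())
NON_NULL_BIAS_LABELS: tuple[str, ...] = tuple(
    lab for lab in BIAS_LABELS if lab != "unbiased"
)

#: resolution priority for genes supported in several categories
BIAS_PRIORITY: tuple[str, ...] = (
    "maintained_F",
    "maintained_M",
    "reversed_F_to_M",
    "reversed_M_to_F",
    "gained_F",
    "gained_M",
    "lost_F",
    "lost_M",
)

#: within-sex status pair (male, female) -> label; "up" = higher under perturbation
WITHIN_SEX_LABELS: dict[tuple[str, str], str] = {
    ("NS", "NS"): "null",
    ("up", "up"): "both_up",
    ("down", "down"): "both_down",
    ("up", "down"): "opposing_MupFdown",
    ("down", "up"): "opposing_MdownFup",
    ("up", "NS"): "male_only_up",
    ("down", "NS"): "male_only_down",
    ("NS", "up"): "female_only_up",
    ("NS", "down"): "female_only_down",
}

WITHIN_LABELS: tuple[str, ...] = tuple(WITHIN_SEX_LABELS.values())


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _bias_status(ln_fc: np.ndarray, significant: np.ndarray) -> np.ndarray:
    """F_biased / M_biased / NS from an F-minus-M ln-fold change and a sig flag.

    An exactly-zero ln-fold change is mapped to NS even if flagged significant
    (defensive; cannot occur with continuous data).
    """
    status = np.full(len(ln_fc), "NS", dtype=object)
    status[np.asarray(significant, bool) & (ln_fc > 0)] = "F_biased"
    status[np.asarray(significant, bool) & (ln_fc < 0)] = "M_biased"
    return status


def classify_between_sex(
    ctrl_ln_fc: np.ndarray,
    ctrl_sig: np.ndarray,
    pert_ln_fc: np.ndarray,
    pert_sig: np.ndarray,
) -> np.ndarray:
    """Landscape labels from the two between-sex contrasts (F minus M)."""
    ctrl = _bias_status(np.asarray(ctrl_ln_fc, float), ctrl_sig)
    pert = _bias_status(np.asarray(pert_ln_fc, float), pert_sig)
    return np.array(
        [BETWEEN_SEX_LABELS[(c, p)] for c, p in zip(ctrl, pert)], dtype=object
    )


def _response_status(ln_fc_ctrl_minus_pert: np.ndarray, significant: np.ndarray) -> np.ndarray:
    # contrasts are control - perturbed, so "up under perturbation" is ln_fc < 0
    status = np.full(len(ln_fc_ctrl_minus_pert), "NS", dtype=object)
    sig = np.asarray(significant, bool)
    status[sig & (ln_fc_ctrl_minus_pert < 0)] = "up"
    status[sig & (ln_fc_ctrl_minus_pert > 0)] = "down"
    return status


def classify_within_sex(
    male_ln_fc: np.ndarray,
    male_sig: np.ndarray,
    female_ln_fc: np.ndarray,
    female_sig: np.ndarray,
) -> np.ndarray:
    """Within-sex response labels from the two control-minus-perturbed contrasts."""
    male = _response_status(np.asarray(male_ln_fc, float), male_sig)
    female = _response_status(np.asarray(female_ln_fc, float), female_sig)
    return np.array(
        [WITHIN_SEX_LABELS[(m, f)] for m, f in zip(male, female)], dtype=object
    )


@dataclass
class GeneCategoryAssignment:
    gene_id: str
    categories: frozenset[str]
    n_exons_per_label: dict[str, int]


def rollup_gene(
    exon_labels: pd.Series,
    gene_ids: pd.Series,
    null_label: str = "unbiased",
) -> dict[str, GeneCategoryAssignment]:
    """Gene-level category sets: every non-null label supported by >= 1 exon."""
    df = pd.DataFrame({"gene_id": gene_ids.values, "label": exon_labels.values})
    out: dict[str, GeneCategoryAssignment] = {}
    for gene_id, sub in df.groupby("gene_id", sort=True):
        counts = sub[sub["label"] != null_label]["label"].value_counts().to_dict()
        out[str(gene_id)] = GeneCategoryAssignment(
            gene_id=str(gene_id),
            categories=frozenset(counts),
            n_exons_per_label={str(k): int(v) for k, v in counts.items()},
        )
    return out


def resolve_priority(categories: frozenset[str], priority: tuple[str, ...]) -> str | None:
    for label in priority:
        if label in categories:
            return label
    return None


def tabulate_landscape(
    assignments: dict[str, GeneCategoryAssignment],
    n_tested_genes: int,
    twofold_genes: set[str] | None = None,
    labels: tuple[str, ...] = NON_NULL_BIAS_LABELS,
    priority: tuple[str, ...] = BIAS_PRIORITY,
) -> pd.DataFrame:
    """Summary table of gene counts and percentages per landscape category.

    One row per label plus a ``significant_union`` row for genes carrying any
    non-null label.  ``n_genes`` counts a gene in every category it supports
    (multi-assignment); ``n_genes_resolved`` counts each gene once, in its
    highest-priority category.  Percentages are of tested genes and of
    significant genes, rounded half-up to one decimal.  ``n_twofold`` counts
    genes (per row) that also show a two-fold change in >= 1 exon.
    """
    significant = {g: a for g, a in assignments.items() if a.categories}
    n_sig = len(significant)
    if n_tested_genes < n_sig:
        raise ValueError(
            f"n_tested_genes ({n_tested_genes}) < significant gene count ({n_sig})"
        )
    twofold_genes = twofold_genes or set()

    rows = []
    for label in labels:
        genes = {g for g, a in significant.items() if label in a.categories}
        resolved = {
            g
            for g, a in significant.items()
            if resolve_priority(a.categories, priority) == label
        }
        rows.append(
            {
                "category": label,
                "n_genes": len(genes),
                "n_genes_resolved": len(resolved),
                "pct_of_tested": percent(len(genes), n_tested_genes),
                "pct_of_significant": percent(len(genes), n_sig),
                "n_twofold": len(genes & twofold_genes),
            }
        )
    n_sig_twofold = len(set(significant) & twofold_genes)
    rows.append(
        {
            "category": "significant_union",
            "n_genes": n_sig,
            "n_genes_resolved": n_sig,
            "pct_of_tested": percent(n_sig, n_tested_genes),
            "pct_of_significant": percent(n_sig, n_sig) if n_sig else 0.0,
            "n_twofold": n_sig_twofold,
        }
    )
    return pd.DataFrame(rows)


def fold_change_table(
    contrast_x: pd.DataFrame,
    contrast_y: pd.DataFrame,
    labels: pd.Series,
) -> pd.DataFrame:
    """Tidy scatter data (one row per region) for fold-change comparison plots.

    ``contrast_x``/``contrast_y`` must be indexed by region and carry
    ``ln_fc`` and significance columns; the output feeds the
    scatter-with-marginal-histograms view of paired contrasts.
    """
    df = pd.DataFrame(
        {
            "region_id": contrast_x.index,
            "ln_fc_x": contrast_x["ln_fc"].values,
            "ln_fc_y": contrast_y.loc[contrast_x.index, "ln_fc"].values,
            "label": labels.loc[contrast_x.index].values,
        }
    )
    return df
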