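"""Synthetic per-region counts with planted sex-by-treatment effect structure.

The generator stands in for the study's RNA-seq reads (Illumina 100 bp
single-end head libraries, four biological replicates per sex-by-treatment
cell, two samples later removed for low coverage).  Each exonic region of
each synthetic gene gets a baseline expression on the ln-RPKM scale plus
additive group effects encoding one of the nine sex-bias landscape
categories; counts are drawn from a negative binomial whose dispersion may
differ between the sexes, planting the variance heterogeneity that the
analysis must be robust to.  Base coverage is counts times read length, so
the quantification stage recovers the intended APN and ln-RPKM.

Group-mean parameterisation (ln-RPKM scale), with male-control as reference::

    mu(M, control)   = baseline
    mu(F, control)   = baseline + effect_sex_control
    mu(M, perturbed) = baseline - effect_treatment_M
    mu(F, perturbed) = baseline - effect_treatment_M + effect_sex_perturbed

Sex effects are F minus M; treatment effects are control minus perturbed,
matching the sign convention of the four contrasts.  The four effects obey
``effect_treatment_F = effect_sex_control - effect_sex_perturbed +
effect_treatment_M`` (only three are free once the baseline is fixed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import SampleDesign
from .landscape import BIAS_LABELS

#: (sign of control sex effect, sign of perturbed sex effect) per category
_CATEGORY_SIGNS: dict[str, tuple[int, int]] = {
    "unbiased": (0, 0),
    "maintained_F": (1, 1),
    "maintained_M": (-1, -1),
    "gained_F": (0, 1),
    "gained_M": (0, -1),
    "lost_F": (1, 0),
    "lost_M": (-1, 0),
    "reversed_F_to_M": (1, -1),
    "reversed_M_to_F": (-1, 1),
}

#: landscape-category gene proportions patterned on the study's reported
#: gene counts (255 maintained-F, 1666 gained-F, 87 maintained-M, 1025
#: gained-M, 95 lost-F, 127 lost-M, 32 reversed, of 8405 tested genes)
STUDY_CATEGORY_COUNTS: dict[str, int] = {
    "unbiased": 5118,
    "maintained_F": 255,
    "maintained_M": 87,
    "gained_F": 1666,
    "gained_M": 1025,
    "lost_F": 95,
    "lost_M": 127,
    "reversed_F_to_M": 16,
    "reversed_M_to_F": 16,
}

_TOTAL = sum(STUDY_CATEGORY_COUNTS.values())
STUDY_CATEGORY_PROPORTIONS: dict[str, float] = {
    k: v / _TOTAL for k, v in STUDY_CATEGORY_COUNTS.items()
}


@dataclass
class ScenarioConfig:
    """Parameters of one simulation scenario.

    Defaults describe the study-like scenario: 1000 genes of 1-6 exonic
    regions, category proportions echoing the reported landscape, sex
    effects of ln 4, and sex-specific negative-binomial dispersions
    (females 0.05, males 0.3) planting variance heterogeneity.
    """

    n_genes: int = 1000
    exons_per_gene: tuple[int, int] = (1, 6)
    length_range: tuple[int, int] = (200, 1200)  # bp
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(STUDY_CATEGORY_PROPORTIONS)
    )
    effect_size: float = math.log(4.0)  # ln-fold sex effect for biased categories
    treatment_effect: float = math.log(4.0)  # ln-fold male response magnitude
    prop_treatment_responsive: float = 0.3  # genes with a planted male response
    baseline_mean: float = 5.0  # mean ln-RPKM
    baseline_sd: float = 1.0
    dispersion_F: float = 0.05  # NB dispersion alpha: var = mu + alpha mu^2
    dispersion_M: float = 0.3
    read_length: int = 100  # bp, single-end

    def __post_init__(self) -> None:
        unknown = set(self.category_proportions) - set(BIAS_LABELS)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        total = sum(self.category_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError(f"category proportions sum to {total}, expected 1")
        if self.dispersion_F < 0 or self.dispersion_M < 0:
            raise ValueError("dispersions must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    @classmethod
    def null_scenario(cls, n_genes: int = 2000, **kw) -> "ScenarioConfig":
        """All effects zero; used for type-I-error calibration.

        Keeps the sex-specific dispersions (0.05 vs 0.3) so the null is
        heteroscedastic, and one region per gene so ``n_genes`` is the
        number of regions.
        """
        props = {k: 0.0 for k in BIAS_LABELS}
        props["unbiased"] = 1.0
        kw.setdefault("exons_per_gene", (1, 1))
        kw.setdefault("prop_treatment_responsive", 0.0)
        return cls(n_genes=n_genes, category_proportions=props, effect_size=0.0, **kw)

    @classmethod
    def planted_scenario(cls, n_genes: int = 1000, **kw) -> "ScenarioConfig":
        """Strong planted effects (ln 4) at homoscedastic dispersion 0.05."""
        kw.setdefault("dispersion_M", 0.05)
        kw.setdefault("dispersion_F", 0.05)
        return cls(n_genes=n_genes, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("exons_per_gene", "length_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def plan_truth(config: ScenarioConfig, seed: int) -> pd.DataFrame:
    """Draw the per-region ground truth for a scenario.

    Returns a DataFrame indexed by ``region_id`` with the gene, length,
    baseline ln-RPKM, the four group effects, per-sex dispersions and the
    planted landscape category.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    labels = list(config.category_proportions)
    probs = np.array([config.category_proportions[k] for k in labels])

    width = max(4, len(str(config.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    gene_cats = rng.choice(labels, size=config.n_genes, p=probs)
    responsive = rng.random(config.n_genes) < config.prop_treatment_responsive
    response_sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    n_exons = rng.integers(
        config.exons_per_gene[0], config.exons_per_gene[1] + 1, size=config.n_genes
    )

    rows = []
    for g, gene_id in enumerate(gene_ids):
        cat = str(gene_cats[g])
        sign_ctrl, sign_pert = _CATEGORY_SIGNS[cat]
        esc = sign_ctrl * config.effect_size
        esp = sign_pert * config.effect_size
        etm = (
            float(response_sign[g]) * config.treatment_effect if responsive[g] else 0.0
        )
        etf = esc - esp + etm
        for k in range(int(n_exons[g])):
            rows.append(
                {
                    "region_id": f"{gene_id}:E{k + 1}",
                    "gene_id": gene_id,
                    "length": int(
                        rng.integers(config.length_range[0], config.length_range[1] + 1)
                    ),
                    "baseline_ln_expr": float(
                        rng.normal(config.baseline_mean, config.baseline_sd)
                    ),
                    "effect_sex_control": esc,
                    "effect_sex_perturbed": esp,
                    "effect_treatment_F": etf,
                    "effect_treatment_M": etm,
                    "dispersion_F": config.dispersion_F,
                    "dispersion_M": config.dispersion_M,
                    "planted_category": cat,
                }
            )
    return pd.DataFrame(rows).set_index("region_id")


def group_mean_ln_expr(truth: pd.DataFrame) -> pd.DataFrame:
    """The four group means on the ln-RPKM scale, one column per design cell."""
    base = truth["baseline_ln_expr"]
    mu_mc = base
    mu_fc = base + truth["effect_sex_control"]
    mu_mp = base - truth["effect_treatment_M"]
    mu_fp = mu_mp + truth["effect_sex_perturbed"]
    return pd.DataFrame(
        {
            ("F", "control"): mu_fc,
            ("F", "perturbed"): mu_fp,
            ("M", "control"): mu_mc,
            ("M", "perturbed"): mu_mp,
        }
    )


def simulate_counts(
    truth: pd.DataFrame,
    design: SampleDesign,
    seed: int,
    read_length: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw negative-binomial counts and base coverage for every sample.

    The count mean is ``exp(group ln-RPKM) * length_kb * library_megareads``
    so quantification recovers the planted ln-RPKM in expectation; variance
    is ``mu + alpha_sex * mu^2`` (Poisson when the sex's dispersion is 0).
    Coverage is counts times read length.  Deterministic given ``seed``.
    """
    if design.library_size <= 0:
        raise ValueError("library size must be positive")
    rng = np.random.default_rng(seed)
    means = group_mean_ln_expr(truth)
    length_kb = truth["length"].to_numpy(float) / 1000.0
    lib_m = design.library_size / 1e6

    counts = {}
    for sample in design.samples:
        mu = np.exp(means[sample.group].to_numpy(float)) * length_kb * lib_m
        alpha = truth[f"dispersion_{sample.sex}"].to_numpy(float)
        draw = np.empty(len(mu), dtype=np.int64)
        pois = alpha <= 0
        if pois.any():
            draw[pois] = rng.poisson(mu[pois])
        if (~pois).any():
            r = 1.0 / alpha[~pois]
            p = r / (r + mu[~pois])
            draw[~pois] = rng.negative_binomial(r, p)
        counts[sample.sample_id] = draw

    counts_df = pd.DataFrame(counts, index=truth.index)
    coverage_df = counts_df * int(read_length)
    return counts_df, coverage_df


def drop_samples(
    counts: pd.DataFrame,
    coverage: pd.DataFrame,
    design: SampleDesign,
    sample_ids: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, SampleDesign]:
    """Remove samples from matrices and design together.

    Mirrors the study's removal of low-coverage libraries; refuses to leave
    any design cell with fewer than the replicate floor (error names the
    group).
    """
    new_design = design.drop(sample_ids)  # validates the replicate floor
    keep = new_design.sample_ids
    return counts[keep], coverage[keep], new_design


def region_meta(truth: pd.DataFrame) -> pd.DataFrame:
    """Region metadata (gene, length) in the layout quantification expects."""
    return truth[["gene_id", "length"]].copy()
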