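"""APN, the detection filter, and ln-RPKM expression.

Quantification works from two region-by-sample matrices: read counts and
total aligned bases.  Average per-nucleotide coverage (APN) is bases
divided by region length; a region is *detected* when its APN exceeds the
threshold (strictly greater than 5 by default) in at least ``min_reps``
replicates of at least one of the four sex-by-treatment groups.  Detected
regions get a natural-log RPKM expression value; undetected regions are
excluded from every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import GROUPS, SampleDesign


def compute_apn(
    base_coverage: pd.DataFrame | np.ndarray | float,
    region_length: pd.Series | np.ndarray | float,
):
    """Average per-nucleotide coverage: aligned bases / region length (bp)."""
    cov = np.asarray(base_coverage, dtype=float)
    length = np.asarray(region_length, dtype=float)
    if np.any(cov < 0):
        raise ValueError("negative base coverage")
    if np.any(length <= 0):
        raise ValueError("region length must be positive")
    if isinstance(base_coverage, pd.DataFrame):
        return base_coverage.div(pd.Series(length, index=base_coverage.index), axis=0)
    return cov / length


def detection_filter(
    apn: pd.DataFrame,
    design: SampleDesign,
    threshold: float = 5.0,
    min_reps: int = 2,
) -> pd.Series:
    """Detected iff some group has >= ``min_reps`` replicates with APN > threshold.

    The inequality is strict: APN exactly equal to the threshold does not
    count toward detection.
    """
    detected = pd.Series(False, index=apn.index)
    for group in GROUPS:
        cols = design.group_samples(group)
        if not cols:
            continue
        n_above = (apn[cols] > threshold).sum(axis=1)
        detected |= n_above >= min_reps
    return detected


def ln_rpkm(
    count,
    region_length,
    library_size,
    pseudocount: float = 0.5,
):
    """Natural-log RPKM: ln((count + pseudocount) / (length_kb * lib_millions)).

    ``library_size`` is the number of mapped reads in the sample.  The
    pseudocount (default 0.5) keeps zero counts finite; pass 0 to disable.
    """
    count = np.asarray(count, dtype=float)
    length = np.asarray(region_length, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if np.any(length <= 0):
        raise ValueError("region length must be positive")
    if np.any(lib <= 0):
        raise ValueError("library size must be positive")
    return np.log((count + pseudocount) / ((length / 1000.0) * (lib / 1e6)))


@dataclass
class ExpressionMatrix:
    """Per-region expression across samples, with detection flags.

    ``ln_rpkm`` holds detected regions only; ``counts`` and ``apn`` keep
    every input region.  ``region_meta`` is indexed by region_id and carries
    at least ``gene_id`` and ``length`` (bp).
    """

    counts: pd.DataFrame
    apn: pd.DataFrame
    ln_rpkm: pd.DataFrame
    detected: pd.Series
    design: SampleDesign
    region_meta: pd.DataFrame
    library_size: pd.Series

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())

    @property
    def detected_genes(self) -> list[str]:
        """Genes with at least one detected region ("tested genes")."""
        genes = self.region_meta.loc[self.detected[self.detected].index, "gene_id"]
        return sorted(genes.unique())


def build_expression_matrix(
    counts: pd.DataFrame,
    base_coverage: pd.DataFrame,
    region_meta: pd.DataFrame,
    design: SampleDesign,
    apn_threshold: float = 5.0,
    min_reps: int = 2,
    pseudocount: float = 0.5,
    library_size: pd.Series | float | None = None,
) -> ExpressionMatrix:
    """Quantify a count/coverage matrix pair into an :class:`ExpressionMatrix`.

    ``library_size`` defaults to the per-sample total of reads mapped to the
    supplied regions; pass a scalar or per-sample Series to use an external
    total instead.
    """
    if not counts.columns.equals(base_coverage.columns) or not counts.index.equals(
        base_coverage.index
    ):
        raise ValueError("counts and coverage matrices must share index and columns")
    missing = set(design.sample_ids) - set(counts.columns)
    if missing:
        raise ValueError(f"design samples missing from matrix: {sorted(missing)}")
    missing_regions = set(counts.index) - set(region_meta.index)
    if missing_regions:
        raise ValueError(
            f"{len(missing_regions)} regions missing from region metadata"
        )
    counts = counts[design.sample_ids]
    base_coverage = base_coverage[design.sample_ids]
    lengths = region_meta.loc[counts.index, "length"]

    apn = compute_apn(base_coverage, lengths)
    detected = detection_filter(apn, design, threshold=apn_threshold, min_reps=min_reps)

    if library_size is None:
        lib = counts.sum(axis=0).astype(float)
    elif np.isscalar(library_size):
        lib = pd.Series(float(library_size), index=counts.columns)
    else:
        lib = pd.Series(library_size).astype(float)[counts.columns]

    det_idx = detected[detected].index
    expr = pd.DataFrame(
        ln_rpkm(
            counts.loc[det_idx].to_numpy(),
            lengths.loc[det_idx].to_numpy()[:, None],
            lib.to_numpy()[None, :],
            pseudocount=pseudocount,
        ),
        index=det_idx,
        columns=counts.columns,
    )
    return ExpressionMatrix(
        counts=counts,
        apn=apn,
        ln_rpkm=expr,
        detected=detected,
        design=design,
        region_meta=region_meta.loc[counts.index],
        library_size=lib,
    )
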