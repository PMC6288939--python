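"""Sample sheets and the four pairwise contrasts of the 2x2 sex-by-treatment design.

The experiment crosses sex (F/M) with an inducible perturbation
(control / perturbed).  Four pairwise comparisons are made on the cell
means, two "within sex" and two "between sex":

1. ``F_ctrl_vs_F_pert``  — female control minus female perturbed
2. ``M_ctrl_vs_M_pert``  — male control minus male perturbed
3. ``F_ctrl_vs_M_ctrl``  — female minus male, control condition
4. ``F_pert_vs_M_pert``  — female minus male, perturbed condition

The sign convention everywhere is ``estimate = mean(group_a) - mean(group_b)``,
so for the within-sex contrasts a *negative* ln-fold change means the region
is up-regulated under perturbation, and for the between-sex contrasts a
*positive* ln-fold change means female-biased expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

SEXES = ("F", "M")
TREATMENTS = ("control", "perturbed")

#: the four (sex, treatment) cells of the design
GROUPS: tuple[tuple[str, str], ...] = (
    ("F", "control"),
    ("F", "perturbed"),
    ("M", "control"),
    ("M", "perturbed"),
)


@dataclass(frozen=True)
class ContrastSpec:
    """One pairwise comparison between two design cells."""

    name: str
    group_a: tuple[str, str]
    group_b: tuple[str, str]

    @property
    def kind(self) -> str:
        """``within_sex`` (control vs perturbed) or ``between_sex`` (F vs M)."""
        return "within_sex" if self.group_a[0] == self.group_b[0] else "between_sex"


CONTRASTS: tuple[ContrastSpec, ...] = (
    ContrastSpec("F_ctrl_vs_F_pert", ("F", "control"), ("F", "perturbed")),
    ContrastSpec("M_ctrl_vs_M_pert", ("M", "control"), ("M", "perturbed")),
    ContrastSpec("F_ctrl_vs_M_ctrl", ("F", "control"), ("M", "control")),
    ContrastSpec("F_pert_vs_M_pert", ("F", "perturbed"), ("M", "perturbed")),
)

CONTRAST_BY_NAME = {c.name: c for c in CONTRASTS}


@dataclass(frozen=True)
class Sample:
    sample_id: str
    sex: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )

    @property
    def group(self) -> tuple[str, str]:
        return (self.sex, self.treatment)


@dataclass
class SampleDesign:
    """The sample -> (sex, treatment, replicate) map defining the 2x2 design.

    Each of the four cells must keep at least ``min_replicates`` samples
    (the detection filter needs two replicates per group), mirroring the
    study layout of n = 4 biological replicates per cell with optional
    removal of low-coverage samples.
    """

    samples: list[Sample] = field(default_factory=list)
    min_replicates: int = 2
    library_size: float = 5_000_000.0  # reads per sample, for simulation

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in design")
        if self.library_size <= 0:
            raise ValueError(f"library_size must be positive, got {self.library_size}")
        self.validate()

    def validate(self) -> None:
        for group in GROUPS:
            n = len(self.group_samples(group))
            if n < self.min_replicates:
                raise ValueError(
                    f"group {group[0]}-{group[1]} has {n} replicates; "
                    f"at least {self.min_replicates} required"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_samples(self, group: tuple[str, str]) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == group]

    def drop(self, sample_ids: Iterable[str]) -> "SampleDesign":
        """Remove samples, enforcing the per-group replicate floor.

        Raises ``ValueError`` naming the offending group if the removal
        would leave any design cell with fewer than ``min_replicates``.
        """
        drop = set(sample_ids)
        unknown = drop - set(self.sample_ids)
        if unknown:
            raise KeyError(f"unknown sample ids: {sorted(unknown)}")
        kept = [s for s in self.samples if s.sample_id not in drop]
        return SampleDesign(
            kept, min_replicates=self.min_replicates, library_size=self.library_size
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "sex": [s.sex for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, min_replicates: int = 2) -> "SampleDesign":
        required = {"sample_id", "sex", "treatment", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        samples = [
            Sample(str(r.sample_id), str(r.sex), str(r.treatment), int(r.replicate))
            for r in df.itertuples(index=False)
        ]
        return cls(samples, min_replicates=min_replicates)

    @classmethod
    def balanced(
        cls, n_replicates: int = 4, library_size: float = 5_000_000.0
    ) -> "SampleDesign":
        """A balanced design: ``n_replicates`` per sex-by-treatment cell."""
        samples = []
        for sex, treatment in GROUPS:
            for rep in range(1, n_replicates + 1):
                abbrev = "ctrl" if treatment == "control" else "pert"
                samples.append(Sample(f"{sex}_{abbrev}_{rep}", sex, treatment, rep))
        return cls(samples, library_size=library_size)
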