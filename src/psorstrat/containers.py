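"""Core in-memory containers shared across the pipeline.

Expression data travel as pandas DataFrames (probes as rows, samples as
columns, log2 scale) wrapped with per-sample metadata. Signature sets are
directed, fixed-size probe lists with their derivation ranks attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CONDITIONS = ("PP", "PN")


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression (probes x samples) plus sample metadata.

    ``metadata`` is indexed by sample id and must carry at least ``subject``
    and ``condition`` (PP = lesional, PN = paired non-lesional); ``sex`` and
    ``batch`` are optional covariate columns.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.metadata.index):
            missing = self.values.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(
                    f"samples absent from metadata: {list(missing)[:5]}"
                )
            self.metadata = self.metadata.loc[self.values.columns]
        bad = set(self.metadata["condition"]) - set(VALID_CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.metadata["subject"]))

    def samples_for(self, condition: str) -> pd.Index:
        return self.metadata.index[self.metadata["condition"] == condition]


@dataclass
class SignatureSet:
    """A directed probe set for one cell population or one cytokine/direction.

    ``direction`` is ``high-in-population`` for cell-type signatures and
    ``induced``/``repressed`` for cytokine sets. ``stage1_rank`` is the
    p-value rank among direction-filtered probes; ``stage2_rank`` the
    fold-change rank within the retained pool.
    """

    name: str
    direction: str
    probes: list
    stage1_rank: dict = field(default_factory=dict)
    stage2_rank: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.probes)) != len(self.probes):
            raise ValueError(f"duplicate probes in signature {self.name!r}")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def label(self) -> str:
        return f"{self.name}.{self.direction}"


@dataclass
class ReferencePanel:
    """Reference expression panel: cell populations plus a skin reference set."""

    expression: pd.DataFrame
    population_of_sample: pd.Series
    skin_reference_ids: list
    truth_marker_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.population_of_sample.value_counts()
        if (counts < 2).any():
            few = counts[counts < 2].index.tolist()
            raise ValueError(f"populations with <2 replicates: {few}")
        if len(self.skin_reference_ids) < 2:
            raise ValueError("skin reference set needs >=2 samples")

    @property
    def populations(self) -> list:
        return sorted(self.population_of_sample.unique())

    def samples_of(self, population: str) -> list:
        mask = self.population_of_sample == population
        return list(self.population_of_sample.index[mask])


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    truth_inflammatory_tier: pd.Series
    truth_cytokine_tier: pd.Series
    truth_marker_map: dict
    effect_scales: dict
    noise_sd: float


@dataclass
class GenotypeTable:
    """Subjects x loci risk-allele counts in {0, 1, 2}; NaN marks missing."""

    counts: pd.DataFrame
    labels: pd.Series | None = None  # case/control labels for training tables

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("allele counts must be 0, 1, 2 or missing")

    @property
    def loci(self) -> pd.Index:
        return self.counts.columns

    @property
    def subjects(self) -> pd.Index:
        return self.counts.index


@dataclass
class SyntheticGenotypes:
    cohort_table: GenotypeTable
    training_table: GenotypeTable
    planted_delta_loci: list
    risk_allele_freqs: pd.Series
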