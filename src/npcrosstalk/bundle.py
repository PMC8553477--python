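"""Core in-memory containers for per-disease expression cohorts.

The central object is :class:`ExpressionBundle`: a log2-scale genes × samples
matrix together with per-sample metadata (case/control group and batch, i.e.
source dataset). Everything downstream — batch correction, differential
expression, coexpression screening — consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_CASE = "case"
GROUP_CONTROL = "control"
VALID_GROUPS = frozenset({GROUP_CASE, GROUP_CONTROL})


@dataclass
class ExpressionBundle:
    """Log2 expression matrix (genes × samples) plus sample metadata.

    Parameters
    ----------
    matrix
        DataFrame indexed by gene symbol, columns are sample ids, values on
        log2 scale.
    metadata
        DataFrame indexed by sample id with columns ``group`` (``case`` or
        ``control``) and ``batch`` (categorical dataset id).
    disease
        Free-text disease label, e.g. ``"MDD"`` or ``"PD"``.
    """

    matrix: pd.DataFrame
    metadata: pd.DataFrame
    disease: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols in matrix: {list(dups[:5])}")
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate sample ids in matrix")
        if not self.matrix.columns.equals(self.metadata.index):
            if set(self.matrix.columns) != set(self.metadata.index):
                raise ValueError("matrix samples and metadata rows do not match")
            # same samples, different order: align metadata to matrix
            self.metadata = self.metadata.loc[self.matrix.columns]
        for col in ("group", "batch"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        bad = set(self.metadata["group"].unique()) - VALID_GROUPS
        if bad:
            raise ValueError(f"invalid group labels: {sorted(bad)}")
        values = self.matrix.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return (self.metadata["group"] == group).to_numpy()

    def case_samples(self) -> pd.Index:
        return self.samples[self.group_mask(GROUP_CASE)]

    def control_samples(self) -> pd.Index:
        return self.samples[self.group_mask(GROUP_CONTROL)]

    def subset_genes(self, genes) -> "ExpressionBundle":
        missing = [g for g in genes if g not in self.matrix.index]
        if missing:
            raise KeyError(f"genes not in bundle: {missing[:5]}")
        return ExpressionBundle(
            matrix=self.matrix.loc[list(genes)].copy(),
            metadata=self.metadata.copy(),
            disease=self.disease,
        )

    def subset_samples(self, samples) -> "ExpressionBundle":
        samples = list(samples)
        return ExpressionBundle(
            matrix=self.matrix[samples].copy(),
            metadata=self.metadata.loc[samples].copy(),
            disease=self.disease,
        )

    def copy(self) -> "ExpressionBundle":
        return ExpressionBundle(
            matrix=self.matrix.copy(), metadata=self.metadata.copy(), disease=self.disease
        )


@dataclass
class ProbeMap:
    """Many-to-one probe id → gene symbol mapping; unmapped probes absent."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # gene symbols are upper-cased on ingest so mixed-source lists compare
        self.mapping = {str(p): str(g).upper() for p, g in self.mapping.items() if g}

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, probe: str) -> str | None:
        return self.mapping.get(probe)
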