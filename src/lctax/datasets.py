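"""Core data containers for categorical LCA data and taxometric indicator matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CategoricalDataset:
    """A case-by-item matrix of ordered categorical responses.

    Responses are integer category codes ``1..M_k`` per item ``k``; an optional
    real-valued covariate matrix (one row per case) can ride along for the
    structural (class-membership) models.
    """

    responses: np.ndarray  # (N, K) int
    case_ids: np.ndarray | None = None
    covariates: np.ndarray | None = None  # (N, P) float
    item_labels: list[str] | None = None
    covariate_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-d case-by-item matrix")
        n, k = self.responses.shape
        if n < 1 or k < 1:
            raise ValueError("need at least one case and one item")
        if self.responses.min() < 1:
            raise ValueError("category codes must start at 1")
        if self.case_ids is None:
            self.case_ids = np.arange(n)
        else:
            self.case_ids = np.asarray(self.case_ids)
            if len(self.case_ids) != n:
                raise ValueError("case_ids length mismatch")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows must align with response rows")
            if not np.isfinite(self.covariates).all():
                raise ValueError("covariates contain non-finite values")
        if self.item_labels is None:
            self.item_labels = [f"item{j + 1}" for j in range(k)]
        if self.covariate_labels is None and self.covariates is not None:
            self.covariate_labels = [f"psi{j + 1}" for j in range(self.covariates.shape[1])]

    @property
    def n_cases(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_categories(self) -> np.ndarray:
        """Number of categories per item, taken as the max observed code."""
        return self.responses.max(axis=0)

    def pattern_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unique response patterns with counts.

        Returns ``(patterns, counts, index)`` where ``patterns[index[i]] ==
        responses[i]`` and ``counts.sum() == N``.
        """
        patterns, index, counts = np.unique(
            self.responses, axis=0, return_inverse=True, return_counts=True
        )
        return patterns, counts, index

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_labels)
        if self.covariates is not None:
            for j, lab in enumerate(self.covariate_labels):
                df[lab] = self.covariates[:, j]
        return df


@dataclass
class IndicatorMatrix:
    """An N-by-k matrix of numeric indicator scores for taxometric analysis.

    Ordinal category codes are treated as numeric scores, which is how
    coherent-cut procedures consume ordered categorical items.
    """

    scores: np.ndarray  # (N, k) float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-d")
        n, k = self.scores.shape
        if k < 2:
            raise ValueError("need at least two indicators")
        if n < 10:
            raise ValueError("need at least 10 cases for cut placement")
        if not np.isfinite(self.scores).all():
            raise ValueError("indicator scores contain non-finite values")
        for j in range(k):
            if np.unique(self.scores[:, j]).size < 2:
                raise ValueError(f"indicator {j} is constant")
        if not self.labels:
            self.labels = [f"ind{j + 1}" for j in range(k)]

    @property
    def n_cases(self) -> int:
        return self.scores.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.scores.shape[1]

    def correlation_matrix(self) -> np.ndarray:
        return np.corrcoef(self.scores, rowvar=False)


def indicator_matrix_from_dataset(data: CategoricalDataset) -> IndicatorMatrix:
    """View the categorical responses as numeric taxometric indicators."""
    return IndicatorMatrix(data.responses.astype(float), list(data.item_labels))
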