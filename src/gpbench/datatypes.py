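"""Core containers shared across the pipeline.

Genotypes are lines x markers with calls coded ``{-1, 0, 1}`` for
``{aa, Aa, AA}``; phenotypes are per-line trait values, min-max normalized to
``[0, 1]`` before modelling.  These containers validate their invariants on
construction and are deliberately thin: numerical work happens on the
underlying numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "TraitTruth",
    "ReplicateSplit",
    "SplitPlan",
    "DegenerateTraitError",
    "EmptyDatasetError",
    "GenotypeFormatError",
    "AlignmentError",
]


class DegenerateTraitError(ValueError):
    """A trait vector is constant (or otherwise carries no usable variation)."""


class EmptyDatasetError(ValueError):
    """Filtering removed every line."""


class GenotypeFormatError(ValueError):
    """Raw genotype calls violate the biallelic / no-missing contract."""


class AlignmentError(ValueError):
    """Two objects that must share line or marker sets do not."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} must be unique")


@dataclass
class GenotypeMatrix:
    """Lines x markers matrix of biallelic calls in ``{-1, 0, 1}``.

    Parameters
    ----------
    line_ids : list of str
        Unique identifiers of the n lines (rows).
    marker_ids : list of str
        Unique identifiers of the p markers (columns).
    calls : ndarray of shape (n, p)
        Integer calls, every entry in ``{-1, 0, 1}`` (aa / Aa / AA).
    allele_freqs : ndarray of shape (p,), optional
        Frequencies of the ``A`` allele used by the simulator; carried as
        provenance so parameter-recovery tests can compare against them.
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    allele_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (lines x markers)")
        n, p = self.calls.shape
        if n < 2 or p < 1:
            raise ValueError("need at least 2 lines and 1 marker")
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise ValueError("id lengths do not match calls shape")
        _check_unique(self.line_ids, "line_ids")
        _check_unique(self.marker_ids, "marker_ids")
        if not np.isin(self.calls, (-1, 0, 1)).all():
            raise GenotypeFormatError("genotype calls must be in {-1, 0, 1}")
        self.calls = self.calls.astype(np.int8, copy=False)

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def X(self) -> np.ndarray:
        """Calls as a float design matrix."""
        return self.calls.astype(float)

    def subset_lines(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            line_ids=[self.line_ids[i] for i in indices],
            marker_ids=list(self.marker_ids),
            calls=self.calls[indices],
            allele_freqs=self.allele_freqs,
        )

    def subset_markers(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            marker_ids=[self.marker_ids[i] for i in indices],
            calls=self.calls[:, indices],
            allele_freqs=None
            if self.allele_freqs is None
            else self.allele_freqs[indices],
        )


@dataclass
class PhenotypeTable:
    """Per-line trait values; NaN marks missing entries before filtering."""

    line_ids: list[str]
    trait_names: list[str]
    values: np.ndarray  # (n, t), float, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, t = self.values.shape
        if len(self.line_ids) != n or len(self.trait_names) != t:
            raise ValueError("id lengths do not match values shape")
        _check_unique(self.line_ids, "line_ids")
        _check_unique(self.trait_names, "trait_names")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    def trait(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(name)]

    def subset_lines(self, indices: np.ndarray) -> "PhenotypeTable":
        indices = np.asarray(indices)
        return PhenotypeTable(
            line_ids=[self.line_ids[i] for i in indices],
            trait_names=list(self.trait_names),
            values=self.values[indices],
        )


@dataclass
class TraitTruth:
    """Everything the simulator knows about a synthetic trait.

    ``genetic_values`` are the pre-noise genetic merits g of each line;
    ``additive_effects`` align with ``qtl_indices``; epistatic pairs are
    (marker index, marker index, effect) triples.
    """

    qtl_indices: np.ndarray
    additive_effects: np.ndarray
    epistatic_pairs: list[tuple[int, int, float]]
    heritability_target: float
    genetic_values: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.heritability_target <= 1.0):
            raise ValueError("heritability_target must be in [0, 1]")

    def full_effect_vector(self, n_markers: int) -> np.ndarray:
        """Additive effects scattered over all p markers (zeros elsewhere)."""
        beta = np.zeros(n_markers)
        beta[self.qtl_indices] = self.additive_effects
        return beta


@dataclass
class ReplicateSplit:
    """Disjoint train / (optional validation) / test line indices."""

    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        self.validation = np.asarray(self.validation, dtype=int)
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("train/validation/test sets overlap")


@dataclass
class SplitPlan:
    """Replicated hold-out design: per replicate, 20% of lines are the test
    set and the rest train (a slice of train may be carved off for
    validation/early stopping)."""

    n_lines: int
    test_fraction: float
    validation_fraction_of_train: float
    master_seed: int
    replicates: list[ReplicateSplit]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)
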