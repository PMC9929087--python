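"""Identity-by-State similarity and the similarity-degree diagonal.

The per-locus similarity between two individuals with alternate-allele
counts a_i, a_j in {0,1,2} is the shared-allele fraction (2 - |a_i - a_j|)/2,
i.e. 1 for identical genotypes, 1/2 when one allele is shared, 0 for opposite
homozygotes.  Pairwise similarity s_ij averages this over the loci observed
in *both* samples (pairwise deletion of missing calls), which is what makes
degree-based corrections robust to target-data missingness.

The similarity degree of individual i is the row sum d_ii = sum_j s_ij over
the reference panel, including the self term for the reference form; its
diagonal matrix D generalizes the spectral decompositions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, GenotypeMatrix


class UndefinedSimilarityError(ValueError):
    """A sample pair shares zero jointly observed loci."""


class DegeneracyError(ValueError):
    """A similarity degree is non-positive."""


@dataclass
class IBSMatrix:
    """Pairwise IBS similarity; ``reference`` form (square, symmetric, unit
    diagonal) or ``cross`` form (targets x reference)."""

    values: np.ndarray
    kind: str  # "reference" | "cross"

    def __post_init__(self) -> None:
        if self.kind not in ("reference", "cross"):
            raise ValueError(f"unknown IBS kind {self.kind!r}")


@dataclass
class DegreeStructure:
    """Similarity degrees d_ii (row sums of an IBS matrix)."""

    degrees: np.ndarray
    kind: str  # "reference" | "target"

    def diagonal_power(self, exponent: float) -> np.ndarray:
        return self.degrees ** exponent


def _class_indicators(values: np.ndarray) -> tuple[np.ndarray, ...]:
    """Indicator matrices for allele counts 0/1/2 and for observedness."""
    obs = (values != MISSING).astype(np.float64)
    i0 = (values == -1).astype(np.float64)
    i1 = (values == 0).astype(np.float64)
    i2 = (values == 1).astype(np.float64)
    return i0, i1, i2, obs


def _ibs_blocks(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mean shared-allele fraction between every row of ``a`` and of ``b``."""
    a0, a1, a2, ao = _class_indicators(a)
    b0, b1, b2, bo = _class_indicators(b)
    shared = (
        a0 @ b0.T
        + a1 @ b1.T
        + a2 @ b2.T
        + 0.5 * (a0 @ b1.T + a1 @ b0.T + a1 @ b2.T + a2 @ b1.T)
    )
    joint = ao @ bo.T
    if (joint == 0).any():
        raise UndefinedSimilarityError(
            "a sample pair has no jointly observed loci; IBS undefined"
        )
    return shared / joint


def ibs_matrix(x: GenotypeMatrix) -> IBSMatrix:
    """Pairwise IBS similarity of a reference panel (symmetric, s_ii = 1)."""
    if x.n_samples < 2:
        raise ValueError("need at least two samples for pairwise IBS")
    s = _ibs_blocks(x.values, x.values)
    s = (s + s.T) / 2.0  # exact symmetry against float noise
    np.fill_diagonal(s, 1.0)
    return IBSMatrix(values=s, kind="reference")


def cross_ibs(y: GenotypeMatrix, x_ref: GenotypeMatrix) -> IBSMatrix:
    """IBS similarity of every target sample against every reference sample.

    The variant sets must already be intersected and allele-matched; loci
    missing in either member of a pair are excluded for that pair.
    """
    if y.n_variants != x_ref.n_variants:
        raise ValueError(
            f"variant mismatch: target has {y.n_variants} SNPs, "
            f"reference has {x_ref.n_variants}"
        )
    if not (y.variants["id"].to_numpy() == x_ref.variants["id"].to_numpy()).all():
        raise ValueError("variant ids differ; run intersect_datasets first")
    return IBSMatrix(values=_ibs_blocks(y.values, x_ref.values), kind="cross")


def degree(s: IBSMatrix) -> DegreeStructure:
    """Similarity degrees: row sums of ``s`` (self term included for the
    reference form, since the sum runs over all reference individuals)."""
    d = s.values.sum(axis=1)
    if (d <= 0).any():
        raise DegeneracyError("non-positive similarity degree encountered")
    return DegreeStructure(degrees=d, kind="reference" if s.kind == "reference" else "target")
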