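"""Core genotype containers and the additive / unit-interval codings.

Genotypes are held sample-major as small integers with the additive coding
``aa = -1, Aa = 0, AA = 1`` (count of alternate alleles minus one) and the
sentinel ``-2`` for a missing call.  All downstream methods — IBS similarity,
the matrix decompositions and the autoencoders — consume this representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -2
VALID_CODES = frozenset({-2, -1, 0, 1})

#: columns every variant table carries, in order
VARIANT_COLUMNS = ("chrom", "id", "pos", "ref", "alt")


def _as_variant_frame(variants: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing_cols:
        raise ValueError(f"variant table lacks columns {missing_cols}")
    out = variants.loc[:, list(VARIANT_COLUMNS)].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    return out


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes for ``n`` samples at ``m`` biallelic SNPs.

    Parameters
    ----------
    values
        ``n x m`` integer matrix with entries in ``{-1, 0, 1, -2}``.
    sample_ids
        Unique sample identifiers, length ``n``.
    variants
        Per-SNP records with columns ``chrom, id, pos, ref, alt`` (1-based
        positions, PLINK/VCF convention).
    labels
        Optional per-sample population label.
    super_labels
        Optional per-sample super-population (continental) label.
    """

    values: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame
    labels: Optional[np.ndarray] = None
    super_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.array_equal(self.values, np.round(self.values)):
                raise ValueError("genotype values must be integers")
            self.values = self.values.astype(np.int8)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variants = _as_variant_frame(self.variants)
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant records for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant ids are not unique")
        bad = ~np.isin(self.values, (-2, -1, 0, 1))
        if bad.any():
            raise ValueError(
                f"genotype codes outside {{-2,-1,0,1}}: e.g. "
                f"{self.values[bad][:5].tolist()}"
            )
        for attr in ("labels", "super_labels"):
            lab = getattr(self, attr)
            if lab is not None:
                lab = np.asarray(lab, dtype=object)
                if lab.shape != (n,):
                    raise ValueError(f"{attr} length {lab.shape} != n={n}")
                setattr(self, attr, lab)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def allele_counts(self) -> np.ndarray:
        """Alternate-allele counts in {0,1,2} as float, NaN where missing."""
        a = self.values.astype(float) + 1.0
        a[self.values == MISSING] = np.nan
        return a

    def alt_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (missing excluded)."""
        a = self.allele_counts()
        with np.errstate(invalid="ignore"):
            return np.nanmean(a, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------
    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=self.variants,
            labels=None if self.labels is None else self.labels[idx],
            super_labels=None if self.super_labels is None else self.super_labels[idx],
        )

    def take_variants(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx],
            labels=self.labels,
            super_labels=self.super_labels,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            values=self.values.copy(),
            sample_ids=list(self.sample_ids),
            variants=self.variants.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            super_labels=None if self.super_labels is None else self.super_labels.copy(),
        )

    def with_values(self, values: np.ndarray) -> "GenotypeMatrix":
        return replace(self, values=values)


@dataclass
class NormalizedMatrix:
    """Unit-interval view of a genotype matrix: ``x = (g + 1) / 2``.

    Observed codes map to {0, 0.5, 1}; the missing code -2 passes through the
    same affine map to -0.5, keeping missingness a distinct input level rather
    than silently imputing it.
    """

    values: np.ndarray
    source: Optional[GenotypeMatrix] = field(default=None, repr=False)

    def to_codes(self) -> np.ndarray:
        """Invert the affine map back to additive codes."""
        return np.rint(self.values * 2.0 - 1.0).astype(np.int8)


def recode_additive(allele_counts: np.ndarray, missing: int = MISSING) -> np.ndarray:
    """Map alternate-allele counts {0,1,2} to additive codes {-1,0,1}.

    ``missing`` marks entries without a call; they become -2.  Any other value
    outside {0,1,2} raises.
    """
    counts = np.asarray(allele_counts)
    out = np.empty(counts.shape, dtype=np.int8)
    is_missing = counts == missing
    observed = counts[~is_missing]
    if observed.size and not np.isin(observed, (0, 1, 2)).all():
        bad = observed[~np.isin(observed, (0, 1, 2))]
        raise ValueError(f"allele counts outside {{0,1,2}}: {np.unique(bad)[:5]}")
    out[~is_missing] = (counts[~is_missing] - 1).astype(np.int8)
    out[is_missing] = MISSING
    return out


def counts_from_codes(codes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`recode_additive` on observed codes; -2 stays -2."""
    codes = np.asarray(codes)
    out = codes.astype(np.int8) + 1
    out[codes == MISSING] = MISSING
    return out


def normalize_unit(g: GenotypeMatrix, impute_missing: bool = False) -> NormalizedMatrix:
    """Rescale additive codes into [0, 1] for network input.

    The map is ``x = (g + 1) / 2`` applied uniformly, so -1/0/1 become
    0/0.5/1 and the missing code -2 becomes -0.5.  With ``impute_missing``
    the missing entries are instead replaced by the per-SNP mean of the
    observed normalized values.
    """
    x = (g.values.astype(np.float64) + 1.0) / 2.0
    if impute_missing:
        miss = g.missing_mask()
        if miss.any():
            xm = np.where(miss, np.nan, x)
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(xm, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)
            x[miss] = np.broadcast_to(col_mean, x.shape)[miss]
    return NormalizedMatrix(values=x, source=g)
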