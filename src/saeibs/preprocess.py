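"""Quality-control preprocessing: sample missingness filter, iterative LD
pruning and cross-dataset variant intersection with allele matching."""

from __future__ import annotations

import numpy as np

from .matrix import MISSING, GenotypeMatrix


class EmptyResultError(ValueError):
    """An operation removed every sample or variant."""


def filter_sample_missingness(g: GenotypeMatrix, max_rate: float = 0.10) -> GenotypeMatrix:
    """Drop samples with *more than* ``max_rate`` missing genotypes.

    The inequality is strict: a sample missing exactly 10% of calls is kept
    at the default threshold.  The variant set is unchanged.
    """
    rate = g.missing_mask().mean(axis=1)
    keep = np.flatnonzero(rate <= max_rate)
    if keep.size == 0:
        raise EmptyResultError("all samples exceed the missingness threshold")
    if keep.size == g.n_samples:
        return g
    return g.take_samples(keep)


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns, missing entries
    excluded pairwise; monomorphic (zero variance) pairs contribute 0."""
    mask = (a != MISSING) & (b != MISSING)
    if mask.sum() < 2:
        return 0.0
    x = a[mask].astype(float)
    y = b[mask].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _prune_round(values: np.ndarray, keep: np.ndarray, window: int, step: int,
                 r2_cut: float, miss_rate: np.ndarray) -> np.ndarray:
    """One sliding-window pass; returns the surviving (global) indices."""
    alive = dict.fromkeys(keep.tolist(), True)
    order = keep.tolist()
    start = 0
    while start < len(order):
        win = [j for j in order[start:start + window] if alive[j]]
        for a_i in range(len(win)):
            for b_i in range(a_i + 1, len(win)):
                ja, jb = win[a_i], win[b_i]
                if not (alive[ja] and alive[jb]):
                    continue
                if _pairwise_r2(values[:, ja], values[:, jb]) > r2_cut:
                    # drop the worse of the pair: higher missing rate first,
                    # then the later one in map order
                    if miss_rate[ja] > miss_rate[jb]:
                        alive[ja] = False
                    else:
                        alive[jb] = False
        start += step
    return np.array([j for j in order if alive[j]], dtype=int)


def ld_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_cut: float = 0.2,
    iterate: bool = True,
) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on dosage r².

    Within each window of ``window`` SNPs advanced by ``step``, one SNP of any
    pair with squared Pearson correlation above ``r2_cut`` is removed (the one
    with the higher missing rate, ties to the later SNP in map order).  With
    ``iterate`` the pass repeats until a round removes nothing, matching the
    multiple-rounds-until-stable protocol.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0.0 < r2_cut <= 1.0:
        raise ValueError("r2_cut must be in (0, 1]")
    miss_rate = g.missing_mask().mean(axis=0)
    keep = np.arange(g.n_variants)
    while True:
        new_keep = _prune_round(g.values, keep, window, step, r2_cut, miss_rate)
        if new_keep.size == keep.size or not iterate:
            keep = new_keep
            break
        keep = new_keep
    if keep.size == g.n_variants:
        return g
    return g.take_variants(keep)


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(ref: str, alt: str) -> bool:
    return _COMPLEMENT.get(ref.upper()) == alt.upper()


def intersect_datasets(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    drop_ambiguous: bool = True,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict both datasets to shared SNPs and match alternate alleles.

    SNPs are keyed by (chromosome, position).  Where ``b``'s ref/alt are
    swapped relative to ``a``, ``b``'s observed codes are sign-flipped so the
    alternate alleles agree; SNPs whose allele sets disagree are dropped, as
    are strand-ambiguous A/T and C/G SNPs when ``drop_ambiguous``.
    """
    key_a = {(r.chrom, r.pos): i for i, r in enumerate(a.variants.itertuples())}
    idx_a, idx_b, flip = [], [], []
    for j, r in enumerate(b.variants.itertuples()):
        i = key_a.get((r.chrom, r.pos))
        if i is None:
            continue
        ra = a.variants.iloc[i]
        if drop_ambiguous and (_is_ambiguous(ra["ref"], ra["alt"]) or _is_ambiguous(r.ref, r.alt)):
            continue
        if (ra["ref"], ra["alt"]) == (r.ref, r.alt):
            idx_a.append(i), idx_b.append(j), flip.append(False)
        elif (ra["ref"], ra["alt"]) == (r.alt, r.ref):
            idx_a.append(i), idx_b.append(j), flip.append(True)
        # otherwise allele sets disagree: drop
    if not idx_a:
        raise EmptyResultError("no overlapping SNPs after allele matching")

    out_a = a.take_variants(idx_a)
    out_b = b.take_variants(idx_b)
    flip = np.asarray(flip)
    if flip.any():
        vals = out_b.values.copy()
        cols = np.flatnonzero(flip)
        observed = vals[:, cols] != MISSING
        vals[:, cols] = np.where(observed, -vals[:, cols], vals[:, cols])
        variants = out_b.variants.copy()
        variants.loc[flip, ["ref", "alt"]] = variants.loc[flip, ["alt", "ref"]].to_numpy()
        out_b = GenotypeMatrix(
            values=vals,
            sample_ids=out_b.sample_ids,
            variants=variants,
            labels=out_b.labels,
            super_labels=out_b.super_labels,
        )
    return out_a, out_b
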