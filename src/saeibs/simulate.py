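"""Synthetic genotype generation and artifact simulation.

Populations follow the Balding–Nichols island model: each SNP has an
ancestral frequency p, and population K draws its frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F) so that the divergence parameter F plays the
role of Fst.  Genotypes are binomial draws of two alleles.  Admixed
individuals draw each SNP from a mixture of the population frequencies, and
families of relatives are created by Mendelian transmission from two parents
sampled out of a source population.

The artifact simulators reproduce the perturbation protocol used to stress
ancestry projection: genotype missingness and genotyping errors applied at a
given rate to the rare SNPs (minor allele frequency below a threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

_OBSERVED_CODES = np.array([-1, 0, 1], dtype=np.int8)


@dataclass
class SimConfig:
    """Parameters of the multi-population genotype generator."""

    n_pops: int = 3
    n_per_pop: Union[int, Sequence[int]] = 100
    m_snps: int = 1000
    fst: Union[float, Sequence[float]] = 0.1
    ancestral_maf_range: tuple[float, float] = (0.01, 0.5)
    admixed: Optional[tuple[int, Sequence[float]]] = None
    families: Optional[list[tuple[int, int]]] = None  # (n_offspring, source pop)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.m_snps < 1:
            raise ValueError("n_pops and m_snps must be positive")
        low, high = self.ancestral_maf_range
        if not 0.0 < low <= high <= 0.5:
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        for f in np.atleast_1d(np.asarray(self.fst, dtype=float)):
            if not 0.0 < f < 1.0:
                raise ValueError("fst must be in (0, 1)")

    def per_pop_counts(self) -> np.ndarray:
        n = np.atleast_1d(np.asarray(self.n_per_pop, dtype=int))
        if n.size == 1:
            n = np.repeat(n, self.n_pops)
        if n.size != self.n_pops or (n <= 0).any():
            raise ValueError("n_per_pop must be positive, one per population")
        return n

    def per_pop_fst(self) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.fst, dtype=float))
        if f.size == 1:
            f = np.repeat(f, self.n_pops)
        if f.size != self.n_pops:
            raise ValueError("fst must be scalar or one value per population")
        return f


@dataclass
class PerturbationSpec:
    """Rates of the genotype artifact simulator (applied to rare SNPs)."""

    miss_rate: float = 0.05
    error_rate: float = 0.05
    maf_threshold: float = 0.05
    mode: str = "both"  # missing | error | both
    rare_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.miss_rate, self.error_rate, self.maf_threshold):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.mode not in ("missing", "error", "both"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")


def _variant_frame(m: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": "1",
            "id": [f"snp{j + 1}" for j in range(m)],
            "pos": np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )


def simulate_populations(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a labelled multi-population genotype matrix under the island model."""
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.per_pop_counts()
    fst = cfg.per_pop_fst()
    low, high = cfg.ancestral_maf_range

    maf = rng.uniform(low, high, size=cfg.m_snps)
    # fold: the alternate allele is the minor one for ~half the SNPs
    p_anc = np.where(rng.random(cfg.m_snps) < 0.5, maf, 1.0 - maf)

    pop_freq = np.empty((cfg.n_pops, cfg.m_snps))
    for kpop in range(cfg.n_pops):
        f = fst[kpop]
        alpha = p_anc * (1.0 - f) / f
        beta = (1.0 - p_anc) * (1.0 - f) / f
        pop_freq[kpop] = np.clip(rng.beta(alpha, beta), 1e-6, 1.0 - 1e-6)

    blocks, labels = [], []
    for kpop, n_k in enumerate(counts):
        dosage = rng.binomial(2, pop_freq[kpop], size=(n_k, cfg.m_snps))
        blocks.append(dosage.astype(np.int8) - 1)
        labels += [f"POP{kpop + 1}"] * n_k

    if cfg.admixed is not None:
        n_adm, props = cfg.admixed
        props = np.asarray(props, dtype=float)
        if props.size != cfg.n_pops or not np.isclose(props.sum(), 1.0):
            raise ValueError("admixture proportions must sum to 1 over populations")
        mix_freq = props @ pop_freq
        dosage = rng.binomial(2, mix_freq, size=(n_adm, cfg.m_snps))
        blocks.append(dosage.astype(np.int8) - 1)
        labels += ["ADMIX"] * n_adm

    values = np.vstack(blocks)
    labels = np.asarray(labels, dtype=object)
    g = GenotypeMatrix(
        values=values,
        sample_ids=[f"S{i + 1:04d}" for i in range(values.shape[0])],
        variants=_variant_frame(cfg.m_snps),
        labels=labels,
        super_labels=labels.copy(),
    )
    if cfg.families:
        g = add_relatives(g, cfg.families, seed=int(rng.integers(2**31)))
    return g


def add_relatives(
    g: GenotypeMatrix,
    families: list[tuple[int, int]],
    seed: int = 0,
    transmit_missing: bool = True,
) -> GenotypeMatrix:
    """Append families of full siblings produced by Mendelian transmission.

    For each ``(n_offspring, source_pop)`` entry two parents are sampled from
    that population (0-based index into POP labels) and each offspring
    genotype is built by independently transmitting one allele per parent per
    SNP.  Offspring are labelled ``REL<f>``; their super-label records the
    source population so robustness metrics can refer relatives back to their
    matching ancestry group.
    """
    if not families:
        return g
    if g.labels is None:
        raise ValueError("add_relatives requires population labels")
    rng = np.random.default_rng(seed)

    values = [g.values]
    sample_ids = list(g.sample_ids)
    labels = list(g.labels)
    supers = list(g.super_labels if g.super_labels is not None else g.labels)

    for fid, (n_off, src) in enumerate(families, start=1):
        pop_label = f"POP{src + 1}"
        members = np.flatnonzero(np.asarray(g.labels) == pop_label)
        if members.size < 2:
            raise ValueError(f"source population {pop_label} has fewer than 2 samples")
        pa, pb = rng.choice(members, size=2, replace=False)
        kids = np.empty((n_off, g.n_variants), dtype=np.int8)
        for child in range(n_off):
            alleles = np.zeros(g.n_variants, dtype=np.int8)
            miss = np.zeros(g.n_variants, dtype=bool)
            for parent in (pa, pb):
                codes = g.values[parent]
                pm = codes == MISSING
                miss |= pm
                count = codes.astype(np.int16) + 1  # alt alleles of the parent
                alleles += (rng.random(g.n_variants) < count / 2.0).astype(np.int8)
            kid = alleles - 1
            if transmit_missing:
                kid[miss] = MISSING
            kids[child] = kid
            sample_ids.append(f"REL{fid}_{child + 1}")
            labels.append(f"REL{fid}")
            supers.append(pop_label)
        values.append(kids)

    return GenotypeMatrix(
        values=np.vstack(values),
        sample_ids=sample_ids,
        variants=g.variants,
        labels=np.asarray(labels, dtype=object),
        super_labels=np.asarray(supers, dtype=object),
    )


def _target_mask(g: GenotypeMatrix, rate: float, spec: PerturbationSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(rate) mask over observed entries of the eligible SNPs."""
    if spec.rare_only:
        eligible_cols = g.maf() < spec.maf_threshold
    else:
        eligible_cols = np.ones(g.n_variants, dtype=bool)
    mask = rng.random(g.shape) < rate
    mask &= eligible_cols[None, :]
    mask &= g.values != MISSING
    return mask


def perturb_errors(g: GenotypeMatrix, spec: PerturbationSpec) -> GenotypeMatrix:
    """Flip genotypes of rare SNPs to one of the other two observed codes.

    MAF is computed on the unperturbed matrix (missing excluded).  Entries at
    common SNPs, and entries already missing, are untouched.
    """
    if spec.mode not in ("error", "both"):
        raise ValueError("spec.mode does not include errors")
    rng = np.random.default_rng(spec.seed)
    if spec.rare_only and not (g.maf() < spec.maf_threshold).any():
        import warnings

        warnings.warn("no rare SNPs present; error perturbation is a no-op")
        return g.copy()
    mask = _target_mask(g, spec.error_rate, spec, rng)
    values = g.values.copy()
    if mask.any():
        current = values[mask]
        # choose uniformly between the two observed codes != current
        offset = rng.integers(1, 3, size=current.size)  # 1 or 2
        values[mask] = _OBSERVED_CODES[(current + 1 + offset) % 3]
    return g.with_values(values)


def perturb_missing(g: GenotypeMatrix, spec: PerturbationSpec) -> GenotypeMatrix:
    """Mask genotypes of rare SNPs to the missing code -2."""
    if spec.mode not in ("missing", "both"):
        raise ValueError("spec.mode does not include missingness")
    rng = np.random.default_rng(spec.seed)
    if spec.rare_only and not (g.maf() < spec.maf_threshold).any():
        import warnings

        warnings.warn("no rare SNPs present; missingness perturbation is a no-op")
        return g.copy()
    mask = _target_mask(g, spec.miss_rate, spec, rng)
    values = g.values.copy()
    values[mask] = MISSING
    return g.with_values(values)


def perturb(g: GenotypeMatrix, spec: PerturbationSpec) -> GenotypeMatrix:
    """Apply the configured perturbation mode(s) with independent substreams."""
    ss = np.random.SeedSequence(spec.seed).spawn(2)
    out = g
    if spec.mode in ("error", "both"):
        sub = PerturbationSpec(**{**spec.__dict__, "mode": "error",
                                  "seed": int(ss[0].generate_state(1)[0] % 2**31)})
        out = perturb_errors(out, sub)
    if spec.mode in ("missing", "both"):
        sub = PerturbationSpec(**{**spec.__dict__, "mode": "missing",
                                  "seed": int(ss[1].generate_state(1)[0] % 2**31)})
        out = perturb_missing(out, sub)
    return out


def replicate_experiment(
    g_target: GenotypeMatrix,
    spec: PerturbationSpec,
    n_reps: int = 100,
) -> list[GenotypeMatrix]:
    """Generate ``n_reps`` independently seeded perturbed copies of a target."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(spec.seed).spawn(n_reps)
    reps = []
    for child in children:
        sub = PerturbationSpec(**{**spec.__dict__,
                                  "seed": int(child.generate_state(1)[0] % 2**31)})
        reps.append(perturb(g_target, sub))
    return reps
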