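"""Simulators for selfing-line pedigrees, genotypes, read depths and LD pairs.

The generators emulate the study design the analyses assume: full-sib (FS)
families propagated by single-seed descent through up to five generations of
self-fertilisation (S1..S5), with exactly one sampled individual per line and
generation; Mendelian segregation with optional viability selection; symmetric
genotyping error and missingness; Poisson read depths with a controllable
heterozygote allele balance; and a mixed-mating range-wide population at
inbreeding equilibrium F = s/(2-s).

All randomness flows through one seeded :class:`numpy.random.Generator`, so an
identical configuration reproduces identical output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GENERATIONS,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    DepthTable,
    GenotypeTable,
    PedigreeTable,
)

__all__ = [
    "SimulationConfig",
    "SelfingTruth",
    "mendelian_selfing_kernel",
    "self_one_generation",
    "simulate_selfing_panel",
    "simulate_mixed_mating_population",
    "simulate_depths",
    "simulate_ld_pairs",
    "equilibrium_fixation_index",
]


class InviableCrossError(ValueError):
    """All offspring genotypes have zero viability weight."""


def equilibrium_fixation_index(s: float) -> float:
    """Equilibrium inbreeding coefficient F = s/(2-s) under mixed mating.

    With a constant selfing rate ``s`` (outcrossing rate t = 1 - s) the
    population inbreeding coefficient converges to s/(2-s); at the study
    species' s = 0.3 this is 0.17647..., truncated to 0.17 where the QC
    cascade uses it as a constant.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"selfing rate must be in [0, 1], got {s}")
    return s / (2.0 - s)


@dataclass
class SimulationConfig:
    """Parameters of the selfing-line and mixed-mating simulators.

    Defaults mirror the study conditions: 28 lines carried to S4/S5 (one tree
    per line-generation), heterozygote fraction at FS of 0.3 (the observed S1
    heterozygosity of ~0.15 doubled under the halving law), mean capture depth
    30x, and a selfing rate of 0.3 (outcrossing 0.7).
    """

    n_lines: int = 28
    n_generations: int = 5  # S1..S5
    n_loci: int = 2000
    fs_het_fraction: float = 0.3
    #: viability fitness (w_RR, w_RA, w_AA); scalar triple or (n_loci, 3) array
    fitness: Sequence[float] | np.ndarray = (1.0, 1.0, 1.0)
    #: optional associative-overdominance model: (recombination fraction r,
    #: fitness of the homozygous deleterious recessive); applied to loci
    #: flagged by ``linked_mask`` (all loci when the mask is None).
    linked_model: tuple[float, float] | None = None
    linked_mask: np.ndarray | None = None
    miscall_rate: float = 0.005
    missing_rate: float = 0.02
    mean_depth: float = 30.0
    het_allele_balance: float = 0.5  # P(read supports REF) at heterozygotes
    selfing_rate: float = 0.3
    seed: int = 0
    loci_per_scaffold: int = 100
    locus_spacing_bp: int = 1000

    def __post_init__(self) -> None:
        for name in ("fs_het_fraction", "miscall_rate", "missing_rate",
                     "het_allele_balance", "selfing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.n_generations <= 5:
            raise ValueError("n_generations must be between 0 and 5")
        w = np.asarray(self.fitness, dtype=float)
        if w.ndim == 1 and w.shape[0] == 3:
            w = np.broadcast_to(w, (self.n_loci, 3))
        if w.shape != (self.n_loci, 3):
            raise ValueError("fitness must be a triple or an (n_loci, 3) array")
        if (w < 0).any() or (w.sum(axis=1) == 0).any():
            raise ValueError("fitness triples must be non-negative and not all zero")
        self._fitness_matrix = np.ascontiguousarray(w)
        if self.linked_model is not None:
            r, w_del = self.linked_model
            if not 0.0 <= r <= 0.5:
                raise ValueError("recombination fraction must be in [0, 0.5]")
            if w_del < 0:
                raise ValueError("deleterious fitness must be non-negative")


@dataclass
class SelfingTruth:
    """Error-free genotypes and selection flags retained by the simulator."""

    genotypes: np.ndarray  # (n_samples, n_loci) int8, no MISSING
    selected: np.ndarray  # (n_loci,) bool: locus under non-neutral fitness
    sample_ids: list[str] = field(default_factory=list)


def mendelian_selfing_kernel(
    fitness: Sequence[float] = (1.0, 1.0, 1.0),
) -> tuple[float, float, float]:
    """Offspring genotype distribution of a selfed heterozygote.

    Mendelian segregation gives (1/4, 1/2, 1/4) for (HOM_REF, HET, HOM_ALT);
    viability selection re-weights by the fitness triple and renormalises.
    Under neutrality the heterozygote fraction is exactly 1/2 — the halving
    law behind every drift expectation in the pipeline.
    """
    w_rr, w_ra, w_aa = (float(w) for w in fitness)
    raw = (0.25 * w_rr, 0.5 * w_ra, 0.25 * w_aa)
    norm = sum(raw)
    if norm == 0:
        raise InviableCrossError("all offspring classes have zero fitness")
    return (raw[0] / norm, raw[1] / norm, raw[2] / norm)


def self_one_generation(
    genotype: int,
    fitness: Sequence[float],
    rng: np.random.Generator,
) -> int:
    """Draw one selfed offspring genotype. Homozygotes breed true."""
    if genotype == HOM_REF or genotype == HOM_ALT:
        w = np.asarray(fitness, dtype=float)
        if (genotype == HOM_REF and w[0] == 0) or (genotype == HOM_ALT and w[2] == 0):
            raise InviableCrossError("homozygous parent genotype is inviable")
        return genotype
    if genotype != HET:
        raise ValueError(f"invalid parent genotype code {genotype}")
    p = mendelian_selfing_kernel(fitness)
    return int(rng.choice([HOM_REF, HET, HOM_ALT], p=p))


def _self_matrix(
    parents: np.ndarray,
    fitness: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised single-seed descent step for a (lines x loci) matrix."""
    child = parents.copy()
    het = parents == HET
    if het.any():
        w = fitness  # (n_loci, 3)
        raw = np.stack([0.25 * w[:, 0], 0.5 * w[:, 1], 0.25 * w[:, 2]], axis=1)
        norm = raw.sum(axis=1, keepdims=True)
        probs = raw / norm  # (n_loci, 3)
        cum = probs.cumsum(axis=1)
        u = rng.random(parents.shape)
        drawn = np.select(
            [u < cum[None, :, 0], u < cum[None, :, 1]],
            [HOM_REF, HET],
            default=HOM_ALT,
        ).astype(np.int8)
        child[het] = drawn[het]
    return child


# -- two-locus associative overdominance ------------------------------------
# Haplotypes encode (marker allele m, deleterious allele d) as h = 2m + d.
# The FS individual is heterozygous at both loci in repulsion phase:
# haplotypes (m=1, d=0) and (m=0, d=1).

def _linked_transition_matrix(r: float, w_del: float) -> np.ndarray:
    """16x16 parent-state -> offspring-state matrix under selfing.

    State s = 4*h1 + h2 over haplotypes h in {0..3}.  Gametes keep a parental
    haplotype with probability (1-r)/2 each and recombine with probability
    r/2 each; offspring viability is 1 except w_del for d/d homozygotes.
    """
    T = np.zeros((16, 16))
    for s in range(16):
        h1, h2 = divmod(s, 4)
        m1, d1 = divmod(h1, 2)
        m2, d2 = divmod(h2, 2)
        gam = np.zeros(4)
        gam[h1] += (1 - r) / 2
        gam[h2] += (1 - r) / 2
        gam[2 * m1 + d2] += r / 2
        gam[2 * m2 + d1] += r / 2
        off = np.outer(gam, gam).ravel()  # offspring state g1*4+g2
        w = np.ones(16)
        for sp in range(16):
            g1, g2 = divmod(sp, 4)
            if (g1 & 1) + (g2 & 1) == 2:
                w[sp] = w_del
        off = off * w
        tot = off.sum()
        if tot == 0:
            raise InviableCrossError("linked model leaves no viable offspring")
        T[s] = off / tot
    return T


def _marker_code_from_state(states: np.ndarray) -> np.ndarray:
    g1, g2 = np.divmod(states, 4)
    dosage_alt = (g1 >> 1) + (g2 >> 1)
    return dosage_alt.astype(np.int8)  # 0->HOM_REF, 1->HET, 2->HOM_ALT


def simulate_selfing_panel(
    config: SimulationConfig,
) -> tuple[GenotypeTable, DepthTable, PedigreeTable, SelfingTruth]:
    """Simulate a single-seed-descent selfing panel.

    One individual is sampled per line x generation (FS, S1..Sn); the next
    generation descends from that sampled individual.  The truth record keeps
    the error-free genotypes and the per-locus selection flags; miscalls and
    missingness are applied afterwards, and read depths are drawn from the
    observed (post-error) genotypes.
    """
    rng = np.random.default_rng(config.seed)
    L, M = config.n_lines, config.n_loci
    gens = GENERATIONS[: config.n_generations + 1]

    # FS genotypes: heterozygous with probability fs_het_fraction, otherwise
    # an even split of the two homozygotes (FS trees are outbred F1s).
    u = rng.random((L, M))
    fs = np.where(
        u < config.fs_het_fraction,
        HET,
        np.where(rng.random((L, M)) < 0.5, HOM_REF, HOM_ALT),
    ).astype(np.int8)

    linked = np.zeros(M, dtype=bool)
    if config.linked_model is not None:
        linked = (
            np.ones(M, dtype=bool)
            if config.linked_mask is None
            else np.asarray(config.linked_mask, dtype=bool)
        )
        T = _linked_transition_matrix(*config.linked_model)
        # linked loci start heterozygous in repulsion phase
        state = np.full((L, linked.sum()), 4 * 2 + 1, dtype=np.int64)
        fs[:, linked] = _marker_code_from_state(state)

    truth_rows = [fs]
    parents = fs
    for _ in range(config.n_generations):
        child = _self_matrix(parents, config._fitness_matrix, rng)
        if config.linked_model is not None and linked.any():
            cum = T.cumsum(axis=1)
            uu = rng.random(state.shape)
            state = (uu[..., None] >= cum[state]).sum(axis=-1)
            child[:, linked] = _marker_code_from_state(state)
        truth_rows.append(child)
        parents = child

    # stack to (n_samples, n_loci): samples ordered line-major, FS..Sn
    line_ids = [f"L{i + 1:02d}" for i in range(L)]
    sample_ids = [f"{lid}_{g}" for lid in line_ids for g in gens]
    truth_geno = np.concatenate(
        [np.stack([truth_rows[t][i] for t in range(len(gens))]) for i in range(L)],
        axis=0,
    ).astype(np.int8)

    selected = ~np.all(config._fitness_matrix == config._fitness_matrix[:, :1], axis=1)
    selected = selected | linked
    truth = SelfingTruth(genotypes=truth_geno.copy(), selected=selected,
                         sample_ids=list(sample_ids))

    # genotyping error: symmetric miscalls, then missingness
    observed = truth_geno.copy()
    if config.miscall_rate > 0:
        flip = rng.random(observed.shape) < config.miscall_rate
        hom_to = rng.random(observed.shape) < 0.5
        was_het = observed == HET
        observed[flip & was_het & hom_to] = HOM_REF
        observed[flip & was_het & ~hom_to] = HOM_ALT
        observed[flip & (truth_geno == HOM_REF)] = HET
        observed[flip & (truth_geno == HOM_ALT)] = HET
    if config.missing_rate > 0:
        observed[rng.random(observed.shape) < config.missing_rate] = MISSING

    loci = _synthetic_loci(M, config.loci_per_scaffold, config.locus_spacing_bp, rng)
    table = GenotypeTable(sample_ids=sample_ids, loci=loci, genotypes=observed)
    depths = simulate_depths(table, config, rng)
    ped = PedigreeTable(
        lines={lid: {g: f"{lid}_{g}" for g in gens} for lid in line_ids}
    )
    return table, depths, ped, truth


def _synthetic_loci(
    n_loci: int, per_scaffold: int, spacing: int, rng: np.random.Generator
) -> pd.DataFrame:
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_loci)]
    alt = bases[(np.char.find("ACGT", ref) + rng.integers(1, 4, n_loci)) % 4]
    idx = np.arange(n_loci)
    return pd.DataFrame(
        {
            "scaffold": [f"scaffold_{i // per_scaffold + 1}" for i in idx],
            "pos": (idx % per_scaffold + 1) * spacing,
            "ref": ref,
            "alt": alt,
            "is_variant": True,
            "qual": 100.0,
        }
    )


def simulate_mixed_mating_population(
    config: SimulationConfig,
    p: float | np.ndarray,
    n_samples: int,
    rng: np.random.Generator | None = None,
) -> GenotypeTable:
    """Draw a population at mixed-mating inbreeding equilibrium.

    Genotype frequencies are p^2 + pqF, 2pq(1-F), q^2 + pqF with
    F = s/(2-s) for the configured selfing rate s.  ``p`` (reference-allele
    frequency) may be a scalar or a per-locus array of length ``n_loci``.
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("allele frequency p must be in (0, 1)")
    p = np.broadcast_to(p, (config.n_loci,))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    F = equilibrium_fixation_index(config.selfing_rate)
    q = 1.0 - p
    f_rr = p * p + p * q * F
    f_het = 2 * p * q * (1 - F)
    cum1 = f_rr
    cum2 = f_rr + f_het
    u = rng.random((n_samples, config.n_loci))
    geno = np.select([u < cum1, u < cum2], [HOM_REF, HET], default=HOM_ALT).astype(np.int8)
    loci = _synthetic_loci(config.n_loci, config.loci_per_scaffold,
                           config.locus_spacing_bp, rng)
    sample_ids = [f"RWP{i + 1:03d}" for i in range(n_samples)]
    return GenotypeTable(sample_ids=sample_ids, loci=loci, genotypes=geno)


def simulate_depths(
    table: GenotypeTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    paralog_mask: np.ndarray | None = None,
    paralog_allele_balance: float = 0.8,
) -> DepthTable:
    """Draw read depths consistent with the called genotypes.

    total ~ Poisson(mean_depth); heterozygote REF reads ~ Binomial(total,
    het_allele_balance); homozygote reads all support the called allele apart
    from per-read miscalls at ``miscall_rate``.  Loci in ``paralog_mask`` use
    ``paralog_allele_balance`` instead — a paralog mimic whose pooled
    read-ratio deviation the D filter is designed to catch.  Missing
    genotypes get zero depth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = table.genotypes.shape
    total = rng.poisson(config.mean_depth, shape).astype(np.int32)
    total[table.genotypes == MISSING] = 0

    p_ref = np.full(shape, config.het_allele_balance)
    if paralog_mask is not None:
        p_ref[:, np.asarray(paralog_mask, dtype=bool)] = paralog_allele_balance

    ref = np.zeros(shape, dtype=np.int32)
    alt = np.zeros(shape, dtype=np.int32)

    het = table.genotypes == HET
    ref[het] = rng.binomial(total[het], p_ref[het])
    alt[het] = total[het] - ref[het]

    hom_r = table.genotypes == HOM_REF
    err_r = rng.binomial(total[hom_r], config.miscall_rate)
    ref[hom_r] = total[hom_r] - err_r
    alt[hom_r] = err_r

    hom_a = table.genotypes == HOM_ALT
    err_a = rng.binomial(total[hom_a], config.miscall_rate)
    alt[hom_a] = total[hom_a] - err_a
    ref[hom_a] = err_a

    return DepthTable(total=total, ref=ref, alt=alt)


def simulate_ld_pairs(
    c_per_bp: float,
    n: int,
    n_pairs: int,
    max_dist: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw (distance, r^2) pairs from the sample-size-adjusted decay curve.

    Distances are uniform on (0, max_dist]; r^2 values sit on the expectation
    E(r^2)(C = c_per_bp * d, n) plus Gaussian noise truncated to [0, 1].
    Returns an (n_pairs, 2) array.
    """
    from .diversity_ld import ld_expectation

    if c_per_bp < 0:
        raise ValueError("c_per_bp must be non-negative")
    d = rng.uniform(0.0, max_dist, n_pairs)
    d = np.where(d == 0.0, max_dist, d)
    r2 = ld_expectation(c_per_bp * d, n)
    if noise_sd > 0:
        r2 = r2 + rng.normal(0.0, noise_sd, n_pairs)
    r2 = np.clip(r2, 0.0, 1.0)
    return np.column_stack([d, r2])
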