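"""Forward-in-time two-population haplotype simulator with known Ne history.

Discrete-generation Wright–Fisher with random mating and recombination.  The
generator exists so that every analysis stage (LD decay, phase persistence,
Ne estimation) has ground truth: a purebred population, a composite carrying
a 5/8 genome contribution from the purebred (a Braford-style breed design),
declining-Ne histories, and SNP-array-style MAF ascertainment.

Recombination model
-------------------
Each meiosis places a Poisson number of crossovers (mean = map length in
Morgans) uniformly along the chromosome, with no interference — i.e. a
Poisson process on the genetic map.  At the marker loci this is exactly
equivalent to a two-state Markov chain along the chromosome: the transmitted
gamete starts on a random parental haplotype and switches between the two
parental haplotypes between adjacent markers with probability
``(1 - exp(-2d))/2`` for inter-marker distance ``d`` Morgans (Haldane's map
function).  The Markov form is what is implemented, because it vectorises
over all gametes of a generation; it is distributionally identical to
explicit crossover placement at the marker positions.

All stochastic draws derive from a single ``numpy.random.Generator`` stream,
so a seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .popdata import HaplotypeSet, MarkerMap

import pandas as pd


@dataclass
class SimConfig:
    """Configuration of a single-population Wright–Fisher run.

    Parameters
    ----------
    ne_trajectory : list of (generation_span, Ne)
        Ordered from past to present; e.g. ``[(80, 400), (20, 150)]`` runs 80
        generations at Ne=400 followed by 20 at Ne=150.  All Ne >= 2.
    n_sample_individuals : int
        Diploids sampled (without replacement) from the final generation.
    chrom_lengths_bp : sequence of int
        Physical length of each simulated autosome.
    n_snps : int or sequence of int
        Markers per chromosome (evenly spaced; positions 1-based).
    recomb_rate_cm_per_mb : float
        Default 1.0, i.e. the 1 Mb = 1 cM convention used throughout.
    admix_proportion : float
        Composite-population genome fraction from population A (default
        5/8 = 0.625); used by :func:`make_composite`.
    maf_min_ascertainment : float
        MAF floor applied by :func:`ascertain_markers` when emulating array
        ascertainment (default 0.03, the array QC floor).
    init_freq_range : (float, float)
        Founder allele-1 frequencies are i.i.d. uniform on this interval
        (default (0.05, 0.95)): array SNPs are pre-ascertained common
        variants, so a mutation-drift spectrum is deliberately not used.
    seed : int
        Fully determines the output.
    """

    ne_trajectory: list[tuple[int, int]]
    n_sample_individuals: int
    chrom_lengths_bp: Sequence[int]
    n_snps: Sequence[int] | int
    recomb_rate_cm_per_mb: float = 1.0
    admix_proportion: float = 0.625
    maf_min_ascertainment: float = 0.03
    init_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def n_snps_per_chrom(self) -> list[int]:
        if np.isscalar(self.n_snps):
            return [int(self.n_snps)] * len(self.chrom_lengths_bp)
        if len(self.n_snps) != len(self.chrom_lengths_bp):
            raise ValueError("n_snps length must match chrom_lengths_bp")
        return [int(n) for n in self.n_snps]

    def validate(self) -> None:
        if not self.ne_trajectory:
            raise ValueError("ne_trajectory must be non-empty")
        for span, ne in self.ne_trajectory:
            if ne < 2:
                raise ValueError("all Ne must be >= 2")
            if span < 0:
                raise ValueError("generation spans must be >= 0")
        if not 0.0 <= self.admix_proportion <= 1.0:
            raise ValueError("admix_proportion must be in [0,1]")
        if sum(self.n_snps_per_chrom()) == 0:
            raise ValueError("zero markers requested")
        if self.recomb_rate_cm_per_mb < 0:
            raise ValueError("recombination rate must be >= 0")


def _even_map(chrom_lengths_bp: Sequence[int], n_snps: Sequence[int]) -> MarkerMap:
    """Evenly spaced markers over each chromosome, 1-based positions."""
    recs = []
    k = 0
    for c, (L, n) in enumerate(zip(chrom_lengths_bp, n_snps), start=1):
        if n > 0:
            pos = np.linspace(1, L, n).round().astype(np.int64)
            # enforce strict increase if rounding collided
            pos = np.maximum.accumulate(pos + np.arange(n) * 0)
            for j in range(1, n):
                if pos[j] <= pos[j - 1]:
                    pos[j] = pos[j - 1] + 1
            for p in pos:
                k += 1
                recs.append((f"snp{k}", str(c), int(p), "A", "G"))
    return MarkerMap(
        pd.DataFrame(recs, columns=["snp_id", "chrom", "pos_bp", "allele1", "allele2"])
    )


def _switch_probs(map_: MarkerMap, rate_cm_per_mb: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (column indices, switch prob between adjacent markers)."""
    out = []
    chrom = map_.chrom
    pos = map_.pos_bp
    for c in dict.fromkeys(chrom):
        cols = np.flatnonzero(chrom == c)
        d_morgans = np.diff(pos[cols]) * rate_cm_per_mb * 1e-8
        p_switch = 0.5 * (1.0 - np.exp(-2.0 * d_morgans))
        out.append((cols, p_switch))
    return out


def _meiosis(
    pop: np.ndarray,
    parent_ids: np.ndarray,
    chrom_blocks: list[tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per entry of ``parent_ids`` (diploid parent indices)."""
    G = len(parent_ids)
    m = pop.shape[1]
    out = np.empty((G, m), dtype=np.uint8)
    for cols, p_switch in chrom_blocks:
        nc = len(cols)
        # which parental haplotype is transmitted at each marker
        state = np.empty((G, nc), dtype=np.uint8)
        state[:, 0] = rng.integers(0, 2, size=G)
        if nc > 1:
            switches = (rng.random((G, nc - 1)) < p_switch).astype(np.uint8)
            state[:, 1:] = switches
            np.bitwise_xor.accumulate(state, axis=1, out=state)
        h0 = pop[2 * parent_ids][:, cols]
        h1 = pop[2 * parent_ids + 1][:, cols]
        out[:, cols] = np.where(state == 0, h0, h1)
    return out


def _next_generation(
    pop: np.ndarray,
    n_offspring: int,
    chrom_blocks: list[tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
) -> np.ndarray:
    n_parents = pop.shape[0] // 2
    parents = rng.integers(0, n_parents, size=(n_offspring, 2))
    gametes_p = _meiosis(pop, parents[:, 0], chrom_blocks, rng)
    gametes_m = _meiosis(pop, parents[:, 1], chrom_blocks, rng)
    new = np.empty((2 * n_offspring, pop.shape[1]), dtype=np.uint8)
    new[0::2] = gametes_p
    new[1::2] = gametes_m
    return new


def _expand_trajectory(ne_trajectory: list[tuple[int, int]]) -> list[int]:
    sizes: list[int] = []
    for span, ne in ne_trajectory:
        sizes.extend([int(ne)] * int(span))
    return sizes


def simulate_population(
    config: SimConfig, return_full: bool = False
) -> HaplotypeSet:
    """Run the Wright–Fisher model and return a phased sample.

    Founders (the first Ne of the trajectory) start in linkage equilibrium
    with i.i.d. uniform allele frequencies; LD then accrues from drift and
    recombination according to the Ne history.

    Parameters
    ----------
    return_full : bool
        If True, return the entire final generation instead of a sample of
        ``n_sample_individuals`` (used as a founder pool for divergence and
        admixture experiments).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    map_ = _even_map(config.chrom_lengths_bp, config.n_snps_per_chrom())
    m = map_.n_markers
    blocks = _switch_probs(map_, config.recomb_rate_cm_per_mb)

    sizes = _expand_trajectory(config.ne_trajectory)
    n0 = sizes[0] if sizes else int(config.ne_trajectory[-1][1])
    freqs = rng.uniform(*config.init_freq_range, size=m)
    pop = (rng.random((2 * n0, m)) < freqs).astype(np.uint8)
    for n_next in sizes:
        pop = _next_generation(pop, n_next, blocks, rng)

    full = HaplotypeSet(
        pop,
        [f"ind{i + 1}" for i in range(pop.shape[0] // 2)],
        map_,
        population_label="sim",
    )
    if return_full:
        return full
    return sample_individuals(full, config.n_sample_individuals, rng)


def evolve_population(
    h: HaplotypeSet,
    ne_trajectory: list[tuple[int, int]],
    seed: int,
    recomb_rate_cm_per_mb: float = 1.0,
    population_label: str | None = None,
) -> HaplotypeSet:
    """Continue Wright–Fisher evolution from an existing population.

    ``h`` is the parent pool for the first new generation.  Used to diverge
    two descendant populations from a shared ancestral population.
    """
    rng = np.random.default_rng(seed)
    blocks = _switch_probs(h.map, recomb_rate_cm_per_mb)
    pop = h.haplotypes
    for n_next in _expand_trajectory(ne_trajectory):
        pop = _next_generation(pop, n_next, blocks, rng)
    return HaplotypeSet(
        pop,
        [f"ind{i + 1}" for i in range(pop.shape[0] // 2)],
        h.map,
        population_label if population_label is not None else h.population_label,
    )


def sample_individuals(
    h: HaplotypeSet, n: int, rng_or_seed: int | np.random.Generator
) -> HaplotypeSet:
    """Sample ``n`` diploids without replacement from a population."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    if n > h.n_individuals:
        raise ValueError(
            f"cannot sample {n} individuals from population of {h.n_individuals}"
        )
    idx = np.sort(rng.choice(h.n_individuals, size=n, replace=False))
    return h.select_individuals(idx)


def make_composite(
    popA: HaplotypeSet,
    popB: HaplotypeSet,
    admix_proportion: float,
    n_generations_since_admixture: int,
    seed: int,
    n_individuals: int | None = None,
    recomb_rate_cm_per_mb: float = 1.0,
    population_label: str = "composite",
) -> HaplotypeSet:
    """Composite population: founders from A with probability
    ``admix_proportion`` (else B), then random mating with recombination.

    With the default 0.625 this emulates a 5/8-contribution composite breed.
    Both parents must share an identical marker map (shared allele coding).
    Returns the full final generation (phased); sample from it with
    :func:`sample_individuals`.
    """
    if popA.map != popB.map:
        raise ValueError("parent populations must share an identical marker map")
    if not 0.0 <= admix_proportion <= 1.0:
        raise ValueError("admix_proportion must be in [0,1]")
    rng = np.random.default_rng(seed)
    N = n_individuals if n_individuals is not None else popA.n_individuals
    from_A = rng.random(N) < admix_proportion
    idxA = rng.integers(0, popA.n_individuals, size=N)
    idxB = rng.integers(0, popB.n_individuals, size=N)
    founders = np.empty((2 * N, popA.n_markers), dtype=np.uint8)
    for i in range(N):
        src, j = (popA, idxA[i]) if from_A[i] else (popB, idxB[i])
        founders[2 * i] = src.haplotypes[2 * j]
        founders[2 * i + 1] = src.haplotypes[2 * j + 1]
    pop = founders
    blocks = _switch_probs(popA.map, recomb_rate_cm_per_mb)
    for _ in range(int(n_generations_since_admixture)):
        pop = _next_generation(pop, N, blocks, rng)
    return HaplotypeSet(
        pop,
        [f"ind{i + 1}" for i in range(N)],
        popA.map,
        population_label,
    )


def ascertain_markers(
    pop: HaplotypeSet, maf_min: float, reference: HaplotypeSet | None = None
) -> HaplotypeSet:
    """Keep markers with MAF >= ``maf_min`` in a designated reference
    population (default: ``pop`` itself).

    Ascertaining on one population and applying the resulting panel to
    another emulates SNP-array ascertainment bias: the second population's
    MAF spectrum is shifted downward on average.  The bias is emulated, not
    corrected.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    ref = reference if reference is not None else pop
    if ref.map != pop.map:
        raise ValueError("reference population must share the marker map")
    keep = ref.maf() >= maf_min
    return pop.select_markers(keep)


def simulate_two_breed_study(
    seed: int,
    ne_trajectory: list[tuple[int, int]] | None = None,
    chrom_lengths_bp: Sequence[int] = (50_000_000,),
    n_snps: Sequence[int] | int = 800,
    divergence_generations: int = 200,
    divergence_ne: int = 200,
    admix_proportion: float = 0.625,
    composite_generations: int = 15,
    n_sample_purebred: int = 60,
    n_sample_composite: int = 60,
    maf_min_ascertainment: float = 0.03,
    max_snps_after_ascertainment: int | None = None,
) -> dict[str, HaplotypeSet]:
    """Canned two-breed study design: purebred + 5/8 composite.

    An ancestral population splits into a "taurine" and an "indicine"
    lineage that drift apart for ``divergence_generations``; the composite is
    founded from the two lineages with the stated admixture proportion and
    random-mates for ``composite_generations``.  The marker panel is
    ascertained on the taurine (purebred) lineage, emulating array bias.

    Returns ``{"H": purebred sample, "B": composite sample}`` on a shared
    map/allele coding.  Desk-scale defaults (one 50 Mb chromosome, 800 SNPs)
    keep a full run in seconds; scale up via the arguments.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=6)
    if ne_trajectory is None:
        ne_trajectory = [(60, 400), (30, 300), (10, 200)]
    anc_cfg = SimConfig(
        ne_trajectory=[(40, divergence_ne)],
        n_sample_individuals=1,
        chrom_lengths_bp=chrom_lengths_bp,
        n_snps=n_snps,
        seed=int(sub[0]),
    )
    ancestral = simulate_population(anc_cfg, return_full=True)
    taurine = evolve_population(
        ancestral,
        [(divergence_generations, divergence_ne)] + ne_trajectory,
        seed=int(sub[1]),
        population_label="H",
    )
    indicine = evolve_population(
        ancestral,
        [(divergence_generations + sum(s for s, _ in ne_trajectory), divergence_ne)],
        seed=int(sub[2]),
        population_label="Z",
    )
    composite = make_composite(
        taurine,
        indicine,
        admix_proportion,
        composite_generations,
        seed=int(sub[3]),
        population_label="B",
    )
    # array-style panel: ascertain on the purebred (taurine) lineage
    panel_mask = taurine.maf() >= maf_min_ascertainment
    if max_snps_after_ascertainment is not None:
        keep_idx = np.flatnonzero(panel_mask)
        if len(keep_idx) > max_snps_after_ascertainment:
            sel = np.linspace(
                0, len(keep_idx) - 1, max_snps_after_ascertainment
            ).round().astype(int)
            keep_idx = keep_idx[sel]
        panel_mask = np.zeros(taurine.n_markers, dtype=bool)
        panel_mask[keep_idx] = True
    H = sample_individuals(
        taurine.select_markers(panel_mask), n_sample_purebred, int(sub[4])
    )
    B = sample_individuals(
        composite.select_markers(panel_mask), n_sample_composite, int(sub[5])
    )
    H.population_label = "H"
    B.population_label = "B"
    return {"H": H, "B": B}
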