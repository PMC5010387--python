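"""Capture of monomers/dimers into extruded liposomes and the resulting
fluorophore-occupancy and photobleaching-step distributions.

Two engines compute the per-liposome visible-fluorophore distribution
``P*``:

* :func:`occupancy_analytic` — exact mixture computation. Within a size
  bin each particle lands on a uniformly random liposome, so the number
  of particles in one liposome is Binomial(N_particles(bin),
  1/N_liposomes(bin)); the fluorophore count is that many independent
  draws from the species' label-count distribution. The per-bin
  distributions are combined with weights proportional to the bin's
  share of liposomes; bins excluded by the species' minimum radius keep
  their liposomes empty, feeding the unoccupied fraction F0.
* :func:`simulate_capture` — seeded Monte Carlo with the same structure.
  Liposomes are never materialized: each particle draws a (bin, index)
  pair and collisions are accumulated by sorting the sparse keys, so the
  liposome count can reach 1e12.

``to_photobleach`` conditions the occupancy distribution on visibility
(at least one fluorophore), which is what the step-count experiment
observes: P_n = P*(n) / (1 - P*(0)) with the top category absorbing the
tail.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .labeling import (
    LabelCountDistribution,
    LabelingYields,
    dimer_label_distribution,
    monomer_label_distribution,
)
from .liposomes import (
    DIMER_EXCLUSION_RADIUS_NM,
    RadiusDistribution,
    accessible_population,
    allocation_weights,
)

__all__ = [
    "CaptureConfig",
    "OccupancyDistribution",
    "PhotobleachDistribution",
    "occupancy_analytic",
    "simulate_capture",
    "simulate_joint_capture",
    "to_photobleach",
    "ideal_pair_at_chi",
    "ideal_distribution_pair",
    "total_variation",
    "CHI_INDISTINGUISHABLE_WARN",
    "DEFAULT_CHI_GRID",
]

# Above this observed mole fraction the monomer and dimer step-count
# distributions are no longer statistically distinguishable.
CHI_INDISTINGUISHABLE_WARN = 3.8e-4

# The experimental density series (observed chi, subunit/lipid).
DEFAULT_CHI_GRID = (
    7.5e-10, 3.8e-9, 7.5e-9, 3.8e-8, 7.5e-8, 3.8e-7, 7.5e-7,
    2.0e-6, 3.8e-6, 7.5e-6, 3.8e-5, 7.5e-5, 3.8e-4,
)

# Binomial -> Poisson crossover for the per-bin particle-count law; at
# this many liposomes per bin the two differ by O(lambda^2 / N) < 1e-4.
_POISSON_N_MIN = 1e4


@dataclass(frozen=True)
class CaptureConfig:
    """Full specification of one capture simulation."""

    species: str  # "monomer" | "dimer"
    n_subunits: float
    n_liposomes: float
    radius_dist: RadiusDistribution
    r_min: float = 0.0
    yields: LabelingYields = field(default_factory=LabelingYields)
    sa_lipid: float = 0.6
    seed: int | None = None
    max_ncy5: int = 12  # occupancy tail bucket

    def __post_init__(self) -> None:
        if self.species not in ("monomer", "dimer"):
            raise ValueError("species must be 'monomer' or 'dimer'")
        if self.n_subunits < 0 or self.n_liposomes <= 0:
            raise ValueError("counts must be positive")
        if self.max_ncy5 < 2:
            raise ValueError("max_ncy5 must be at least 2")

    @property
    def n_particles(self) -> float:
        if self.species == "monomer":
            return self.n_subunits
        n = self.n_subunits / 2.0
        if float(self.n_subunits).is_integer() and int(self.n_subunits) % 2:
            warnings.warn(
                "odd subunit count for dimer species; using floor(n/2) dimers",
                stacklevel=3,
            )
            n = math.floor(n)
        return n

    @property
    def label_dist(self) -> LabelCountDistribution:
        if self.species == "monomer":
            return monomer_label_distribution(self.yields)
        return dimer_label_distribution(self.yields)


@dataclass(frozen=True)
class OccupancyDistribution:
    """P*(N_Cy5) per liposome; the last entry is the tail bucket."""

    p_star: np.ndarray
    n_occupied: float | None = None  # MC diagnostic: visible liposomes

    def __post_init__(self) -> None:
        p = np.asarray(self.p_star, dtype=float)
        object.__setattr__(self, "p_star", p)
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("p_star must be a probability vector")

    @property
    def f0(self) -> float:
        """Fraction of liposomes with zero visible fluorophores."""
        return float(self.p_star[0])

    @property
    def mean_ncy5(self) -> float:
        """Mean visible fluorophores per liposome (tail at its index)."""
        return float(np.arange(len(self.p_star)) @ self.p_star)


@dataclass(frozen=True)
class PhotobleachDistribution:
    """P1 ... P(m-1), Pm+ among visibly occupied liposomes."""

    m: int
    probs: np.ndarray
    n_spots: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (self.m,):
            raise ValueError(f"probs must have length m={self.m}")
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probs must be a probability vector")

    @classmethod
    def from_counts(cls, counts) -> "PhotobleachDistribution":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0 or np.any(counts < 0):
            raise ValueError("counts must be non-negative with positive sum")
        return cls(m=len(counts), probs=counts / total, n_spots=int(round(total)))


def _conv_tail(a: np.ndarray, b: np.ndarray, size: int) -> np.ndarray:
    """Convolve two tail-bucketed distributions of length ``size``;
    mass at or beyond the last index folds into the last index."""
    out = np.zeros(size)
    full = np.convolve(a, b)
    out[: size - 1] = full[: size - 1]
    out[size - 1] = full[size - 1 :].sum()
    return out


def _binned_system(config: CaptureConfig):
    """Per-bin liposome counts, particle counts and label distribution."""
    pop = accessible_population(config.radius_dist, config.r_min)
    weights = allocation_weights(pop).weights
    n_lip_r = config.radius_dist.probs * config.n_liposomes
    n_par_r = weights * config.n_particles
    return pop, n_lip_r, n_par_r, config.label_dist.probs


def _particle_count_pmf(n: float, n_lip: float) -> np.ndarray:
    """pmf of the number of particles in one liposome of a bin holding
    ``n`` particles spread over ``n_lip`` liposomes."""
    if n <= 0:
        return np.array([1.0])
    mean = n / n_lip
    k_hi = int(max(8, math.ceil(mean + 12.0 * math.sqrt(mean) + 12)))
    if n_lip >= _POISSON_N_MIN:
        k = np.arange(k_hi + 1)
        log_pmf = k * math.log(mean) - mean - gammaln(k + 1)
        return np.exp(log_pmf)

    # exact binomial; fractional expected bin counts are handled as the
    # mean-preserving mixture of the two bracketing integer counts
    def binom_pmf(n_int: int) -> np.ndarray:
        if n_int == 0:
            return np.array([1.0])
        k = np.arange(min(k_hi, n_int) + 1)
        p = 1.0 / n_lip
        log_pmf = (
            gammaln(n_int + 1)
            - gammaln(k + 1)
            - gammaln(n_int - k + 1)
            + k * math.log(p)
            + (n_int - k) * math.log1p(-p)
        )
        return np.exp(log_pmf)

    lo = math.floor(n)
    frac = n - lo
    if frac < 1e-12:
        return binom_pmf(lo)
    pmf_lo, pmf_hi = binom_pmf(lo), binom_pmf(lo + 1)
    size = max(len(pmf_lo), len(pmf_hi))
    out = np.zeros(size)
    out[: len(pmf_lo)] += (1.0 - frac) * pmf_lo
    out[: len(pmf_hi)] += frac * pmf_hi
    return out


def occupancy_analytic(config: CaptureConfig) -> OccupancyDistribution:
    """Exact fluorophore-occupancy distribution via the per-bin mixture
    of compound particle-count x label-count laws."""
    pop, n_lip_r, n_par_r, label = _binned_system(config)
    size = config.max_ncy5 + 1
    p_star = np.zeros(size)
    for i in range(len(n_lip_r)):
        share = n_lip_r[i] / config.n_liposomes
        if share <= 0:
            continue
        if n_par_r[i] <= 0:
            p_star[0] += share
            continue
        pmf = _particle_count_pmf(n_par_r[i], n_lip_r[i])
        occ_bin = np.zeros(size)
        power = np.zeros(size)
        power[0] = 1.0  # label distribution convolved k times
        occ_bin += pmf[0] * power
        for k in range(1, len(pmf)):
            power = _conv_tail(power, label, size)
            occ_bin += pmf[k] * power
        # truncated particle-count mass: park it in the tail bucket
        occ_bin[-1] += max(0.0, 1.0 - pmf.sum())
        p_star += share * occ_bin
    return OccupancyDistribution(p_star=p_star)


def _sparse_collisions(keys: np.ndarray, labels: np.ndarray, size: int):
    """Histogram of per-liposome visible-fluorophore sums from sparse
    (liposome key, N_Cy5) particle draws."""
    order = np.argsort(keys, kind="stable")
    keys = keys[order]
    labels = labels[order]
    boundaries = np.flatnonzero(np.diff(keys)) + 1
    starts = np.concatenate(([0], boundaries))
    sums = np.add.reduceat(labels, starts)
    sums = np.minimum(sums, size - 1)
    hist = np.bincount(sums.astype(np.int64), minlength=size).astype(float)
    return hist  # hist[0] counts occupied-but-invisible liposomes


def simulate_capture(config: CaptureConfig) -> OccupancyDistribution:
    """Seeded sparse Monte Carlo realization of the capture process."""
    pop, n_lip_r, n_par_r, label = _binned_system(config)
    weights = allocation_weights(pop).weights
    size = config.max_ncy5 + 1
    n_lip_int = np.round(n_lip_r).astype(np.int64)
    active = weights > 0
    n_lip_int[active] = np.maximum(n_lip_int[active], 1)

    ss = np.random.SeedSequence(config.seed)
    alloc_rng = np.random.default_rng(ss.spawn(1)[0])
    bin_seeds = ss.spawn(len(weights))

    n_particles = int(round(config.n_particles))
    counts = alloc_rng.multinomial(n_particles, weights)
    bases = np.concatenate(([0], np.cumsum(n_lip_int)[:-1]))
    all_keys, all_labels = [], []
    n_label = len(label)
    for i in np.flatnonzero(counts):
        rng = np.random.default_rng(bin_seeds[i])
        idx = rng.integers(0, n_lip_int[i], size=counts[i], dtype=np.int64)
        all_keys.append(bases[i] + idx)
        all_labels.append(rng.choice(n_label, size=counts[i], p=label))
    if not all_keys:
        return OccupancyDistribution(
            p_star=np.eye(size)[0], n_occupied=0
        )
    keys = np.concatenate(all_keys)
    labels = np.concatenate(all_labels)
    hist = _sparse_collisions(keys, labels, size)
    p_star = np.zeros(size)
    p_star[1:] = hist[1:] / config.n_liposomes
    p_star[0] = 1.0 - p_star[1:].sum()
    return OccupancyDistribution(p_star=p_star, n_occupied=float(hist[1:].sum()))


def simulate_joint_capture(
    f_dimer: float,
    n_subunits: float,
    n_liposomes: float,
    radius_dist: RadiusDistribution,
    yields: LabelingYields | None = None,
    r_min_dimer: float = DIMER_EXCLUSION_RADIUS_NM,
    sa_lipid: float = 0.6,
    seed: int | None = None,
    max_ncy5: int = 12,
) -> OccupancyDistribution:
    """Monte Carlo capture with monomers and dimers sharing one liposome
    population (co-capture of the two species in one vesicle allowed).

    ``f_dimer`` is the fraction of subunits in the dimer form; monomers
    are allocated over the full population and dimers over the
    dimer-accessible one, with a common liposome key space.
    """
    if not 0 <= f_dimer <= 1:
        raise ValueError("f_dimer must lie in [0, 1]")
    yields = yields if yields is not None else LabelingYields()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    n_mono = int(round((1.0 - f_dimer) * n_subunits))
    n_dim = int(round(f_dimer * n_subunits / 2.0))
    size = max_ncy5 + 1
    n_lip_int = np.round(radius_dist.probs * n_liposomes).astype(np.int64)
    bases = np.concatenate(([0], np.cumsum(n_lip_int)[:-1]))

    all_keys, all_labels = [], []
    for species, n_part, r_min, sub_ss in (
        ("monomer", n_mono, 0.0, ss.spawn(1)[0]),
        ("dimer", n_dim, r_min_dimer, ss.spawn(1)[0]),
    ):
        if n_part <= 0:
            continue
        pop = accessible_population(radius_dist, r_min)
        weights = allocation_weights(pop).weights
        label = (
            monomer_label_distribution(yields).probs
            if species == "monomer"
            else dimer_label_distribution(yields).probs
        )
        alloc_rng = np.random.default_rng(sub_ss.spawn(1)[0])
        bin_seeds = sub_ss.spawn(len(weights))
        counts = alloc_rng.multinomial(n_part, weights)
        for i in np.flatnonzero(counts):
            rng = np.random.default_rng(bin_seeds[i])
            n_lip_i = max(int(n_lip_int[i]), 1)
            idx = rng.integers(0, n_lip_i, size=counts[i], dtype=np.int64)
            all_keys.append(bases[i] + idx)
            all_labels.append(rng.choice(len(label), size=counts[i], p=label))
    if not all_keys:
        return OccupancyDistribution(p_star=np.eye(size)[0], n_occupied=0)
    hist = _sparse_collisions(
        np.concatenate(all_keys), np.concatenate(all_labels), size
    )
    p_star = np.zeros(size)
    p_star[1:] = hist[1:] / n_liposomes
    p_star[0] = 1.0 - p_star[1:].sum()
    return OccupancyDistribution(p_star=p_star, n_occupied=float(hist[1:].sum()))


def to_photobleach(occ: OccupancyDistribution, m: int = 3) -> PhotobleachDistribution:
    """Condition the occupancy distribution on visibility: P_n for
    n = 1..m-1 plus the m+ tail."""
    if m < 2:
        raise ValueError("m must be at least 2")
    visible = 1.0 - occ.f0
    if visible <= 0:
        raise ValueError("no visibly occupied liposomes (F0 = 1)")
    probs = np.zeros(m)
    upper = min(m, len(occ.p_star))
    probs[: upper - 1] = occ.p_star[1:upper] / visible
    probs[m - 1] = 1.0 - probs[: m - 1].sum()
    probs[m - 1] = max(probs[m - 1], 0.0)
    return PhotobleachDistribution(m=m, probs=probs)


def _config_for_chi(
    chi: float,
    species: str,
    radius_dist: RadiusDistribution,
    yields: LabelingYields,
    r_min: float,
    sa_lipid: float,
    n_liposomes: float,
    seed: int | None,
    max_ncy5: int,
) -> CaptureConfig:
    n_subunits = (
        chi * n_liposomes * 8.0 * math.pi * radius_dist.mean_sq_radius / sa_lipid
    )
    return CaptureConfig(
        species=species,
        n_subunits=n_subunits,
        n_liposomes=n_liposomes,
        radius_dist=radius_dist,
        r_min=r_min,
        yields=yields,
        sa_lipid=sa_lipid,
        seed=seed,
        max_ncy5=max_ncy5,
    )


def _ideal_occupancies(
    chi: float,
    yields: LabelingYields | None,
    radius_dist: RadiusDistribution | None,
    r_min_dimer: float,
    engine: str,
    n_liposomes: float,
    seed: int | None,
    max_ncy5: int,
) -> tuple[OccupancyDistribution, OccupancyDistribution]:
    from .liposomes import default_radius_distribution

    if not 0 < chi < 1:
        raise ValueError("chi must lie in (0, 1)")
    if chi > CHI_INDISTINGUISHABLE_WARN:
        warnings.warn(
            f"chi={chi:g} exceeds the {CHI_INDISTINGUISHABLE_WARN:g} "
            "subunit/lipid dynamic-range limit; monomer and dimer "
            "distributions may be indistinguishable",
            stacklevel=3,
        )
    if engine not in ("analytic", "mc"):
        raise ValueError("engine must be 'analytic' or 'mc'")
    yields = yields if yields is not None else LabelingYields()
    radius_dist = (
        radius_dist if radius_dist is not None else default_radius_distribution()
    )
    run = occupancy_analytic if engine == "analytic" else simulate_capture
    occs = []
    for species, r_min in (("monomer", 0.0), ("dimer", r_min_dimer)):
        cfg = _config_for_chi(
            chi, species, radius_dist, yields, r_min, 0.6, n_liposomes,
            seed, max_ncy5,
        )
        occs.append(run(cfg))
    return occs[0], occs[1]


def ideal_pair_at_chi(
    chi: float,
    yields: LabelingYields | None = None,
    radius_dist: RadiusDistribution | None = None,
    r_min_dimer: float = DIMER_EXCLUSION_RADIUS_NM,
    m: int = 5,
    engine: str = "analytic",
    n_liposomes: float = 1e12,
    seed: int | None = None,
    max_ncy5: int = 12,
) -> tuple[PhotobleachDistribution, PhotobleachDistribution]:
    """Ideal all-monomer and all-dimer step-count distributions at one
    observed mole fraction ``chi``."""
    occ_m, occ_d = _ideal_occupancies(
        chi, yields, radius_dist, r_min_dimer, engine, n_liposomes, seed,
        max_ncy5,
    )
    return to_photobleach(occ_m, m=m), to_photobleach(occ_d, m=m)


def ideal_distribution_pair(
    chi_grid,
    yields: LabelingYields | None = None,
    radius_dist: RadiusDistribution | None = None,
    r_min_dimer: float = DIMER_EXCLUSION_RADIUS_NM,
    m: int = 5,
    engine: str = "analytic",
    n_liposomes: float = 1e12,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tabulate ideal monomer/dimer distributions over a chi grid.

    Returns a DataFrame with columns chi, species, P1..P{m-1}, Pmplus, F0.
    """
    records = []
    for chi in np.atleast_1d(np.asarray(chi_grid, dtype=float)):
        occ_m, occ_d = _ideal_occupancies(
            chi, yields, radius_dist, r_min_dimer, engine, n_liposomes,
            seed, 12,
        )
        for species, occ in (("monomer", occ_m), ("dimer", occ_d)):
            pb = to_photobleach(occ, m=m)
            row = {"chi": float(chi), "species": species}
            for n in range(1, m):
                row[f"P{n}"] = pb.probs[n - 1]
            row[f"P{m}plus"] = pb.probs[m - 1]
            row["F0"] = occ.f0
            records.append(row)
    return pd.DataFrame.from_records(records)


def total_variation(a: OccupancyDistribution, b: OccupancyDistribution) -> float:
    """Total-variation distance between two occupancy distributions."""
    pa, pb = a.p_star, b.p_star
    size = max(len(pa), len(pb))
    pa = np.pad(pa, (0, size - len(pa)))
    pb = np.pad(pb, (0, size - len(pb)))
    return 0.5 * float(np.abs(pa - pb).sum())
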