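"""Seeded synthetic titration datasets with the statistical structure
the analysis assumes.

The generator plays the role of the experiment: pick a true equilibrium
constant and baseline, evaluate the isotherm at each density, and draw
per-sample step counts. Two noise models are provided:

* ``mixture`` — counts are multinomial draws from the F-weighted mixture
  of the ideal monomer and dimer step distributions (exactly the
  estimator's own model, so recovery tests isolate estimation error);
* ``joint`` — one Monte Carlo capture run with both species present in
  the same liposome population, so independent monomers and dimers can
  co-occupy a vesicle. This is the stricter realism test of the
  mixture approximation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .capture import (
    DIMER_EXCLUSION_RADIUS_NM,
    ideal_pair_at_chi,
    simulate_joint_capture,
    to_photobleach,
)
from .isotherm import isotherm_fdimer
from .labeling import LabelingYields
from .liposomes import RadiusDistribution, counts_for_chi

__all__ = [
    "TitrationDataset",
    "synth_radius_distribution",
    "generate_titration",
    "write_dataset",
    "read_dataset",
    "DEFAULT_TITRATION_CHI_STAR",
]

FORMAT_VERSION = "lipodimer-titration v1"

# Reactive mole fractions mimicking the experimental density series.
DEFAULT_TITRATION_CHI_STAR = tuple(
    chi / 2.0
    for chi in (7.5e-10, 3.8e-9, 7.5e-9, 3.8e-8, 7.5e-8, 3.8e-7, 7.5e-7,
                2.0e-6, 3.8e-6, 7.5e-6, 3.8e-5, 7.5e-5, 3.8e-4)
)


@dataclass
class TitrationDataset:
    """Per-density step counts plus the generating ground truth."""

    chi_star: np.ndarray  # reactive mole fractions, one per row
    counts: np.ndarray  # (n_rows, m) integer step counts
    n_spots: np.ndarray  # row sums
    m: int = 5
    truth: dict | None = field(default=None)

    def __post_init__(self) -> None:
        self.chi_star = np.asarray(self.chi_star, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.n_spots = np.asarray(self.n_spots, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.m:
            raise ValueError(f"counts must be (n_rows, {self.m})")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) != self.n_spots):
            raise ValueError("counts must sum to n_spots per row")
        if np.any(self.chi_star <= 0):
            raise ValueError("chi_star values must be positive")
        if np.any(np.diff(self.chi_star) < 0):
            raise ValueError("chi_star values must be sorted ascending")


def synth_radius_distribution(
    median_nm: float = 32.0,
    sigma_log: float = 0.35,
    r_range: tuple[float, float] = (10.0, 100.0),
    bin_width: float = 2.5,
    target_small_fraction: float | None = 0.40,
    small_radius_nm: float = 27.5,
) -> RadiusDistribution:
    """Truncated-lognormal stand-in for the cryo-EM radius histogram.

    Bins of ``bin_width`` nm on ``r_range``; if ``target_small_fraction``
    is given, the median is adjusted by bisection until the probability
    mass below ``small_radius_nm`` matches it to within 0.01.
    """
    lo, hi = r_range
    if not 0 < lo < hi <= 500:
        raise ValueError("r_range must lie within (0, 500] nm")
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def binned(median: float) -> np.ndarray:
        if sigma_log < 1e-9:
            probs = np.zeros(len(centers))
            probs[int(np.argmin(np.abs(centers - median)))] = 1.0
            return probs
        cdf = stats.lognorm.cdf(edges, s=sigma_log, scale=median)
        probs = np.diff(cdf)
        total = probs.sum()
        if total <= 0:
            raise ValueError("lognormal mass vanishes on r_range")
        return probs / total

    def small_mass(median: float) -> float:
        probs = binned(median)
        return float(probs[centers < small_radius_nm].sum())

    if target_small_fraction is not None and sigma_log >= 1e-9:
        lo_m, hi_m = lo + 1e-6, hi - 1e-6
        f_lo, f_hi = small_mass(lo_m), small_mass(hi_m)
        # small-radius mass decreases with the median
        if not (f_hi - 0.01 <= target_small_fraction <= f_lo + 0.01):
            raise ValueError(
                f"target small-radius fraction {target_small_fraction} is "
                f"unreachable on r_range (attainable {f_hi:.3f}-{f_lo:.3f})"
            )
        a, b = lo_m, hi_m
        for _ in range(200):
            mid = 0.5 * (a + b)
            if small_mass(mid) > target_small_fraction:
                a = mid
            else:
                b = mid
            if b - a < 1e-9:
                break
        median_nm = 0.5 * (a + b)
    return RadiusDistribution(radii=centers, probs=binned(median_nm))


def _joint_counts(
    chi_obs, f, n_spots, yields, radius_dist, r_min_dimer, m, rng, seed,
    sa_lipid,
):
    """One joint-capture MC realization, subsampled to n_spots spots."""
    target_occupied = max(20 * n_spots, 5000)
    n_sub, n_lip = counts_for_chi(
        chi_obs, target_occupied, radius_dist, yields, sa_lipid
    )
    occ = simulate_joint_capture(
        f_dimer=f, n_subunits=n_sub, n_liposomes=n_lip,
        radius_dist=radius_dist, yields=yields, r_min_dimer=r_min_dimer,
        sa_lipid=sa_lipid, seed=seed,
    )
    pb = to_photobleach(occ, m=m)
    return rng.multinomial(n_spots, pb.probs)


def generate_titration(
    true_k: float,
    y0: float = 0.0,
    chi_list=DEFAULT_TITRATION_CHI_STAR,
    n_spots: int = 300,
    mode: str = "mixture",
    seed: int | None = None,
    yields: LabelingYields | None = None,
    radius_dist: RadiusDistribution | None = None,
    r_min_dimer: float = DIMER_EXCLUSION_RADIUS_NM,
    m: int = 5,
    n_replicates: int = 1,
    sa_lipid: float = 0.6,
) -> TitrationDataset:
    """Draw a synthetic titration at reactive mole fractions ``chi_list``.

    Each density appears ``n_replicates`` times with independent counts.
    The capture model sees the observed mole fraction 2*chi_star.
    """
    if true_k <= 0:
        raise ValueError("true_k must be strictly positive")
    if n_spots < 1:
        raise ValueError("n_spots must be at least 1")
    if mode not in ("mixture", "joint"):
        raise ValueError("mode must be 'mixture' or 'joint'")
    from .liposomes import default_radius_distribution

    yields = yields if yields is not None else LabelingYields()
    radius_dist = (
        radius_dist if radius_dist is not None else default_radius_distribution()
    )
    chi_star = np.sort(np.asarray(chi_list, dtype=float))
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rows_chi, rows_counts = [], []
    for chi in chi_star:
        f = isotherm_fdimer(chi, true_k, y0)
        chi_obs = 2.0 * chi
        if mode == "mixture":
            p_m, p_d = ideal_pair_at_chi(
                chi_obs, yields=yields, radius_dist=radius_dist,
                r_min_dimer=r_min_dimer, m=m,
            )
            probs = (1.0 - f) * p_m.probs + f * p_d.probs
            probs = np.clip(probs, 0.0, None)
            probs /= probs.sum()
            for _ in range(n_replicates):
                rows_chi.append(chi)
                rows_counts.append(rng.multinomial(n_spots, probs))
        else:
            for _ in range(n_replicates):
                rows_chi.append(chi)
                rows_counts.append(
                    _joint_counts(
                        chi_obs, f, n_spots, yields, radius_dist,
                        r_min_dimer, m, rng, ss.spawn(1)[0], sa_lipid,
                    )
                )
    counts = np.asarray(rows_counts, dtype=np.int64)
    truth = {
        "k_chi_star": true_k,
        "y0": y0,
        "p_cy5": yields.p_cy5,
        "p_ns": yields.p_ns,
        "r_min_dimer": r_min_dimer,
        "seed": seed,
        "mode": mode,
    }
    return TitrationDataset(
        chi_star=np.asarray(rows_chi),
        counts=counts,
        n_spots=counts.sum(axis=1),
        m=m,
        truth=truth,
    )


def write_dataset(dataset: TitrationDataset, path: str | Path) -> None:
    """Delimited text with a commented JSON ground-truth header."""
    m = dataset.m
    cols = [f"n{i}" for i in range(1, m)] + [f"n{m}plus"]
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        if dataset.truth is not None:
            fh.write(f"# truth: {json.dumps(dataset.truth)}\n")
        fh.write("chi_star\t" + "\t".join(cols) + "\tn_spots\n")
        for chi, row, n in zip(dataset.chi_star, dataset.counts, dataset.n_spots):
            fh.write(
                f"{chi:.8e}\t" + "\t".join(str(int(c)) for c in row)
                + f"\t{int(n)}\n"
            )


def read_dataset(path: str | Path) -> TitrationDataset:
    """Lossless counterpart of :func:`write_dataset`."""
    truth = None
    header = None
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("truth:"):
                    try:
                        truth = json.loads(body[len("truth:"):])
                    except json.JSONDecodeError as exc:
                        raise ValueError(
                            f"{path}:{lineno}: malformed truth block"
                        ) from exc
                continue
            if header is None:
                header = line.split("\t")
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(parts)}"
                )
            try:
                chi = float(parts[0])
                counts = [int(p) for p in parts[1:-1]]
                n = int(parts[-1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            if any(c < 0 for c in counts):
                raise ValueError(f"{path}:{lineno}: negative count")
            if sum(counts) != n:
                raise ValueError(f"{path}:{lineno}: counts do not sum to n_spots")
            rows.append((chi, counts, n))
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    m = len(header) - 2
    return TitrationDataset(
        chi_star=np.array([r[0] for r in rows]),
        counts=np.array([r[1] for r in rows], dtype=np.int64),
        n_spots=np.array([r[2] for r in rows], dtype=np.int64),
        m=m,
        truth=truth,
    )
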