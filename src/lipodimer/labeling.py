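"""Fluorophore labeling stoichiometry of monomers and dimers.

Each subunit carries two maleimide-reactive positions: the engineered
cysteine (H234C) and a lumped "non-specific" site (lysines, the
N-terminus, partially exposed internal cysteines). The overall labeling
yield ``p_cy5`` measured by spectrophotometry is the sum of the specific
site yield ``p_site = p_cy5 - p_ns`` and the non-specific yield
``p_ns``, measured on constructs lacking the engineered cysteine.

A subunit therefore carries 0, 1 or 2 visible fluorophores; a dimer,
modeled as two independently labeled subunits, carries 0–4. These
distributions are what the capture simulator and the photobleaching
step-count model consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_P_CY5",
    "DEFAULT_P_NS",
    "LabelingYields",
    "SiteStateDistribution",
    "LabelCountDistribution",
    "site_state_distribution",
    "monomer_label_distribution",
    "dimer_label_distribution",
    "yield_from_absorbance",
]

# Pooled spectrophotometric yields over all constructs.
DEFAULT_P_CY5 = 0.72
DEFAULT_P_NS = 0.14


@dataclass(frozen=True)
class LabelingYields:
    """Per-subunit labeling probabilities (overall and non-specific)."""

    p_cy5: float = DEFAULT_P_CY5
    p_ns: float = DEFAULT_P_NS

    def __post_init__(self) -> None:
        if not 0 <= self.p_ns <= self.p_cy5 <= 1:
            raise ValueError(
                "labeling yields must satisfy 0 <= p_ns <= p_cy5 <= 1 "
                f"(got p_cy5={self.p_cy5}, p_ns={self.p_ns})"
            )

    @property
    def p_site(self) -> float:
        """Specific-site (engineered cysteine) labeling probability."""
        return self.p_cy5 - self.p_ns


@dataclass(frozen=True)
class SiteStateDistribution:
    """Joint (specific site, non-specific site) labeled/unlabeled states.

    ``o`` = unlabeled, ``x`` = labeled; first index is the specific site.
    """

    p_oo: float
    p_ox: float
    p_xo: float
    p_xx: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_oo, self.p_ox, self.p_xo, self.p_xx])


@dataclass(frozen=True)
class LabelCountDistribution:
    """Probability that a species carries N_Cy5 visible fluorophores."""

    species: str  # "monomer" | "dimer"
    probs: np.ndarray  # length 3 (monomer) or 5 (dimer)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        expected = {"monomer": 3, "dimer": 5}.get(self.species)
        if expected is None:
            raise ValueError("species must be 'monomer' or 'dimer'")
        if probs.shape != (expected,):
            raise ValueError(f"{self.species} needs {expected} probabilities")
        if np.any(probs < -1e-12) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def mean(self) -> float:
        return float(np.arange(len(self.probs)) @ self.probs)


def site_state_distribution(yields: LabelingYields) -> SiteStateDistribution:
    """Four pairwise products of the two independent site outcomes."""
    ps, pn = yields.p_site, yields.p_ns
    return SiteStateDistribution(
        p_oo=(1 - ps) * (1 - pn),
        p_ox=(1 - ps) * pn,
        p_xo=ps * (1 - pn),
        p_xx=ps * pn,
    )


def monomer_label_distribution(yields: LabelingYields) -> LabelCountDistribution:
    """Marginalize the site states over N_Cy5 = 0, 1, 2."""
    s = site_state_distribution(yields)
    probs = np.array([s.p_oo, s.p_ox + s.p_xo, s.p_xx])
    return LabelCountDistribution(species="monomer", probs=probs)


def dimer_label_distribution(yields: LabelingYields) -> LabelCountDistribution:
    """Two independent subunits: the monomer distribution convolved
    with itself, N_Cy5 = 0..4."""
    mono = monomer_label_distribution(yields).probs
    return LabelCountDistribution(species="dimer", probs=np.convolve(mono, mono))


def yield_from_absorbance(
    a280: float,
    a_fluor: float,
    cf_fluor: float,
    eps_subunit: float,
    eps_fluor: float,
) -> tuple[float, float]:
    """Subunit concentration (M) and labeling yield from a UV-Vis scan.

    The fluorophore absorbs at 280 nm too, so the protein absorbance is
    corrected by ``cf_fluor`` times the fluorophore peak absorbance
    before dividing by the subunit extinction coefficient. The yield is
    the fluorophore/subunit concentration ratio.
    """
    if eps_subunit <= 0 or eps_fluor <= 0:
        raise ValueError("extinction coefficients must be strictly positive")
    if a280 < 0 or a_fluor < 0 or cf_fluor < 0:
        raise ValueError("absorbances and correction factor must be non-negative")
    a_corrected = a280 - a_fluor * cf_fluor
    if a_corrected <= 0:
        raise ValueError(
            "corrected A280 is non-positive; absorbances are inconsistent"
        )
    subunit_conc = a_corrected / eps_subunit
    p_fluor = (a_fluor / eps_fluor) / subunit_conc
    return subunit_conc, p_fluor
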