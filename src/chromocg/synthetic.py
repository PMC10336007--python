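"""Synthetic inputs: contact maps with Micro-C-like structure, exact ideal-chain
ensembles, and the nucleosome-linker bead geometry estimate.

The synthetic map emulates the statistical structure of a nucleosome-resolution
contact probability matrix: power-law decay of contact probability with genomic
separation, block-enriched TAD-like domains, and optional multiplicative
log-normal noise.  It makes the whole pipeline testable with no download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_io import ContactMap

__all__ = [
    "SyntheticMapSpec",
    "UnitSystem",
    "generate_synthetic_map",
    "sample_ideal_chain",
    "estimate_nl_bead_geometry",
]


@dataclass
class SyntheticMapSpec:
    """Parameters of a synthetic contact map.

    ``P_ij = clip(A * s^(-gamma) * B_ij * eta_ij, 0, 1)`` for ``s = |i-j| >= 1``,
    unit diagonal.  ``B_ij = tad_boost`` when i and j fall inside the same
    TAD-like block, else 1.  ``eta_ij`` is symmetric log-normal noise with unit
    median and coefficient of variation ``noise_cv``.
    """

    n_bins: int = 200
    decay_exponent: float = 1.0
    amplitude: float = 0.9
    tad_boundaries: tuple[int, ...] = ()
    tad_boost: float = 1.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")
        if self.tad_boost < 1:
            raise ValueError("tad_boost must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        b = tuple(self.tad_boundaries)
        if any(x <= 0 or x >= self.n_bins for x in b) or list(b) != sorted(set(b)):
            raise ValueError(
                "tad_boundaries must be strictly increasing, within [1, n_bins-1]"
            )
        self.tad_boundaries = b


@dataclass
class UnitSystem:
    """Physical units of the reduced model.

    All internal computation is in reduced units (bead diameter sigma = 1,
    kBT = 1); conversion happens only at reporting time.  Defaults: a 200 bp
    nucleosome-linker bead of diameter 21 nm at kBT = 4.1 pN nm.
    """

    sigma_nm: float = 21.0
    bp_per_bead: int = 200
    kBT_pN_nm: float = 4.1

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0 or self.bp_per_bead <= 0 or self.kBT_pN_nm <= 0:
            raise ValueError("all unit parameters must be positive")

    def length_nm(self, x_sigma: float | np.ndarray) -> float | np.ndarray:
        return x_sigma * self.sigma_nm

    def spring_pN_per_um(self, k_kBT_per_sigma2: float) -> float:
        """Convert a spring constant from kBT/sigma^2 to pN/um."""
        return k_kBT_per_sigma2 * self.kBT_pN_nm / self.sigma_nm**2 * 1e3


def generate_synthetic_map(spec: SyntheticMapSpec) -> ContactMap:
    """Build the synthetic contact map described by ``spec`` (deterministic
    given ``spec.seed``)."""
    n = spec.n_bins
    i, j = np.indices((n, n))
    s = np.abs(i - j).astype(float)
    with np.errstate(divide="ignore"):
        p = spec.amplitude * np.where(s > 0, s, 1.0) ** (-spec.decay_exponent)

    if spec.tad_boundaries and spec.tad_boost > 1:
        edges = (0, *spec.tad_boundaries, n)
        block = np.zeros((n, n), dtype=bool)
        for lo, hi in zip(edges[:-1], edges[1:]):
            block[lo:hi, lo:hi] = True
        p = np.where(block, p * spec.tad_boost, p)

    if spec.noise_cv > 0:
        # unit-median log-normal: exp(N(0, s^2)) with CV^2 = exp(s^2) - 1
        sln = np.sqrt(np.log1p(spec.noise_cv**2))
        rng = np.random.default_rng(spec.seed)
        g = rng.normal(0.0, sln, size=(n, n))
        eta = np.exp(np.triu(g) + np.triu(g, 1).T)  # symmetric draw
        p = p * eta

    p = np.clip(p, 0.0, 1.0)
    p = 0.5 * (p + p.T)
    np.fill_diagonal(p, 1.0)
    return ContactMap(p, resolution_bp=200, chrom="synth", start_bp=0)


def sample_ideal_chain(
    n_beads: int, n_samples: int, bond_length: float = 1.0, seed: int = 0
):
    """Exact equilibrium ensemble of an ideal (phantom) bead-spring chain.

    Step vectors are independent isotropic Gaussian triples scaled so that
    ``<step^2> = b^2``; this samples the Gaussian-chain Boltzmann distribution
    directly, with no integrator error.  Returns an :class:`~chromocg.dynamics.Ensemble`.
    """
    from .dynamics import Ensemble  # deferred: avoid import cycle

    if n_beads < 2:
        raise ValueError("n_beads must be >= 2")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    comp_sd = bond_length / np.sqrt(3.0)
    steps = rng.normal(0.0, comp_sd, size=(n_samples, n_beads - 1, 3))
    coords = np.zeros((n_samples, n_beads, 3))
    coords[:, 1:] = np.cumsum(steps, axis=1)
    return Ensemble(
        coords=coords,
        provenance={"kind": "ideal", "bond_length": bond_length, "seed": seed},
    )


def estimate_nl_bead_geometry(
    units: UnitSystem | None = None,
    linker_bp: int = 50,
    nucleosome_diameter_nm: float = 11.0,
    rise_nm_per_bp: float = 0.34,
) -> tuple[float, float]:
    """Geometric bounds on the size of a nucleosome-linker bead.

    Two neighbouring nucleosomes joined by a straight rigid linker sit at most
    ``diameter + linker_bp * rise`` apart (centre to centre, edge-attached
    linker); two unconnected nucleosomes can approach to one nucleosome
    diameter.  With an 11 nm core and a 50 bp linker at 0.34 nm/bp this gives
    (28 nm, 11 nm), bracketing the ~21 nm effective bead diameter.
    """
    if linker_bp < 0 or nucleosome_diameter_nm <= 0 or rise_nm_per_bp <= 0:
        raise ValueError("geometry arguments must be positive (linker_bp >= 0)")
    max_separation = nucleosome_diameter_nm + linker_bp * rise_nm_per_bp
    min_approach = nucleosome_diameter_nm
    return float(max_separation), float(min_approach)
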