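"""Systematic coarse-graining of bead-spring ensembles.

A coarse-grained (CG) bead is the centroid of ``n_b`` consecutive fine-grained
beads.  From an ensemble this module measures the scale-dependent observables
of the CG polymer: window radius of gyration Rg, CG bond length l_cg, bond
angle theta_cg = pi - alpha (alpha the angle between successive bond vectors),
signed dihedral phi_cg, the overlap parameter O = 2<Rg>/<l_cg>, the effective
spring constant K_cg = kBT / var(l_cg), angle distributions with the
sin-measure correction, Boltzmann-inverted effective potentials, two-Gaussian
angle deconvolution, and cosine-form bending-stiffness fits.

Profiles along the genome use sliding windows; distributions and CG polymer
quantities (bonds, angles, dihedrals, K_cg, O) use the blocked disjoint
partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics import Ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "CGSpec",
    "CGSummary",
    "EffectivePotential",
    "AngleDeconvolution",
    "StiffnessFit",
    "AngleDistribution",
    "radius_of_gyration",
    "cg_trace",
    "rg_profile",
    "cg_profile",
    "cg_bond_lengths",
    "cg_bond_angles",
    "cg_dihedrals",
    "overlap_parameter",
    "spring_constant",
    "angle_distribution",
    "effective_potential",
    "deconvolute_two_gaussians",
    "fit_bending_stiffness",
    "angle_dihedral_energy_map",
    "nonbonded_overlap_fraction",
    "cg_summary",
]


@dataclass
class CGSpec:
    """Coarse-graining window: ``n_b`` beads per CG bead, blocked or sliding."""

    n_b: int = 1
    mode: str = "blocked"

    def __post_init__(self) -> None:
        if self.n_b < 1:
            raise ValueError("n_b must be >= 1")
        if self.mode not in ("blocked", "sliding"):
            raise ValueError("mode must be 'blocked' or 'sliding'")


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square distance of points from their centroid (equal masses)."""
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 1:
        raise ValueError("coords must have shape (n >= 1, 3)")
    c = x - x.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))


def cg_trace(coords: np.ndarray, spec: CGSpec | int) -> np.ndarray:
    """CG-bead centres of one conformation.

    Blocked mode: centroid of each consecutive disjoint block of ``n_b`` beads
    (a trailing remainder is dropped with a warning).  Sliding mode: centroid
    of every window ``[i, i + n_b)``.
    """
    if isinstance(spec, int):
        spec = CGSpec(n_b=spec)
    x = np.asarray(coords, dtype=float)
    n = x.shape[0]
    nb = spec.n_b
    if n < nb:
        raise ValueError(f"chain of {n} beads cannot be grouped by n_b={nb}")
    if spec.mode == "blocked":
        n_cg = n // nb
        if n % nb:
            logger.warning("dropping %d trailing beads (N=%d, n_b=%d)",
                           n % nb, n, nb)
        return x[: n_cg * nb].reshape(n_cg, nb, 3).mean(axis=1)
    # sliding
    cs = np.cumsum(np.vstack([np.zeros(3), x]), axis=0)
    return (cs[nb:] - cs[:-nb]) / nb


def _window_rg(coords: np.ndarray, nb: int) -> np.ndarray:
    """Rg of every sliding window of nb beads, for an (S, N, 3) stack.

    Uses Rg^2 = <|x|^2> - |<x>|^2 with cumulative sums over the chain.
    """
    X = np.asarray(coords, dtype=float)
    S, N, _ = X.shape
    z = np.zeros((S, 1))
    cs = np.concatenate([np.zeros((S, 1, 3)), np.cumsum(X, axis=1)], axis=1)
    cs2 = np.concatenate([z, np.cumsum((X**2).sum(axis=2), axis=1)], axis=1)
    mean_x = (cs[:, nb:] - cs[:, :-nb]) / nb
    mean_x2 = (cs2[:, nb:] - cs2[:, :-nb]) / nb
    rg2 = np.maximum(mean_x2 - (mean_x**2).sum(axis=2), 0.0)
    return np.sqrt(rg2)


def rg_profile(ensemble: Ensemble, spec: CGSpec | int) -> pd.DataFrame:
    """Ensemble mean and SD of sliding-window Rg per genomic start index."""
    nb = spec.n_b if isinstance(spec, CGSpec) else int(spec)
    rg = _window_rg(ensemble.coords, nb)
    return pd.DataFrame(
        {
            "window_start": np.arange(rg.shape[1]),
            "n_b": nb,
            "statistic": "Rg",
            "mean": rg.mean(axis=0),
            "sd": rg.std(axis=0),
            "n": rg.shape[0],
        }
    )


def cg_profile(ensemble: Ensemble, spec: CGSpec | int) -> pd.DataFrame:
    """Sliding-window profiles of Rg, l_cg, theta_cg and overlap along the
    genome, in the tidy layout (window_start, n_b, statistic, mean, sd, n)."""
    nb = spec.n_b if isinstance(spec, CGSpec) else int(spec)
    X = ensemble.coords
    S, N, _ = X.shape
    frames = [rg_profile(ensemble, nb)]

    centers = np.stack([cg_trace(X[s], CGSpec(nb, "sliding")) for s in range(S)])
    # l_cg^i: distance between centroids of windows starting i and i + n_b
    if centers.shape[1] > nb:
        d = np.linalg.norm(centers[:, nb:] - centers[:, :-nb], axis=2)
        frames.append(pd.DataFrame({
            "window_start": np.arange(d.shape[1]),
            "n_b": nb, "statistic": "l_cg",
            "mean": d.mean(axis=0), "sd": d.std(axis=0), "n": S,
        }))
        rg = _window_rg(X, nb)[:, : d.shape[1]]
        o = 2.0 * rg.mean(axis=0) / d.mean(axis=0)
        frames.append(pd.DataFrame({
            "window_start": np.arange(d.shape[1]),
            "n_b": nb, "statistic": "overlap",
            "mean": o, "sd": np.nan, "n": S,
        }))
    # theta_cg^i from three consecutive sliding centroids spaced n_b apart
    if centers.shape[1] > 2 * nb:
        a = centers[:, :-2 * nb]
        b = centers[:, nb:-nb]
        c = centers[:, 2 * nb:]
        th = _angles_deg(b - a, c - b)
        frames.append(pd.DataFrame({
            "window_start": np.arange(th.shape[1]),
            "n_b": nb, "statistic": "theta_cg",
            "mean": np.nanmean(th, axis=0), "sd": np.nanstd(th, axis=0), "n": S,
        }))
    return pd.concat(frames, ignore_index=True)


def cg_bond_lengths(trace: np.ndarray) -> np.ndarray:
    """Euclidean distances between successive CG centres."""
    t = np.asarray(trace, dtype=float)
    if t.shape[0] < 2:
        raise ValueError("need at least 2 CG centres")
    return np.linalg.norm(np.diff(t, axis=0), axis=1)


def _angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """theta_cg = 180 - angle(u, v) in degrees; NaN where a vector vanishes."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    bad = (nu < 1e-12) | (nv < 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosa = (u * v).sum(axis=-1) / (nu * nv)
    cosa = np.clip(cosa, -1.0, 1.0)
    th = 180.0 - np.degrees(np.arccos(cosa))
    th = np.where(bad, np.nan, th)
    return th


def cg_bond_angles(trace: np.ndarray) -> np.ndarray:
    """Bond angles theta_cg = pi - alpha at interior CG beads, in degrees.

    Collinear forward = 180 deg, complete fold-back = 0 deg.  Angles at
    zero-length bonds are undefined and excluded with a warning.
    """
    t = np.asarray(trace, dtype=float)
    if t.shape[0] < 3:
        raise ValueError("need at least 3 CG centres")
    b = np.diff(t, axis=0)
    th = _angles_deg(b[:-1], b[1:])
    n_bad = int(np.isnan(th).sum())
    if n_bad:
        logger.warning("excluding %d angles at zero-length CG bonds", n_bad)
    return th[~np.isnan(th)]


def cg_dihedrals(trace: np.ndarray) -> np.ndarray:
    """Signed dihedrals in (-180, 180] degrees (right-handed atan2 convention;
    planar cis = 0, planar trans = 180).  Collinear triples are excluded."""
    t = np.asarray(trace, dtype=float)
    if t.shape[0] < 4:
        raise ValueError("need at least 4 CG centres")
    b1 = np.diff(t, axis=0)[:-2]
    b2 = np.diff(t, axis=0)[1:-1]
    b3 = np.diff(t, axis=0)[2:]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    bad = (np.linalg.norm(n1, axis=1) < 1e-12) | (
        np.linalg.norm(n2, axis=1) < 1e-12
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        x = (n1 * n2).sum(axis=1) * b2n
        y = (np.cross(n1, n2) * b2).sum(axis=1)
        phi = np.degrees(np.arctan2(y, x))
    phi = np.where(phi <= -180.0, phi + 360.0, phi)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("excluding %d dihedrals at collinear triples", n_bad)
    return phi[~bad]


def overlap_parameter(mean_rg: float, mean_lcg: float) -> float:
    """O = 2<Rg>/<l_cg>; O > 1 signals interpenetrating CG beads."""
    if mean_lcg <= 0:
        raise ValueError("mean l_cg must be positive")
    return 2.0 * mean_rg / mean_lcg


def spring_constant(lengths: np.ndarray, kBT: float = 1.0) -> float:
    """Effective CG spring constant K_cg = kBT / (<l^2> - <l>^2) (population
    variance).  Raises on zero variance (rigid bond)."""
    x = np.asarray(lengths, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 bond lengths")
    var = x.var()
    if var == 0:
        raise ValueError("rigid bond: zero variance in l_cg")
    return kBT / var


@dataclass
class AngleDistribution:
    """Binned P(theta) and its sin-measure-corrected density P~ = P/sin."""

    edges: np.ndarray  # degrees
    p: np.ndarray  # density, unit integral over degrees
    p_tilde: np.ndarray  # NaN in the masked outermost bins

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def angle_distribution(angles: np.ndarray, n_bins: int = 36) -> AngleDistribution:
    """Histogram of bond angles on [0, 180] degrees, normalized to unit
    integral, plus the sin-corrected density ``P~ = P / sin(theta)`` evaluated
    at bin centres (outermost bins masked, where sin -> 0)."""
    a = np.asarray(angles, dtype=float)
    p, edges = np.histogram(a, bins=n_bins, range=(0.0, 180.0), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        pt = p / np.sin(np.radians(centers))
    pt[0] = np.nan
    pt[-1] = np.nan
    return AngleDistribution(edges, p, pt)


@dataclass
class EffectivePotential:
    """Boltzmann-inverted potential V = -kBT ln(density) on a grid, minimum
    shifted to zero; NaN marks empty (masked) bins."""

    variable: str
    grid: np.ndarray
    v: np.ndarray
    normalization: str = "min-shifted to 0; empty bins masked"


def effective_potential(
    grid: np.ndarray, density: np.ndarray, variable: str = "l"
) -> EffectivePotential:
    """V = -ln(density) in kBT on occupied bins; empty bins are masked, not
    extrapolated; the minimum is shifted to zero for reporting."""
    grid = np.asarray(grid, dtype=float)
    d = np.asarray(density, dtype=float)
    occ = np.isfinite(d) & (d > 0)
    if not occ.any():
        raise ValueError("all-empty distribution")
    v = np.full_like(d, np.nan)
    v[occ] = -np.log(d[occ])
    v -= np.nanmin(v)
    return EffectivePotential(variable, grid, v)


@dataclass
class AngleDeconvolution:
    """Two-Gaussian decomposition of an angle distribution (means and SDs in
    degrees; weights sum to 1)."""

    mean1: float
    sd1: float
    weight1: float
    mean2: float
    sd2: float
    weight2: float
    residual: float  # RMS residual relative to the mean density
    ok: bool

    POOR_FIT_THRESHOLD = 0.10


def _gauss(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def deconvolute_two_gaussians(
    grid: np.ndarray, density: np.ndarray
) -> AngleDeconvolution:
    """Nonlinear least squares of ``w N(mu1, s1) + (1-w) N(mu2, s2)`` to a
    binned angle density; means ordered mu1 < mu2 after the fit; multi-start
    over 5 fixed initializations, best residual wins."""
    x = np.asarray(grid, dtype=float)
    y = np.asarray(density, dtype=float)
    occ = np.isfinite(y)
    x, y = x[occ], y[occ]
    if x.size < 20:
        raise ValueError("need >= 20 occupied bins for deconvolution")

    def resid(p):
        w, m1, s1, m2, s2 = p
        return w * _gauss(x, m1, s1) + (1 - w) * _gauss(x, m2, s2) - y

    starts = [
        (0.5, 60.0, 15.0, 110.0, 25.0),
        (0.3, 50.0, 10.0, 120.0, 30.0),
        (0.5, 40.0, 20.0, 100.0, 40.0),
        (0.7, 70.0, 25.0, 130.0, 20.0),
        (0.5, 90.0, 45.0, 90.0, 45.0),
    ]
    lb = [0.0, 0.0, 1.0, 0.0, 1.0]
    ub = [1.0, 180.0, 90.0, 180.0, 90.0]
    best = None
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub))
        except Exception:  # pragma: no cover - optimizer edge case
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("two-Gaussian deconvolution failed from all starts")
    w, m1, s1, m2, s2 = best.x
    if m1 > m2:  # the mixture is symmetric under component swap
        w, m1, s1, m2, s2 = 1 - w, m2, s2, m1, s1
    rms = float(np.sqrt(np.mean(best.fun**2)))
    rel = rms / max(y.mean(), 1e-300)
    return AngleDeconvolution(
        mean1=float(m1), sd1=float(s1), weight1=float(w),
        mean2=float(m2), sd2=float(s2), weight2=float(1 - w),
        residual=rel, ok=rel <= AngleDeconvolution.POOR_FIT_THRESHOLD,
    )


@dataclass
class StiffnessFit:
    """Cosine bending potential fit V = offset + (k_b/2)(1 + cos(theta - theta0))."""

    k_b: float  # kBT
    theta0: float  # degrees
    residual: float


def fit_bending_stiffness(potential: EffectivePotential) -> StiffnessFit:
    """Least squares of ``(k_b/2)(1 + cos(theta - theta0))`` plus an additive
    offset to an effective angle potential (theta in degrees, V in kBT)."""
    occ = np.isfinite(potential.v)
    th = np.radians(potential.grid[occ])
    v = potential.v[occ]
    if th.size < 10:
        raise ValueError("need >= 10 potential points")

    def resid(p):
        kb, th0, c = p
        return c + 0.5 * kb * (1 + np.cos(th - th0)) - v

    sol = least_squares(
        resid, (1.0, np.radians(90.0), 0.0),
        bounds=([0.0, -np.pi, -np.inf], [np.inf, 2 * np.pi, np.inf]),
    )
    return StiffnessFit(
        k_b=float(sol.x[0]),
        theta0=float(np.degrees(sol.x[1])),
        residual=float(np.sqrt(np.mean(sol.fun**2))),
    )


def angle_dihedral_energy_map(
    v_theta: EffectivePotential, v_phi: EffectivePotential
) -> np.ndarray:
    """Additive (theta, phi) energy surface V(theta, phi) = V(theta) + V(phi)
    on the tensor grid (assumes the two distributions are independent);
    NaN where either factor is masked."""
    return v_theta.v[:, None] + v_phi.v[None, :]


def nonbonded_overlap_fraction(
    ensemble: Ensemble, spec: CGSpec | int, l_cg_ref: float
) -> tuple[np.ndarray, float]:
    """Fraction of (configuration, CG pair) events with centre distance below
    ``l_cg_ref``, for pairs at least 2 CG bonds apart.

    Returns (per-pair fraction matrix with NaN on excluded pairs, aggregate
    fraction over all counted events).
    """
    nb = spec.n_b if isinstance(spec, CGSpec) else int(spec)
    centers = np.stack(
        [cg_trace(c, CGSpec(nb, "blocked")) for c in ensemble.coords]
    )
    S, n_cg, _ = centers.shape
    d = np.linalg.norm(centers[:, :, None, :] - centers[:, None, :, :], axis=3)
    below = (d < l_cg_ref).mean(axis=0)
    i, j = np.indices((n_cg, n_cg))
    far = np.abs(i - j) >= 2
    per_pair = np.where(far, below, np.nan)
    aggregate = float(below[far].mean()) if far.any() else float("nan")
    return per_pair, aggregate


@dataclass
class CGSummary:
    """Ensemble-aggregated blocked CG observables at one coarse-graining size."""

    n_b: int
    mean_rg: float
    sd_rg: float
    mean_lcg: float
    sd_lcg: float
    k_cg: float  # kBT / sigma^2
    k_cg_lcg2: float  # kBT / l_cg^2
    overlap: float
    theta_deg: np.ndarray
    phi_deg: np.ndarray
    lcg: np.ndarray


def cg_summary(ensemble: Ensemble, n_b: int) -> CGSummary:
    """Blocked-partition CG observables pooled over the ensemble."""
    rgs = []
    lcgs = []
    thetas = []
    phis = []
    spec = CGSpec(n_b, "blocked")
    for conf in ensemble.coords:
        n_cg = conf.shape[0] // n_b
        blocks = conf[: n_cg * n_b].reshape(n_cg, n_b, 3)
        c = blocks - blocks.mean(axis=1, keepdims=True)
        rgs.append(np.sqrt((c**2).sum(axis=2).mean(axis=1)))
        trace = blocks.mean(axis=1)
        if n_cg >= 2:
            lcgs.append(cg_bond_lengths(trace))
        if n_cg >= 3:
            thetas.append(cg_bond_angles(trace))
        if n_cg >= 4:
            phis.append(cg_dihedrals(trace))
    rg = np.concatenate(rgs)
    lcg = np.concatenate(lcgs) if lcgs else np.empty(0)
    theta = np.concatenate(thetas) if thetas else np.empty(0)
    phi = np.concatenate(phis) if phis else np.empty(0)
    k = spring_constant(lcg) if lcg.size >= 2 and lcg.var() > 0 else np.nan
    mean_lcg = lcg.mean() if lcg.size else np.nan
    return CGSummary(
        n_b=n_b,
        mean_rg=float(rg.mean()),
        sd_rg=float(rg.std()),
        mean_lcg=float(mean_lcg),
        sd_lcg=float(lcg.std()) if lcg.size else np.nan,
        k_cg=float(k),
        k_cg_lcg2=float(k * mean_lcg**2) if np.isfinite(k) else np.nan,
        overlap=overlap_parameter(rg.mean(), mean_lcg) if lcg.size else np.nan,
        theta_deg=theta,
        phi_deg=phi,
        lcg=lcg,
    )
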