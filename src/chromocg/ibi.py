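"""Iterative Boltzmann inversion (IBI) and the parametric soft pair potential.

IBI refines a tabulated non-bonded pair potential so that the simulated
distribution of distances between non-bonded CG beads matches a target
distribution:

    V_{i+1}(r) = V_i(r) + alpha(r) kBT ln( P_i(r) / P_target(r) ),

with the damping ``alpha(r) = a exp(-r^2/2)`` (a = 0.2, r in CG bond-length
units) keeping the resulting potential short-ranged.  Convergence is monitored
with KL(P_target || P_i) and the best iterate is returned.

The converged table is summarized by a bounded soft form with independently
tunable softness and depth:

    V_soft(r) = V0 [1 - (r/r_m)^eta1]^eta2 - eps          (r < r_m)
              = (eps/2) [cos(mu r^2 + nu) - 1]            (r_m <= r < r_c)
              = 0                                         (r >= r_c)

where mu and nu are fixed analytically by continuity and differentiability at
r_m and r_c.  Softness is measured as 1/F_max (inverse maximum repulsive
force) and eps is the attraction depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dynamics import Ensemble, ForceField, LangevinParams, run_langevin_batch
from .validation import kl_divergence

logger = logging.getLogger(__name__)

__all__ = [
    "TabulatedPotential",
    "IBIState",
    "SoftPotentialParams",
    "CGPolymerSpec",
    "ibi_update",
    "run_ibi",
    "soft_potential_eval",
    "solve_attractive_phase",
    "fit_soft_potential",
    "softness_and_depth",
    "simulate_cg_with_soft_potential",
    "tabulate_soft_potential",
]

ALPHA_PREFACTOR = 0.2
MIN_BIN_COUNT = 10


@dataclass
class TabulatedPotential:
    """Potential energy on a uniform distance grid (kBT vs sigma units);
    zero at and beyond ``cutoff``."""

    r: np.ndarray
    v: np.ndarray
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.r.ndim != 1 or self.r.size < 4 or np.any(np.diff(self.r) <= 0):
            raise ValueError("grid must be strictly increasing with >= 4 points")
        if self.r.shape != self.v.shape or not np.all(np.isfinite(self.v)):
            raise ValueError("V must be finite and match the grid")
        if self.cutoff is None:
            self.cutoff = float(self.r[-1])

    def to_tsv(self, path: str) -> None:
        np.savetxt(path, np.column_stack([self.r, self.v]),
                   fmt="%.8g", delimiter="\t", header="r_sigma\tV_kBT")

    @classmethod
    def from_tsv(cls, path: str) -> "TabulatedPotential":
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1])


@dataclass
class IBIState:
    """One step of the IBI fixed-point iteration."""

    iteration: int
    potential: TabulatedPotential
    p_current: np.ndarray
    p_target: np.ndarray
    counts: np.ndarray | None = None
    alpha_prefactor: float = ALPHA_PREFACTOR
    kl_history: list = field(default_factory=list)


def alpha_of_r(r: np.ndarray, a: float = ALPHA_PREFACTOR) -> np.ndarray:
    """IBI damping factor ``a exp(-r^2 / 2)``."""
    return a * np.exp(-np.asarray(r, dtype=float) ** 2 / 2.0)


def ibi_update(
    state: IBIState, floor: float = 1e-8, smooth: bool = False
) -> TabulatedPotential:
    """One update of the IBI relation.

    Bins where either distribution falls below ``floor`` (or, when counts are
    available, with fewer than 10 events) leave V unchanged; V at and beyond
    the cutoff is reset to 0 and the table shifted so V(cutoff) = 0.  With
    ``smooth`` the *increment* is 3-point averaged (smoothing the accumulated
    potential instead would blur it a little more every iteration).
    """
    pot = state.potential
    r = pot.r
    p_i = np.asarray(state.p_current, dtype=float)
    p_t = np.asarray(state.p_target, dtype=float)
    if p_i.shape != r.shape or p_t.shape != r.shape:
        raise ValueError("distributions must live on the potential grid")
    v = pot.v.copy()
    ok = (p_i > floor) & (p_t > floor)
    if state.counts is not None:
        ok &= np.asarray(state.counts) >= MIN_BIN_COUNT
    dv = alpha_of_r(r, state.alpha_prefactor) * np.log(
        np.where(ok, p_i / np.where(p_t > 0, p_t, 1.0), 1.0)
    )
    dv = np.where(ok, dv, 0.0)
    if smooth:
        dv = _smooth3(dv)
    v = v + dv
    # anchor the tail: zero at and beyond the cutoff, shift so V(cutoff) = 0
    beyond = r >= pot.cutoff
    inside = ~beyond
    if inside.any():
        v[inside] -= v[inside][-1]
    v[beyond] = 0.0
    return TabulatedPotential(r, v, pot.cutoff)


def _smooth3(v: np.ndarray) -> np.ndarray:
    out = v.copy()
    out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    return out


@dataclass
class CGPolymerSpec:
    """A coarse-grained bead-spring chain: harmonic bonds with rest length
    ``l_cg`` and stiffness ``k_cg`` (from CG measurements) plus a non-bonded
    term (None, TabulatedPotential, or SoftPotentialParams)."""

    n_cg: int = 50
    l_cg: float = 1.0
    k_cg: float = 50.0
    nonbonded: object | None = None

    def __post_init__(self) -> None:
        if self.n_cg < 2 or self.l_cg <= 0 or self.k_cg <= 0:
            raise ValueError("CG polymer parameters must be positive, n_cg >= 2")


def _nb_pair(spec: CGPolymerSpec):
    nb = spec.nonbonded
    if nb is None or isinstance(nb, TabulatedPotential):
        return nb
    if isinstance(nb, SoftPotentialParams):
        return tabulate_soft_potential(nb)
    raise TypeError(f"unsupported non-bonded term {type(nb).__name__}")


def _simulate_nonbonded_hist(
    spec: CGPolymerSpec,
    pair,
    edges: np.ndarray,
    seed: int,
    n_replicas: int = 12,
    n_steps: int = 4000,
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium non-bonded distance histogram of the CG chain.

    Returns (density, counts) on ``edges``; pools the second half of the
    sampled frames over ``n_replicas`` independent replicas.
    """
    from .synthetic import sample_ideal_chain

    ff = ForceField(chain_k=spec.k_cg, chain_r0=spec.l_cg, pair=pair)
    ss = np.random.SeedSequence(seed)
    s_init, s_run = [int(x) % 2**31 for x in ss.generate_state(2)]
    init = sample_ideal_chain(
        spec.n_cg, n_replicas, bond_length=spec.l_cg, seed=s_init
    ).coords
    params = LangevinParams(
        dt=0.005, n_steps=n_steps, seed=s_run, sample_every=max(1, n_steps // 20)
    )
    _, _, _, samples = run_langevin_batch(init, ff, params, return_samples=True)
    frames = samples[:, samples.shape[1] // 2:].reshape(-1, spec.n_cg, 3)
    i, j = np.triu_indices(spec.n_cg, k=2)
    d = np.linalg.norm(frames[:, i, :] - frames[:, j, :], axis=2).ravel()
    counts, _ = np.histogram(d, bins=edges)
    total = counts.sum()
    width = edges[1] - edges[0]
    dens = counts / (total * width) if total else counts.astype(float)
    return dens, counts


def run_ibi(
    target_density: np.ndarray,
    edges: np.ndarray,
    spec: CGPolymerSpec,
    max_iter: int = 30,
    kl_tol: float = 0.01,
    seed: int = 0,
    smooth: bool = True,
    alpha_prefactor: float = ALPHA_PREFACTOR,
    n_replicas: int = 12,
    n_steps: int = 4000,
) -> tuple[TabulatedPotential, list[IBIState]]:
    """Derive the non-bonded potential whose CG simulation reproduces
    ``target_density`` (non-bonded distance distribution on ``edges``).

    Starts from a flat potential V = 0; each iteration simulates the CG chain
    with the current table, measures P_i(r), applies :func:`ibi_update`
    (optionally 3-point smoothed) and records KL(P_target || P_i).  Stops at
    ``KL < kl_tol`` or ``max_iter``; returns the best-KL iterate and the
    state history.  Deterministic given ``seed``.
    """
    edges = np.asarray(edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p_t = np.asarray(target_density, dtype=float)
    if p_t.shape != centers.shape:
        raise ValueError("target density must have one value per bin")
    width = edges[1] - edges[0]
    p_t = p_t / (p_t.sum() * width)
    cutoff = float(edges[-1])
    pot = TabulatedPotential(centers, np.zeros_like(centers), cutoff)
    history: list[IBIState] = []
    best_pot, best_kl = pot, np.inf
    kl_hist: list[float] = []
    ss = np.random.SeedSequence(seed)
    for it in range(max_iter):
        pair = pot if np.any(pot.v != 0) else None
        dens, counts = _simulate_nonbonded_hist(
            spec, pair, edges, int(ss.generate_state(it + 1)[-1]) % 2**31,
            n_replicas=n_replicas, n_steps=n_steps,
        )
        kl = kl_divergence(p_t * width, dens * width)
        kl_hist.append(kl)
        state = IBIState(
            iteration=it, potential=pot, p_current=dens, p_target=p_t,
            counts=counts, alpha_prefactor=alpha_prefactor,
            kl_history=list(kl_hist),
        )
        history.append(state)
        if kl < best_kl:
            best_kl, best_pot = kl, pot
        if kl < kl_tol:
            logger.info("IBI converged at iteration %d (KL=%.4g)", it, kl)
            break
        pot = ibi_update(state, smooth=smooth)
    return best_pot, history


# ---------------------------------------------------------------------------
# parametric soft potential


@dataclass
class SoftPotentialParams:
    """Parameters of the bounded soft pair potential (see module docstring).

    ``r_m`` is the location of the minimum, ``eps`` its depth, ``V0`` the
    height of the repulsion at r = 0 (V(0) = V0 - eps), ``eta1``/``eta2``
    shape the repulsive branch, ``mu``/``nu`` phase the cosine attraction,
    ``r_c`` is the cutoff.  ``r_m == r_c`` is allowed only for the degenerate
    purely repulsive case eps = 0 (empty attractive branch).
    """

    V0: float
    r_m: float
    eps: float
    eta1: float
    eta2: float
    mu: float
    nu: float
    r_c: float

    def __post_init__(self) -> None:
        if self.eps < 0 or self.eta1 <= 0 or self.eta2 <= 0:
            raise ValueError("eps must be >= 0; eta1, eta2 > 0")
        if not (0 < self.r_m < self.r_c or (self.eps == 0 and self.r_m == self.r_c)):
            raise ValueError("need 0 < r_m < r_c (r_m = r_c only when eps = 0)")


def solve_attractive_phase(r_m: float, r_c: float) -> tuple[float, float]:
    """Phase parameters of the cosine attraction from its boundary conditions.

    Solving ``cos(mu r_m^2 + nu) = -1`` and ``cos(mu r_c^2 + nu) = 1`` with a
    single half-period between them gives ``mu = pi / (r_c^2 - r_m^2)`` and
    ``nu = pi - mu r_m^2``; the slope then vanishes at both ends, so the
    branch matches C^1 at r_m (for eta2 > 1) and at r_c.
    """
    if not 0 < r_m < r_c:
        raise ValueError("need 0 < r_m < r_c")
    mu = np.pi / (r_c**2 - r_m**2)
    nu = np.pi - mu * r_m**2
    return float(mu), float(nu)


def soft_potential_eval(params: SoftPotentialParams, r) -> np.ndarray | float:
    """Piecewise evaluation of the soft potential (kBT)."""
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    v = np.zeros_like(r)
    rep = r < params.r_m
    if rep.any():
        base = 1.0 - (r[rep] / params.r_m) ** params.eta1
        v[rep] = params.V0 * base**params.eta2 - params.eps
    att = (r >= params.r_m) & (r < params.r_c)
    if att.any() and params.eps > 0:
        v[att] = 0.5 * params.eps * (
            np.cos(params.mu * r[att] ** 2 + params.nu) - 1.0
        )
    return float(v[0]) if scalar else v


def tabulate_soft_potential(
    params: SoftPotentialParams, dr: float = 0.01
) -> TabulatedPotential:
    """Tabulate the soft form on a uniform grid up to its cutoff."""
    r = np.arange(0.0, params.r_c + dr, dr)
    return TabulatedPotential(r, soft_potential_eval(params, r), params.r_c)


def fit_soft_potential(
    tab: TabulatedPotential,
) -> tuple[SoftPotentialParams, float]:
    """Fit the parametric soft form to a tabulated potential.

    ``r_m`` comes from the tabulated argmin, ``eps`` from the depth, ``r_c``
    from the first zero crossing beyond ``r_m`` (linear interpolation);
    ``mu``/``nu`` follow analytically; ``V0``, ``eta1``, ``eta2`` are fit by
    least squares on the repulsive branch with ``eta2 >= 1`` enforced.
    Returns (params, RMS residual over the table's support).
    """
    r, v = tab.r, tab.v
    k_min = int(np.argmin(v))
    if v[k_min] < 0:
        if k_min == 0 or k_min == r.size - 1:
            raise ValueError("no interior minimum in the table")
        eps = float(-v[k_min])
        r_m = float(r[k_min])
        r_c = _first_zero_after(r, v, k_min)
        mu, nu = solve_attractive_phase(r_m, r_c)
    else:
        # purely repulsive: degenerate depth, attractive branch absent
        eps = 0.0
        r_c = _first_zero_after(r, v, 0)
        r_m = r_c
        mu, nu = 0.0, np.pi

    rep = r < r_m
    rr, vv = r[rep], v[rep]
    if rr.size < 3:
        raise ValueError("too few repulsive-branch points to fit")

    def resid(p):
        v0, e1, e2 = p
        base = np.maximum(1.0 - (rr / r_m) ** e1, 0.0)
        return v0 * base**e2 - eps - vv

    v0_guess = max(vv[0] + eps, 1e-3)
    # eta1 >= 1 keeps the repulsive force finite at the origin; eta2 >= 1
    # makes the repulsive branch meet the minimum with zero slope
    sol = least_squares(
        resid, (v0_guess, 2.0, 2.0),
        bounds=([1e-9, 1.0, 1.0], [np.inf, 50.0, 50.0]),
    )
    params = SoftPotentialParams(
        V0=float(sol.x[0]), r_m=r_m, eps=eps,
        eta1=float(sol.x[1]), eta2=float(sol.x[2]), mu=mu, nu=nu, r_c=r_c,
    )
    support = r <= r_c
    rms = float(
        np.sqrt(np.mean((soft_potential_eval(params, r[support]) - v[support]) ** 2))
    )
    return params, rms


def _first_zero_after(r: np.ndarray, v: np.ndarray, k0: int) -> float:
    """First zero crossing of v at or after index k0, by linear interpolation."""
    for k in range(k0, r.size - 1):
        if v[k] == 0.0:
            return float(r[k])
        if np.sign(v[k + 1]) != np.sign(v[k]):
            t = v[k] / (v[k] - v[k + 1])
            return float(r[k] + t * (r[k + 1] - r[k]))
    return float(r[-1])


def softness_and_depth(
    pot: SoftPotentialParams | TabulatedPotential, n_grid: int = 2000
) -> tuple[float, float]:
    """Softness 1/F_max (inverse of the maximum repulsive force -dV/dr) and
    depth eps of a pair potential."""
    if isinstance(pot, SoftPotentialParams):
        eps = pot.eps
        r = np.linspace(1e-6, pot.r_m * (1 - 1e-9), n_grid)
        v = soft_potential_eval(pot, r)
        f = -np.gradient(v, r)
    else:
        from scipy.interpolate import CubicSpline

        v_min = pot.v.min()
        eps = float(-v_min) if v_min < 0 else 0.0
        cs = CubicSpline(pot.r, pot.v, bc_type="natural")
        k_min = int(np.argmin(pot.v)) if eps > 0 else pot.v.size - 1
        r_hi = pot.r[k_min] if k_min > 0 else pot.r[-1]
        r = np.linspace(pot.r[0] + 1e-9, r_hi, n_grid)
        f = -cs(r, 1)
    f_max = float(f.max())
    if f_max <= 0:
        raise ValueError("no repulsive force; softness undefined")
    return 1.0 / f_max, float(eps)


def simulate_cg_with_soft_potential(
    spec: CGPolymerSpec,
    n_samples: int,
    seed: int = 0,
    n_steps: int = 6000,
    dt: float = 0.005,
) -> Ensemble:
    """Langevin sampling of the CG chain (harmonic bonds l_cg, K_cg and the
    spec's non-bonded term); one equilibrated conformation per sample."""
    from .synthetic import sample_ideal_chain

    pair = _nb_pair(spec)
    ff = ForceField(chain_k=spec.k_cg, chain_r0=spec.l_cg, pair=pair)
    ss = np.random.SeedSequence(seed)
    s_init, s_run = [int(x) % 2**31 for x in ss.generate_state(2)]
    init = sample_ideal_chain(
        spec.n_cg, n_samples, bond_length=spec.l_cg, seed=s_init
    ).coords
    params = LangevinParams(
        dt=dt, n_steps=n_steps, seed=s_run, sample_every=max(1, n_steps // 20)
    )
    final, rg, _ = run_langevin_batch(init, ff, params)
    return Ensemble(
        coords=final,
        provenance={
            "kind": "cg_soft", "n_cg": spec.n_cg, "l_cg": spec.l_cg,
            "k_cg": spec.k_cg, "seed": seed, "n_steps": n_steps,
        },
    )
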