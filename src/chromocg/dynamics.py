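"""Langevin dynamics for bead-spring chains.

A chain of N beads (mass 1) in reduced units (sigma = 1, kBT = 1 by default)
with harmonic chain bonds, optional per-configuration harmonic constraint
springs, and one of the pair interactions: none, WCA, truncated-shifted
Lennard-Jones, or a tabulated potential (cubic interpolation, force from the
analytic derivative).  Integration is BAOAB discretized Langevin dynamics;
the contract is distributional (Boltzmann sampling), not trajectory-level
agreement with any external MD engine.

Also provides the SAW and collapsed-globule control ensembles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
from scipy.interpolate import CubicSpline

from . import _kernels as K

logger = logging.getLogger(__name__)

__all__ = [
    "PairWCA",
    "PairLJ",
    "ForceField",
    "LangevinParams",
    "Trajectory",
    "Ensemble",
    "evaluate_forces",
    "run_langevin",
    "run_langevin_batch",
    "detect_equilibration",
    "make_control_ensemble",
    "initial_conformation",
    "radius_of_gyration_series",
]


@dataclass
class PairWCA:
    """Purely repulsive Weeks-Chandler-Andersen pair term (LJ truncated and
    shifted at ``r = 2^(1/6) sigma``)."""

    epsilon: float = 1.0
    sigma: float = 1.0


@dataclass
class PairLJ:
    """Lennard-Jones pair term, truncated and shifted to zero at ``r_cut``."""

    epsilon: float = 1.0
    sigma: float = 1.0
    r_cut: float = 2.5

    def __post_init__(self) -> None:
        if self.r_cut <= self.sigma:
            raise ValueError("LJ r_cut must exceed sigma")


@dataclass
class ForceField:
    """Bonded and non-bonded interactions of a bead-spring chain.

    ``pair`` is None, :class:`PairWCA`, :class:`PairLJ`, or any object with
    ``r``/``v``/``cutoff`` attributes (a tabulated potential).
    ``constraint_bonds`` holds (i, j, k, r0) springs for single-conformation
    evaluation; ensemble-level per-configuration bonds are passed separately.
    """

    chain_k: float = 100.0
    chain_r0: float = 1.0
    pair: object | None = None
    constraint_bonds: Sequence[tuple[int, int, float, float]] = field(
        default_factory=tuple
    )

    def __post_init__(self) -> None:
        if self.chain_k <= 0 or self.chain_r0 <= 0:
            raise ValueError("chain bond stiffness and rest length must be positive")

    def max_stiffness(self) -> float:
        k = self.chain_k
        for (_, _, kb, _) in self.constraint_bonds:
            k = max(k, kb)
        return k


@dataclass
class LangevinParams:
    """BAOAB integrator settings (reduced units)."""

    dt: float = 0.005
    friction: float = 1.0
    temperature: float = 1.0
    n_steps: int = 10_000
    seed: int = 0
    sample_every: int = 100

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction <= 0 or self.temperature < 0:
            raise ValueError("dt, friction must be positive; temperature >= 0")
        if self.n_steps < 1 or self.sample_every < 1:
            raise ValueError("n_steps and sample_every must be >= 1")


@dataclass
class Trajectory:
    """Sampled output of one Langevin run."""

    samples: np.ndarray  # (n_rec, N, 3)
    rg: np.ndarray  # (n_rec,)
    energies: np.ndarray  # potential energy at sample times
    kinetic: np.ndarray  # kinetic energy at sample times
    max_bond: np.ndarray
    burn_index: int
    equilibrated: bool

    @property
    def production(self) -> np.ndarray:
        return self.samples[self.burn_index:]


@dataclass
class Ensemble:
    """A set of conformations of equal bead count.

    ``coords`` has shape (n_samples, N, 3); ``bonds`` optionally holds one
    (m_s, 2) int array of constraint-bond pairs per conformation.
    """

    coords: np.ndarray
    bonds: list[np.ndarray] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_samples, N, 3)")
        if self.coords.shape[1] < 2:
            raise ValueError("conformations need at least 2 beads")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.bonds is not None and len(self.bonds) != self.coords.shape[0]:
            raise ValueError("one bond list per conformation required")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("coords", data=self.coords)
            for key, val in self.provenance.items():
                f["coords"].attrs[str(key)] = str(val)
            if self.bonds is not None:
                g = f.create_group("bonds")
                for s, b in enumerate(self.bonds):
                    g.create_dataset(str(s), data=np.asarray(b, dtype=np.int64))

    @classmethod
    def load(cls, path: str) -> "Ensemble":
        with h5py.File(path, "r") as f:
            coords = f["coords"][...]
            prov = {k: v for k, v in f["coords"].attrs.items()}
            bonds = None
            if "bonds" in f:
                bonds = [
                    f["bonds"][str(s)][...] for s in range(coords.shape[0])
                ]
        return cls(coords=coords, bonds=bonds, provenance=prov)

    def export_xyz(self, path: str, index: int = 0) -> None:
        x = self.coords[index]
        with open(path, "w") as f:
            f.write(f"{x.shape[0]}\nconformation {index}\n")
            for a in x:
                f.write(f"C {a[0]:.6f} {a[1]:.6f} {a[2]:.6f}\n")


# ---------------------------------------------------------------------------
# force-field marshalling for the kernels

_EMPTY_TC = np.zeros((1, 4))


def _pair_args(pair) -> tuple:
    """Map a pair term onto kernel scalars (kind, eps, sig, rcut, tab...)."""
    if pair is None:
        return (K.PAIR_NONE, 0.0, 0.0, 0.0, 0.0, 1.0, _EMPTY_TC, 0.0)
    if isinstance(pair, PairWCA):
        return (K.PAIR_WCA, pair.epsilon, pair.sigma, 0.0, 0.0, 1.0,
                _EMPTY_TC, 0.0)
    if isinstance(pair, PairLJ):
        return (K.PAIR_LJ, pair.epsilon, pair.sigma, pair.r_cut, 0.0, 1.0,
                _EMPTY_TC, 0.0)
    # tabulated: duck-typed on r / v / cutoff
    r = np.asarray(pair.r, dtype=float)
    v = np.asarray(pair.v, dtype=float)
    dr = np.diff(r)
    if r.size < 4 or not np.allclose(dr, dr[0], rtol=1e-6):
        raise ValueError("tabulated potential needs a uniform grid of >= 4 points")
    cs = CubicSpline(r, v, bc_type="natural")
    # cs.c is (4, n_int) highest power first -> (n_int, 4) lowest first
    tc = np.ascontiguousarray(cs.c[::-1].T)
    cutoff = float(getattr(pair, "cutoff", r[-1]))
    return (K.PAIR_TAB, 0.0, 0.0, 0.0, float(r[0]), float(dr[0]), tc, cutoff)


def _bond_arrays(bond_lists, n_samples):
    """Flatten per-configuration (i, j, k, r0) bonds into CSR arrays."""
    ptr = np.zeros(n_samples + 1, dtype=np.int64)
    if bond_lists is None:
        z = np.zeros(0)
        return ptr, np.zeros(0, np.int64), np.zeros(0, np.int64), z, z
    bi, bj, bk, br = [], [], [], []
    for s in range(n_samples):
        for (i, j, k, r0) in bond_lists[s]:
            bi.append(i)
            bj.append(j)
            bk.append(k)
            br.append(r0)
        ptr[s + 1] = len(bi)
    return (ptr, np.asarray(bi, np.int64), np.asarray(bj, np.int64),
            np.asarray(bk, float), np.asarray(br, float))


def evaluate_forces(coords: np.ndarray, ff: ForceField) -> tuple[float, np.ndarray]:
    """Potential energy and per-bead forces (exact negative gradients) for one
    conformation under ``ff``, including its ``constraint_bonds``."""
    x = np.ascontiguousarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 2:
        raise ValueError("coords must have shape (N >= 2, 3)")
    f = np.zeros_like(x)
    pk, pe_, ps, prc, tx0, tdx, tc, tcut = _pair_args(ff.pair)
    cb = ff.constraint_bonds
    ci = np.asarray([b[0] for b in cb], np.int64)
    cj = np.asarray([b[1] for b in cb], np.int64)
    ck = np.asarray([b[2] for b in cb], float)
    cr = np.asarray([b[3] for b in cb], float)
    pe = K._forces_one(x, f, ff.chain_k, ff.chain_r0,
                       pk, pe_, ps, prc, tx0, tdx, tc, tcut, ci, cj, ck, cr)
    return float(pe), f


def _check_stability(ff: ForceField, params: LangevinParams) -> None:
    # harmonic stability: dt * omega_max <= 0.1 (omega = sqrt(k/m), m = 1)
    kmax = ff.max_stiffness()
    if params.dt * np.sqrt(kmax) > 0.1:
        warnings.warn(
            f"dt = {params.dt} exceeds the stability guideline "
            f"0.1/sqrt(k_max) = {0.1 / np.sqrt(kmax):.4g}; integration may "
            "be inaccurate",
            RuntimeWarning,
            stacklevel=3,
        )


def detect_equilibration(series: np.ndarray, window: int) -> tuple[int, bool]:
    """First index at which consecutive window means of a scalar series agree
    within 2%.

    Returns ``(index, equilibrated)``; ``(len(series), False)`` when the
    criterion is never met.  Requires ``len(series) >= 2*window``.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if window < 1 or n < 2 * window:
        raise ValueError("series must be at least twice the window length")
    for t in range(0, n - 2 * window + 1):
        m1 = series[t:t + window].mean()
        m2 = series[t + window:t + 2 * window].mean()
        ref = abs(m1) if m1 != 0 else 1e-12
        if abs(m2 - m1) < 0.02 * ref:
            return t, True
    return n, False


def run_langevin(
    coords: np.ndarray,
    ff: ForceField,
    params: LangevinParams,
) -> Trajectory:
    """Integrate one conformation and return sampled frames.

    Frames are recorded every ``sample_every`` steps; the burn-in index is
    determined from the window-mean radius-of-gyration criterion of
    :func:`detect_equilibration` and exposed as ``Trajectory.burn_index``
    (``production`` holds the post-burn-in frames).  Deterministic given
    ``params.seed``.
    """
    _check_stability(ff, params)
    x = np.ascontiguousarray(coords, dtype=float)[None, ...].copy()
    n = x.shape[1]
    rng = np.random.default_rng(params.seed)
    if params.temperature > 0:
        v = rng.normal(0.0, np.sqrt(params.temperature), size=x.shape)
    else:
        v = np.zeros_like(x)
    n_rec = params.n_steps // params.sample_every
    if n_rec < 1:
        raise ValueError("n_steps must allow at least one sample")
    rg = np.empty((1, n_rec))
    pe = np.empty((1, n_rec))
    ke = np.empty((1, n_rec))
    mb = np.empty((1, n_rec))
    samples = np.empty((1, n_rec, n, 3))
    pk, pe_, ps, prc, tx0, tdx, tc, tcut = _pair_args(ff.pair)
    ptr, ci, cj, ck, cr = _bond_arrays(
        [list(ff.constraint_bonds)] if ff.constraint_bonds else None, 1
    )
    status = K.baoab_batch(
        x, v, params.dt, params.friction, params.temperature,
        params.n_steps, int(params.seed) % 2**31, params.sample_every,
        ff.chain_k, ff.chain_r0, pk, pe_, ps, prc, tx0, tdx, tc, tcut,
        ptr, ci, cj, ck, cr, rg, pe, ke, mb, 1, samples,
    )
    if status >= 0:
        raise RuntimeError(
            f"non-finite coordinates at step {status}; reduce dt or stiffness"
        )
    if n_rec >= 4:
        burn, ok = detect_equilibration(rg[0], max(1, n_rec // 4))
    else:
        burn, ok = 0, True
    if not ok:
        logger.warning("trajectory flagged not equilibrated (n_rec=%d)", n_rec)
        burn = 0
    return Trajectory(samples[0], rg[0], pe[0], ke[0], mb[0], burn, ok)


def run_langevin_batch(
    coords: np.ndarray,
    ff: ForceField,
    params: LangevinParams,
    bond_lists: list | None = None,
    return_samples: bool = False,
) -> tuple:
    """Integrate a batch of chains sharing a force field, each with its own
    constraint bonds.

    Returns ``(final_coords, rg_series, max_bond_series)`` where the series
    have shape (S, n_rec); with ``return_samples=True`` a fourth element of
    shape (S, n_rec, N, 3) holds the sampled frames.
    """
    _check_stability(ff, params)
    x = np.ascontiguousarray(coords, dtype=float).copy()
    S, n, _ = x.shape
    rng = np.random.default_rng(params.seed)
    if params.temperature > 0:
        v = rng.normal(0.0, np.sqrt(params.temperature), size=x.shape)
    else:
        v = np.zeros_like(x)
    n_rec = max(1, params.n_steps // params.sample_every)
    rg = np.empty((S, n_rec))
    pe = np.empty((S, n_rec))
    ke = np.empty((S, n_rec))
    mb = np.empty((S, n_rec))
    samples = (
        np.empty((S, n_rec, n, 3)) if return_samples else np.empty((1, 1, 1, 3))
    )
    pk, pe_, ps, prc, tx0, tdx, tc, tcut = _pair_args(ff.pair)
    if bond_lists is not None and ff.constraint_bonds:
        raise ValueError("give constraint bonds per configuration or in ff, not both")
    if bond_lists is None and ff.constraint_bonds:
        bond_lists = [list(ff.constraint_bonds)] * S
    ptr, ci, cj, ck, cr = _bond_arrays(bond_lists, S)
    status = K.baoab_batch(
        x, v, params.dt, params.friction, params.temperature,
        params.n_steps, int(params.seed) % 2**31, params.sample_every,
        ff.chain_k, ff.chain_r0, pk, pe_, ps, prc, tx0, tdx, tc, tcut,
        ptr, ci, cj, ck, cr, rg, pe, ke, mb, int(return_samples), samples,
    )
    if status >= 0:
        raise RuntimeError(
            f"non-finite coordinates at step {status}; reduce dt or stiffness"
        )
    if return_samples:
        return x, rg, mb, samples
    return x, rg, mb


def initial_conformation(
    n_beads: int, seed: int = 0, step: float = 1.0, min_dist: float = 0.8
) -> np.ndarray:
    """Self-avoiding random placement: unit steps in random directions,
    retrying steps that land within ``min_dist`` of any earlier bead; falls
    back to a helical (spiral) layout after 1000 consecutive failures."""
    rng = np.random.default_rng(seed)
    x = np.zeros((n_beads, 3))
    for a in range(1, n_beads):
        placed = False
        for _ in range(1000):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = x[a - 1] + step * u
            d2 = np.sum((x[:a] - cand) ** 2, axis=1)
            if np.all(d2 >= min_dist**2):
                x[a] = cand
                placed = True
                break
        if not placed:
            return _spiral_layout(n_beads, step)
    return x


def _spiral_layout(n_beads: int, step: float) -> np.ndarray:
    """Non-overlapping helix with bead spacing ``step`` along the contour."""
    radius = 2.0 * step
    pitch = 1.2 * step
    dtheta = 2.0 * np.arcsin(
        np.sqrt(max(step**2 - pitch**2, 0.01 * step**2)) / (2 * radius)
    )
    t = np.arange(n_beads) * dtheta
    return np.column_stack(
        (radius * np.cos(t), radius * np.sin(t), np.arange(n_beads) * pitch)
    )


def make_control_ensemble(
    kind: str,
    n_beads: int,
    n_samples: int,
    params: LangevinParams | None = None,
) -> Ensemble:
    """Equilibrated control ensembles.

    ``kind='saw'``: chain bonds + WCA(eps=1, sigma=1) — the self-avoiding walk.
    ``kind='globule'``: chain bonds + attractive LJ(eps=1 kBT, sigma=1,
    r_cut=2.5) — a collapsed chain.  Each sample starts from an independent
    self-avoiding random placement; equilibration is verified with the
    window-mean Rg detector and failures are logged and flagged.
    """
    if n_beads < 50:
        raise ValueError("control ensembles need n_beads >= 50 for statistics")
    if kind == "saw":
        ff = ForceField(pair=PairWCA(1.0, 1.0))
    elif kind == "globule":
        ff = ForceField(pair=PairLJ(1.0, 1.0, 2.5))
    else:
        raise ValueError(f"unknown control kind {kind!r}")
    params = params or LangevinParams(n_steps=40_000, sample_every=200)
    ss = np.random.SeedSequence(params.seed)
    init_seeds = ss.generate_state(n_samples + 1)
    x0 = np.stack(
        [initial_conformation(n_beads, int(s) % 2**31) for s in init_seeds[:-1]]
    )
    run = LangevinParams(
        dt=params.dt, friction=params.friction, temperature=params.temperature,
        n_steps=params.n_steps, seed=int(init_seeds[-1]) % 2**31,
        sample_every=params.sample_every,
    )
    final, rg, mb = run_langevin_batch(x0, ff, run)
    n_rec = rg.shape[1]
    window = max(1, n_rec // 4)
    n_bad = 0
    for s in range(n_samples):
        burn = 0
        if n_rec >= 2 * window:
            burn, ok = detect_equilibration(rg[s], window)
            n_bad += not ok
            if not ok:  # no plateau found: check the latter half instead
                burn = n_rec // 2
        if mb[s, burn:].max() >= 3 * ff.chain_r0:
            raise RuntimeError(f"chain {s} broke (bond > 3 r0); run rejected")
    if n_bad:
        logger.warning("%d/%d control chains flagged not equilibrated",
                       n_bad, n_samples)
    return Ensemble(
        coords=final,
        provenance={
            "kind": kind, "n_beads": n_beads, "n_samples": n_samples,
            "seed": params.seed, "n_steps": params.n_steps, "dt": params.dt,
            "not_equilibrated": n_bad,
        },
    )


def radius_of_gyration_series(coords: np.ndarray) -> np.ndarray:
    """Rg of each conformation in an (S, N, 3) stack."""
    c = coords - coords.mean(axis=1, keepdims=True)
    return np.sqrt((c**2).sum(axis=2).mean(axis=1))
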