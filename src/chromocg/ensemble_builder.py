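"""Two-step construction of a fine-grained ensemble consistent with a contact
probability map.

Step 1 bonds each prominent contact (i, j) in every configuration where an
independent uniform draw ``r_n < P_ij``, then equilibrates.  Step 2 goes
beyond the prominent contacts: for every pair, the ``P_ij`` fraction of
configurations whose current 3D distances r_ij are smallest receive a
harmonic spring (configurations already bonded in step 1 count toward the
quota), followed by a second equilibration.  The ensemble contact map is
the fraction of configurations with ``r_ij`` below a cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .contact_io import ContactMap, ProminentContactSet, find_prominent_contacts
from .dynamics import (
    Ensemble,
    ForceField,
    LangevinParams,
    PairWCA,
    detect_equilibration,
    initial_conformation,
    run_langevin_batch,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BondAssignment",
    "assign_step1_bonds",
    "assign_step2_bonds",
    "build_ensemble",
    "ensemble_contact_map",
    "DEFAULT_CONSTRAINT_K",
    "DEFAULT_CONSTRAINT_R0",
    "DEFAULT_CONTACT_CUTOFF",
]

# constraint-spring defaults: strong enough to bring pairs into contact range,
# soft enough for dt = 0.005
DEFAULT_CONSTRAINT_K = 50.0
DEFAULT_CONSTRAINT_R0 = 1.0
DEFAULT_CONTACT_CUTOFF = 2.0  # sigma; must exceed the constraint rest length


@dataclass
class BondAssignment:
    """Per-configuration constraint-bond pairs from one assignment step."""

    pairs: list[np.ndarray]  # one (m_s, 2) int array per configuration
    step: int = 1
    seed: int = 0

    @property
    def n_configs(self) -> int:
        return len(self.pairs)

    def counts_per_pair(self) -> dict[tuple[int, int], int]:
        out: dict[tuple[int, int], int] = {}
        for arr in self.pairs:
            for i, j in arr:
                out[(int(i), int(j))] = out.get((int(i), int(j)), 0) + 1
        return out


def assign_step1_bonds(
    prominent: ProminentContactSet, n_configs: int, seed: int = 0
) -> BondAssignment:
    """Bernoulli(P_ij) bond draws for every (configuration, prominent pair).

    Draws are consumed in a fixed order — configurations outer, pairs sorted
    by (i, j) inner — so the assignment is deterministic given ``seed``.
    """
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs_sorted = sorted(prominent.pairs)
    out = []
    for _ in range(n_configs):
        chosen = [
            (i, j) for (i, j, p) in pairs_sorted if rng.uniform() < p
        ]
        out.append(np.asarray(chosen, dtype=np.int64).reshape(-1, 2))
    return BondAssignment(out, step=1, seed=seed)


def assign_step2_bonds(
    ensemble: Ensemble,
    cmap: ContactMap,
    existing: BondAssignment,
) -> BondAssignment:
    """Distance-ranked quota bonding of all pairs beyond chain neighbours.

    For every pair (i, j) with ``j - i >= 2`` and ``P_ij >= 1/n_configs``
    (smaller probabilities have quota zero), the quota
    ``round_half_even(P_ij * n_configs)`` of configurations with the smallest
    current r_ij are bonded.  Exact distance ties at the quota boundary are
    broken toward the lower configuration index.  Step-1 bonds are retained
    everywhere and count toward the quota.  Quotas are computed from one
    distance snapshot, so pair processing order is immaterial.
    """
    S = ensemble.n_samples
    n = ensemble.n_beads
    if cmap.n_bins != n:
        raise ValueError(
            f"map has {cmap.n_bins} bins but ensemble has {n} beads"
        )
    if existing.n_configs != S:
        raise ValueError("existing assignment does not match the ensemble")

    iu, ju = np.triu_indices(n, k=2)
    p = cmap.matrix[iu, ju]
    keep = p >= 1.0 / S
    iu, ju, p = iu[keep], ju[keep], p[keep]

    # distances for all candidate pairs in all configurations: (S, n_pairs)
    d = np.linalg.norm(
        ensemble.coords[:, iu, :] - ensemble.coords[:, ju, :], axis=2
    )
    # round-half-even quotas
    quotas = np.rint(p * S).astype(int)

    bonded = [set(map(tuple, existing.pairs[s])) for s in range(S)]
    order = np.argsort(d, axis=0, kind="stable")  # ascending r_ij, ties by index
    new_pairs: list[list[tuple[int, int]]] = [[] for _ in range(S)]
    for col in range(iu.size):
        q = quotas[col]
        if q == 0:
            continue
        pair = (int(iu[col]), int(ju[col]))
        for s in order[:q, col]:
            if pair not in bonded[s]:
                new_pairs[int(s)].append(pair)
    out = []
    for s in range(S):
        merged = sorted(bonded[s] | set(new_pairs[s]))
        out.append(np.asarray(merged, dtype=np.int64).reshape(-1, 2))
    return BondAssignment(out, step=2, seed=existing.seed)


def _equilibrate(
    coords: np.ndarray,
    bond_pairs: list[np.ndarray],
    ff: ForceField,
    params: LangevinParams,
    constraint_k: float,
    constraint_r0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Run Langevin on the batch with the given constraint bonds; returns
    final coordinates and a per-configuration equilibration flag."""
    S = coords.shape[0]
    bond_lists = [
        [(int(i), int(j), constraint_k, constraint_r0) for i, j in bp]
        for bp in bond_pairs
    ]
    final, rg, mb = run_langevin_batch(coords, ff, params, bond_lists)
    n_rec = rg.shape[1]
    window = max(1, n_rec // 4)
    ok = np.ones(S, dtype=bool)
    for s in range(S):
        burn = 0
        if n_rec >= 2 * window:
            burn, ok[s] = detect_equilibration(rg[s], window)
        if not ok[s]:
            continue
        # chain must stay intact over the accepted (equilibrated) portion;
        # the insertion transient is allowed to stretch bonds
        if mb[s, burn:].max() >= 3 * ff.chain_r0:
            logger.warning("configuration %d rejected: chain bond > 3 r0", s)
            ok[s] = False
    return final, ok


def build_ensemble(
    cmap: ContactMap,
    n_configs: int = 200,
    ff: ForceField | None = None,
    params: LangevinParams | None = None,
    constraint_k: float = DEFAULT_CONSTRAINT_K,
    constraint_r0: float = DEFAULT_CONSTRAINT_R0,
) -> Ensemble:
    """Full two-step pipeline: initialize, step-1 bonds, equilibrate, step-2
    bonds, equilibrate again.

    Per-configuration seeds derive from ``params.seed``; configurations that
    fail the equilibration check (or break a chain bond) are excluded with a
    logged count.  The second equilibration runs twice as many steps as the
    first: step-2 inserts an order of magnitude more springs, and the
    resulting collapse relaxes more slowly.
    """
    n = cmap.n_bins
    ff = ff or ForceField(pair=PairWCA(1.0, 1.0))
    params = params or LangevinParams(n_steps=6000, sample_every=100)
    ss = np.random.SeedSequence(params.seed)
    seeds = ss.generate_state(4)

    x0 = np.stack(
        [
            initial_conformation(n, int(s) % 2**31)
            for s in np.random.SeedSequence(seeds[0]).generate_state(n_configs)
        ]
    )
    prominent = find_prominent_contacts(cmap)
    step1 = assign_step1_bonds(prominent, n_configs, seed=int(seeds[1]) % 2**31)

    p1 = LangevinParams(
        dt=params.dt, friction=params.friction, temperature=params.temperature,
        n_steps=params.n_steps, seed=int(seeds[2]) % 2**31,
        sample_every=params.sample_every,
    )
    x1, ok1 = _equilibrate(x0, step1.pairs, ff, p1, constraint_k, constraint_r0)

    ens1 = Ensemble(coords=x1, bonds=step1.pairs)
    step2 = assign_step2_bonds(ens1, cmap, step1)

    p2 = LangevinParams(
        dt=params.dt, friction=params.friction, temperature=params.temperature,
        n_steps=2 * params.n_steps, seed=int(seeds[3]) % 2**31,
        sample_every=params.sample_every,
    )
    x2, ok2 = _equilibrate(x1, step2.pairs, ff, p2, constraint_k, constraint_r0)

    ok = ok1 & ok2
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("excluding %d/%d non-equilibrated configurations",
                       n_bad, n_configs)
    keep = np.nonzero(ok)[0]
    return Ensemble(
        coords=x2[keep],
        bonds=[step2.pairs[int(s)] for s in keep],
        provenance={
            "source": "build_ensemble",
            "n_bins": n, "n_configs": n_configs, "seed": params.seed,
            "n_steps_per_phase": params.n_steps, "dt": params.dt,
            "constraint_k": constraint_k, "constraint_r0": constraint_r0,
            "n_prominent": len(prominent), "n_excluded": n_bad,
        },
    )


def ensemble_contact_map(
    ensemble: Ensemble, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> ContactMap:
    """Contact map recomputed from an ensemble: ``P_ij`` is the fraction of
    configurations with ``r_ij < cutoff``; unit diagonal."""
    if ensemble.n_samples < 1:
        raise ValueError("empty ensemble")
    X = ensemble.coords
    d2 = ((X[:, :, None, :] - X[:, None, :, :]) ** 2).sum(axis=3)
    p = (d2 < cutoff**2).mean(axis=0)
    p = 0.5 * (p + p.T)
    np.fill_diagonal(p, 1.0)
    return ContactMap(p, resolution_bp=200, chrom="ensemble", start_bp=0)
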