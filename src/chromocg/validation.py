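"""Quantitative comparison of contact maps and distributions.

The stratum-adjusted correlation coefficient (SCC) follows the HiCRep
construction: both maps are optionally smoothed with a 2D mean filter, a
Pearson correlation is computed within each diagonal stratum (fixed genomic
separation), and the per-stratum correlations are combined with weights
``N_s * sd_A,s * sd_B,s``.  Distribution comparisons use the Kullback-Leibler
divergence with additive regularization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .coarse_grain import CGSpec, cg_trace
from .dynamics import Ensemble

__all__ = [
    "SCCConfig",
    "scc",
    "kl_divergence",
    "distance_distribution",
    "compare_rg_distributions",
]

KL_EPS = 1e-10


@dataclass
class SCCConfig:
    """SCC settings: strata 2..max_stratum, mean-filter half-width h."""

    max_stratum: int = 50
    smoothing_half_width: int = 1

    def __post_init__(self) -> None:
        if self.max_stratum < 2:
            raise ValueError("max_stratum must be >= 2")
        if self.smoothing_half_width < 0:
            raise ValueError("smoothing half-width must be >= 0")


def scc(map_a, map_b, cfg: SCCConfig | None = None) -> float:
    """Stratum-adjusted correlation coefficient between two contact maps.

    Accepts :class:`~chromocg.contact_io.ContactMap` objects or bare square
    matrices of equal dimension.  Strata with zero variance in either map are
    skipped; an error is raised if every stratum is skipped.
    """
    a = np.asarray(getattr(map_a, "matrix", map_a), dtype=float)
    b = np.asarray(getattr(map_b, "matrix", map_b), dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("maps must be square matrices of equal dimension")
    n = a.shape[0]
    if cfg is None:
        cfg = SCCConfig(max_stratum=max(2, min(50, n // 3)))
    h = cfg.smoothing_half_width
    if h > 0:
        size = 2 * h + 1
        a = uniform_filter(a, size=size, mode="nearest")
        b = uniform_filter(b, size=size, mode="nearest")
    num = 0.0
    den = 0.0
    for s in range(2, min(cfg.max_stratum, n - 1) + 1):
        va = np.diagonal(a, offset=s)
        vb = np.diagonal(b, offset=s)
        sa = va.std()
        sb = vb.std()
        if sa == 0.0 or sb == 0.0:
            continue
        rho = np.corrcoef(va, vb)[0, 1]
        w = va.size * sa * sb
        num += w * rho
        den += w
    if den == 0.0:
        raise ValueError("all strata skipped (zero variance); SCC undefined")
    return float(num / den)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(P || Q) = sum P ln(P/Q) over a common grid, after additive
    regularization (eps = 1e-10) and renormalization of both distributions."""
    p = np.asarray(p, dtype=float) + KL_EPS
    q = np.asarray(q, dtype=float) + KL_EPS
    if p.shape != q.shape:
        raise ValueError("distributions must share a grid")
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))


def distance_distribution(
    ensemble: Ensemble,
    spec: CGSpec | int = 1,
    pair_class: str = "nonbonded",
    bin_width: float = 0.1,
    r_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned distribution of 3D distances between CG-bead pairs.

    ``pair_class``: 'bonded' (|i-j| = 1), 'nonbonded' (|i-j| >= 2) or
    'all-pairs'.  Pools all (configuration, pair) events; returns
    ``(bin_edges, density)`` normalized to unit integral, truncated at the
    last occupied bin.
    """
    nb = spec.n_b if isinstance(spec, CGSpec) else int(spec)
    centers = np.stack(
        [cg_trace(c, CGSpec(nb, "blocked")) for c in ensemble.coords]
    )
    S, n_cg, _ = centers.shape
    i, j = np.triu_indices(n_cg, k=1)
    sep = j - i
    if pair_class == "bonded":
        keep = sep == 1
    elif pair_class == "nonbonded":
        keep = sep >= 2
    elif pair_class == "all-pairs":
        keep = np.ones_like(sep, dtype=bool)
    else:
        raise ValueError(f"unknown pair class {pair_class!r}")
    i, j = i[keep], j[keep]
    if i.size == 0:
        raise ValueError(f"no pairs in class {pair_class!r} at n_cg={n_cg}")
    d = np.linalg.norm(centers[:, i, :] - centers[:, j, :], axis=2).ravel()
    auto_range = r_max is None
    if auto_range:
        r_max = d.max() + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    dens, edges = np.histogram(d, bins=edges, density=True)
    if auto_range:  # truncate at the last occupied bin
        last = np.nonzero(dens)[0]
        if last.size and last[-1] + 1 < dens.size:
            dens = dens[: last[-1] + 1]
            edges = edges[: last[-1] + 2]
    return edges, dens


def compare_rg_distributions(
    fg_ensemble: Ensemble,
    cg_ensemble: Ensemble,
    spec: CGSpec | int,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Compare whole-chain Rg between a fine-grained ensemble (measured on its
    blocked CG trace, so both sides measure the same object) and a
    coarse-grained simulation.

    Returns means, quartiles, the relative mean difference, a bootstrap CI of
    the difference, and Cohen's d.
    """
    nb = spec.n_b if isinstance(spec, CGSpec) else int(spec)
    rg_fg = np.array(
        [_rg(cg_trace(c, CGSpec(nb, "blocked"))) for c in fg_ensemble.coords]
    )
    rg_cg = np.array([_rg(c) for c in cg_ensemble.coords])
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        diffs[b] = (
            rng.choice(rg_cg, rg_cg.size).mean()
            - rng.choice(rg_fg, rg_fg.size).mean()
        )
    pooled_sd = np.sqrt(0.5 * (rg_fg.var(ddof=1) + rg_cg.var(ddof=1)))
    return {
        "fg_mean": float(rg_fg.mean()),
        "cg_mean": float(rg_cg.mean()),
        "fg_quartiles": np.percentile(rg_fg, [25, 50, 75]).tolist(),
        "cg_quartiles": np.percentile(rg_cg, [25, 50, 75]).tolist(),
        "relative_mean_difference": float(
            (rg_cg.mean() - rg_fg.mean()) / rg_fg.mean()
        ),
        "difference_ci95": np.percentile(diffs, [2.5, 97.5]).tolist(),
        "cohens_d": float((rg_cg.mean() - rg_fg.mean()) / pooled_sd)
        if pooled_sd > 0
        else 0.0,
    }


def _rg(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))
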