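"""Transfer-operator propagators for fixed-bond-length flexible chains.

The equilibrium monomer density of an r-mer in external fields is assembled
from auxiliary propagators c(i, z) built by the recursion

    c(1, z) = w(1, z),
    c(i, z) = w(i, z) · T[w(i−1, ·) c(i−1, ·)](z),   i > 1,

where w(i, z) = exp(−[Z_i ψ(z) + λ_ex(z) + V_ex(z)]/2) is the *half* Boltzmann
weight of monomer i and T the fixed-bond-length transfer operator

    (T f)(z) = (1/2b) ∫_{z−b}^{z+b} f(z′) dz′,

truncated (not renormalized) at the walls: configurations crossing a wall are
forbidden by the steric wall potential, so their weight is simply lost.  For a
palindromic charge sequence (alternating ±1 with equal ends) the propagators
from either chain end coincide, and the density of monomer i is

    n_i(z) = e^{βμ′} c(i, z) c(r+1−i, z),

the half-weight convention counting monomer i's full Boltzmann factor exactly
once.  With zero fields in an unbounded system this reduces to the ideal-gas
sum rule n′ = r n_chain, and for r = 1 to the plain Boltzmann distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ChainArchitecture, Grid

__all__ = ["SiteWeights", "PropagatorSet", "bond_transfer", "site_weights",
           "propagate", "assemble_density"]

_EXP_CAP = 250.0  # cap on |exponent| in intermediate iterates; converged states sit far below


def _safe_exp(x: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(x, -_EXP_CAP, _EXP_CAP))


@dataclass
class SiteWeights:
    """Per-monomer half-weights w(i, z) for one species on one grid."""

    w: np.ndarray  # shape (r, N)
    arch: ChainArchitecture


@dataclass
class PropagatorSet:
    """Propagator slices c(i, z), i = 1..r (row i−1), for one species.

    Slices are stored rescaled to unit maximum with the logarithm of the
    rescaling factor in ``log_scale``, so the recursion cannot overflow even
    for wildly out-of-equilibrium transient fields; the physical slice is
    ``c[i] * exp(log_scale[i])``.
    """

    c: np.ndarray  # shape (r, N), each row scaled to max 1
    log_scale: np.ndarray  # shape (r,)
    arch: ChainArchitecture


def bond_transfer(f: np.ndarray, grid: Grid, b: float | None = None,
                  support: tuple[int, int] | None = None) -> np.ndarray:
    """Apply the bond transfer operator (T f)(z) = (1/2b)∫_{z−b}^{z+b} f dz′.

    The integration window is truncated at the boundaries of f's support and
    NOT renormalized: configurations reaching across a wall are forbidden by
    the steric potential and their weight is simply lost.  ``support`` gives
    the node range [lo, hi] outside which f vanishes (default: the whole
    grid); weighted propagator slices are supported on the accessible window,
    and restricting the trapezoid to it keeps the jump at the contact plane
    from polluting the quadrature.  ``b`` must be a multiple of the grid
    spacing (at least one step) so the kernel edges fall on nodes.
    """
    if b is None:
        b = grid.b
    if f.shape != (grid.n_nodes,):
        raise ValueError("profile does not match the grid")
    if b < grid.dz:
        raise ValueError("bond length must be at least one grid step")
    nb = round(b / grid.dz)
    if abs(nb * grid.dz - b) > 1e-6 * b:
        raise ValueError("bond length must be a multiple of the grid spacing")
    s_lo, s_hi = support if support is not None else (0, grid.n_nodes - 1)
    cum = np.zeros(grid.n_nodes)
    seg = f[s_lo : s_hi + 1]
    cum[s_lo + 1 : s_hi + 1] = np.cumsum((seg[1:] + seg[:-1]) * (grid.dz / 2.0))
    cum[s_hi + 1 :] = cum[s_hi]
    idx = np.arange(grid.n_nodes)
    hi = np.minimum(idx + nb, grid.n_nodes - 1)
    lo = np.maximum(idx - nb, 0)
    return (cum[hi] - cum[lo]) / (2.0 * b)


def site_weights(arch: ChainArchitecture, psi: np.ndarray, lam_ex: np.ndarray,
                 grid: Grid) -> SiteWeights:
    """Half Boltzmann weights exp(−[Z_i ψ + λ_ex]/2), zero outside the window."""
    mask = grid.accessible
    charges = np.asarray(arch.charges, dtype=float)[:, None]
    expo = -0.5 * (charges * psi[None, :] + lam_ex[None, :])
    w = _safe_exp(expo) * mask[None, :]
    return SiteWeights(w=w, arch=arch)


def propagate(weights: SiteWeights, arch: ChainArchitecture, grid: Grid) -> PropagatorSet:
    """Run the propagator recursion for all r monomers of one species."""
    if weights.arch.r != arch.r or weights.w.shape[0] != arch.r:
        raise ValueError("weights are inconsistent with the chain architecture")
    r = arch.r
    i0 = grid.i_contact
    support = (i0, grid.n_nodes - 1 - i0)
    c = np.empty_like(weights.w)
    log_scale = np.zeros(r)
    c[0] = weights.w[0]
    for i in range(r):
        if i > 0:
            c[i] = weights.w[i] * bond_transfer(
                weights.w[i - 1] * c[i - 1], grid, arch.b, support=support)
            log_scale[i] = log_scale[i - 1]
        peak = float(c[i].max())
        if peak > 0.0:
            c[i] /= peak
            log_scale[i] += np.log(peak)
        else:
            log_scale[i] = -np.inf
    return PropagatorSet(c=c, log_scale=log_scale, arch=arch)


def assemble_density(cs: PropagatorSet, weights: SiteWeights, mu_prime: float,
                     arch: ChainArchitecture, grid: Grid) -> np.ndarray:
    """Per-monomer densities n_i(z) = e^{βμ′} c(i, z) c(r+1−i, z); shape (r, N).

    ``mu_prime`` is the normalization chemical potential fixing the bulk chain
    density (ln n_chain,bulk + r λ_ex,bulk for this functional).  Total species
    monomer density is ``result.sum(axis=0)``.  Out-of-equilibrium transients
    can predict astronomically large local densities; the amplitude is capped
    at the exponent level (e^300) so intermediate iterates stay finite — the
    cap is far above any physical density and never binds at convergence.
    """
    amp = np.exp(np.minimum(mu_prime + cs.log_scale + cs.log_scale[::-1], 300.0))
    return amp[:, None] * cs.c * cs.c[::-1]
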