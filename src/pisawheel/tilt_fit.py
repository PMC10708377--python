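"""Helix tilt and rotation fitting from SLF peak lists.

Grid search of the PISA forward model over (τ, ρ₀), scoring each candidate
wheel by the minimum-cost one-to-one matching between simulated and
observed peaks in normalized spectral units, followed by deterministic
golden-section refinement.  A two-wheel variant fits the dimer
interpretation, in which two helices with different membrane orientations
contribute one wheel each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .helix_model import HelixGeometry
from .oriented_nmr import (
    BicelleModel,
    CSATensor,
    SLFPeak,
    WheelParams,
    _wheel_frequencies,
)

__all__ = [
    "FitResult",
    "default_scale",
    "match_peaks",
    "fit_tilt",
    "fit_two_wheels",
]

DEFAULT_TAU_GRID = np.arange(0.0, 30.0 + 1e-9, 0.5)
DEFAULT_RHO_GRID = np.arange(0.0, 360.0, 5.0)


@dataclass
class FitResult:
    """Best-fit wheel parameters with the full search profile.

    ``rmsd`` is the root-mean-square matched-peak distance in normalized
    (dimensionless) spectral units.  ``profile`` has columns
    (tilt_deg, rho0_deg, rmsd) over the search grid; its minimum equals
    the reported fit.  ``assignment`` maps observed-peak index to the
    matched residue (when residues are known).
    """

    tilt_deg: float
    rho0_deg: float
    rmsd: float
    profile: np.ndarray
    assignment: dict[int, int] = field(default_factory=dict)
    n_peaks: int = 0

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def default_scale(t15n: CSATensor, b: BicelleModel,
                  nu_parallel: float) -> tuple[float, float]:
    """Normalization spans making the two spectral axes comparable.

    The shift axis is divided by the full scaled CSA span
    (σ33 − σ11)·S·|f| and the coupling axis by the scaled maximal
    coupling ν∥·S·|f|.
    """
    sf = b.order_parameter * abs(b.factor)
    return ((t15n.sigma33 - t15n.sigma11) * sf, nu_parallel * sf)


def _peak_arrays(peaks: list[SLFPeak]):
    shifts = np.array([p.shift_ppm for p in peaks])
    coups = np.array([p.coupling_khz for p in peaks])
    residues = [p.residue for p in peaks]
    return shifts, coups, residues


def match_peaks(simulated: list[SLFPeak], observed: list[SLFPeak],
                scale: tuple[float, float]) -> tuple[dict[int, int], float]:
    """Minimum-cost one-to-one matching between two SLF peak lists.

    Distances are Euclidean after dividing each axis by its span in
    ``scale`` (ppm_span, khz_span).  When both lists carry residue labels,
    matching is label-constrained; otherwise the assignment is the global
    minimum-total-cost matching over min(n, m) pairs (Hungarian
    algorithm), with ties resolved deterministically by the solver's
    lexicographic ordering.  Returns (observed index → simulated index,
    rmsd over matched pairs).
    """
    if not simulated or not observed:
        raise ValueError("peak lists must be non-empty")
    ppm_span, khz_span = scale
    if ppm_span <= 0 or khz_span <= 0:
        raise ValueError("scale spans must be positive")
    s_sh, s_cp, s_res = _peak_arrays(simulated)
    o_sh, o_cp, o_res = _peak_arrays(observed)

    labelled = (all(r is not None for r in s_res)
                and all(r is not None for r in o_res)
                and set(o_res) <= set(s_res)
                and len(set(o_res)) == len(o_res))
    if labelled:
        pos = {r: j for j, r in enumerate(s_res)}
        assignment = {i: pos[r] for i, r in enumerate(o_res)}
        d2 = [((o_sh[i] - s_sh[j]) / ppm_span) ** 2
              + ((o_cp[i] - s_cp[j]) / khz_span) ** 2
              for i, j in assignment.items()]
        return assignment, float(np.sqrt(np.mean(d2)))

    dx = (o_sh[:, None] - s_sh[None, :]) / ppm_span
    dy = (o_cp[:, None] - s_cp[None, :]) / khz_span
    cost = dx * dx + dy * dy
    rows, cols = linear_sum_assignment(cost)
    assignment = {int(i): int(j) for i, j in zip(rows, cols)}
    return assignment, float(np.sqrt(cost[rows, cols].mean()))


def _grid_rmsd(observed: list[SLFPeak], h: HelixGeometry, t15n: CSATensor,
               b: BicelleModel, nu_parallel: float, residues: np.ndarray,
               tau_grid: np.ndarray, rho_grid: np.ndarray,
               scale: tuple[float, float]) -> np.ndarray:
    """RMSD surface over the (τ, ρ₀) grid, vectorized over ρ₀."""
    ppm_span, khz_span = scale
    o_sh, o_cp, o_res = _peak_arrays(observed)
    idx = residues - 1

    labelled = (all(r is not None for r in o_res)
                and set(o_res) <= set(residues.tolist())
                and len(set(o_res)) == len(o_res))
    if labelled:
        pos = {int(r): j for j, r in enumerate(residues)}
        order = np.array([pos[r] for r in o_res])

    out = np.empty((tau_grid.size, rho_grid.size))
    for a, tau in enumerate(tau_grid):
        w = WheelParams(tilt_deg=float(tau), rho0_deg=0.0,
                        nu_parallel_khz=nu_parallel)
        sh, cp = _wheel_frequencies(h, t15n, w, b, idx, rho_grid)  # (R, M)
        cp = np.abs(cp)
        if labelled:
            d2 = (((o_sh[None, :] - sh[:, order]) / ppm_span) ** 2
                  + ((o_cp[None, :] - cp[:, order]) / khz_span) ** 2)
            out[a] = np.sqrt(d2.mean(axis=1))
        else:
            for r in range(rho_grid.size):
                dx = (o_sh[:, None] - sh[r][None, :]) / ppm_span
                dy = (o_cp[:, None] - cp[r][None, :]) / khz_span
                cmat = dx * dx + dy * dy
                ri, ci = linear_sum_assignment(cmat)
                out[a, r] = np.sqrt(cmat[ri, ci].mean())
    return out


def _golden_refine(fun, lo, hi, tol=1e-3, max_iter=60):
    """Golden-section minimization of a 1D function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    x = c if fc < fd else d
    return x, min(fc, fd)


def fit_tilt(observed: list[SLFPeak], h: HelixGeometry, t15n: CSATensor,
             b: BicelleModel, nu_parallel: float | None = None,
             residues: list[int] | None = None,
             tau_grid: np.ndarray | None = None,
             rho_grid: np.ndarray | None = None,
             scale: tuple[float, float] | None = None,
             refine: bool = True) -> FitResult:
    """Fit helix tilt τ and rotation ρ₀ to an observed SLF peak list.

    Evaluates the PISA forward model for ``h`` at every (τ, ρ₀) grid
    point, scores by :func:`match_peaks`, and returns the global grid
    minimum (optionally golden-section refined, one coordinate at a time)
    with the full rmsd profile.

    ``residues`` are the helix residues simulated against the data
    (default: all amide-bearing residues 2..n).
    """
    from .oriented_nmr import DEFAULT_NU_PARALLEL_KHZ, pisa_wheel

    if not observed:
        raise ValueError("observed peak list is empty")
    nu = nu_parallel if nu_parallel is not None else DEFAULT_NU_PARALLEL_KHZ
    tau_grid = np.asarray(tau_grid if tau_grid is not None else DEFAULT_TAU_GRID,
                          dtype=float)
    rho_grid = np.asarray(rho_grid if rho_grid is not None else DEFAULT_RHO_GRID,
                          dtype=float)
    if tau_grid.size == 0 or rho_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if residues is None:
        res = np.arange(2, h.n_residues + 1)
    else:
        res = np.asarray(sorted(set(residues)), dtype=int)
    if scale is None:
        scale = default_scale(t15n, b, nu)

    surface = _grid_rmsd(observed, h, t15n, b, nu, res,
                         tau_grid, rho_grid, scale)
    a, r = np.unravel_index(np.argmin(surface), surface.shape)
    tau_best, rho_best = float(tau_grid[a]), float(rho_grid[r])
    rmsd_best = float(surface[a, r])

    def score(tau, rho):
        w = WheelParams(tilt_deg=tau, rho0_deg=rho % 360.0,
                        nu_parallel_khz=nu)
        sim = pisa_wheel(h, t15n, w, b, residues=res.tolist())
        return match_peaks(sim, observed, scale)[1]

    if refine:
        dtau = float(np.diff(tau_grid).min()) if tau_grid.size > 1 else 1.0
        drho = float(np.diff(rho_grid).min()) if rho_grid.size > 1 else 5.0
        for _ in range(3):
            tau_best, _ = _golden_refine(
                lambda t: score(t, rho_best),
                max(0.0, tau_best - dtau), min(90.0, tau_best + dtau))
            rho_best, rmsd_best = _golden_refine(
                lambda p: score(tau_best, p),
                rho_best - drho, rho_best + drho)
        rho_best %= 360.0

    w = WheelParams(tilt_deg=tau_best, rho0_deg=rho_best, nu_parallel_khz=nu)
    sim = pisa_wheel(h, t15n, w, b, residues=res.tolist())
    assignment, rmsd_final = match_peaks(sim, observed, scale)
    profile = np.column_stack([
        np.repeat(tau_grid, rho_grid.size),
        np.tile(rho_grid, tau_grid.size),
        surface.ravel(),
    ])
    res_map = {i: int(res[j]) for i, j in assignment.items()}
    return FitResult(tilt_deg=tau_best, rho0_deg=rho_best,
                     rmsd=min(rmsd_best, rmsd_final) if refine else rmsd_best,
                     profile=profile, assignment=res_map,
                     n_peaks=len(observed))


def _per_wheel_distances(observed: list[SLFPeak], h: HelixGeometry,
                         t15n: CSATensor, b: BicelleModel, nu: float,
                         residues: np.ndarray, tau_grid: np.ndarray,
                         rho_grid: np.ndarray,
                         scale: tuple[float, float]) -> np.ndarray:
    """Distance of each observed peak to its nearest simulated peak, for
    every (τ, ρ₀) grid point.  Shape (n_tau, n_rho, n_obs)."""
    ppm_span, khz_span = scale
    o_sh, o_cp, o_res = _peak_arrays(observed)
    idx = residues - 1
    labelled = (all(r is not None for r in o_res)
                and set(o_res) <= set(residues.tolist()))
    if labelled:
        pos = {int(r): j for j, r in enumerate(residues)}
        order = np.array([pos[r] for r in o_res])

    out = np.empty((tau_grid.size, rho_grid.size, len(observed)))
    for a, tau in enumerate(tau_grid):
        w = WheelParams(tilt_deg=float(tau), rho0_deg=0.0,
                        nu_parallel_khz=nu)
        sh, cp = _wheel_frequencies(h, t15n, w, b, idx, rho_grid)
        cp = np.abs(cp)
        if labelled:
            out[a] = np.sqrt(((o_sh[None, :] - sh[:, order]) / ppm_span) ** 2
                             + ((o_cp[None, :] - cp[:, order]) / khz_span) ** 2)
        else:
            dx = (o_sh[None, :, None] - sh[:, None, :]) / ppm_span
            dy = (o_cp[None, :, None] - cp[:, None, :]) / khz_span
            out[a] = np.sqrt((dx * dx + dy * dy).min(axis=2))
    return out


def fit_two_wheels(observed: list[SLFPeak], h: HelixGeometry,
                   t15n: CSATensor, b: BicelleModel,
                   nu_parallel: float | None = None,
                   residues: list[int] | None = None,
                   coarse_tau_step: float = 2.0,
                   coarse_rho_step: float = 20.0,
                   tau_max: float = 30.0,
                   scale: tuple[float, float] | None = None
                   ) -> tuple[FitResult, FitResult]:
    """Two-component PISA-wheel fit for a dimer with inequivalent monomers.

    Joint coarse grid search over two (τ, ρ₀) pairs, assigning each
    observed peak to the nearer of the two simulated wheels; the peak
    partition at the coarse optimum is then refined by independent
    single-wheel fits (:func:`fit_tilt`) on fine local grids.  Results
    are returned ordered by tilt.  A component that captures no peaks is
    flagged by ``n_peaks == 0`` and rmsd 0.
    """
    from .oriented_nmr import DEFAULT_NU_PARALLEL_KHZ

    if len(observed) < 4:
        raise ValueError("two-wheel fit needs at least 4 peaks")
    nu = nu_parallel if nu_parallel is not None else DEFAULT_NU_PARALLEL_KHZ
    if residues is None:
        res = np.arange(2, h.n_residues + 1)
    else:
        res = np.asarray(sorted(set(residues)), dtype=int)
    if scale is None:
        scale = default_scale(t15n, b, nu)

    tau_grid = np.arange(0.0, tau_max + 1e-9, coarse_tau_step)
    rho_grid = np.arange(0.0, 360.0, coarse_rho_step)
    D = _per_wheel_distances(observed, h, t15n, b, nu, res,
                             tau_grid, rho_grid, scale)
    flat = D.reshape(-1, len(observed))               # (G, n_obs)
    # joint cost over unordered pairs of grid points
    G = flat.shape[0]
    best = (np.inf, 0, 0)
    # chunked pairwise min to bound memory
    chunk = 256
    for start in range(0, G, chunk):
        block = np.minimum(flat[start:start + chunk, None, :], flat[None, :, :])
        cost = (block ** 2).mean(axis=2)               # (c, G)
        k = np.unravel_index(np.argmin(cost), cost.shape)
        val = float(cost[k])
        if val < best[0]:
            best = (val, start + k[0], k[1])
    _, g1, g2 = best
    n_rho = rho_grid.size

    def grid_params(g):
        return float(tau_grid[g // n_rho]), float(rho_grid[g % n_rho])

    (tau1, rho1), (tau2, rho2) = grid_params(g1), grid_params(g2)

    # partition peaks by nearer wheel at the coarse optimum
    nearer = D.reshape(-1, len(observed))[[g1, g2]]
    comp = np.argmin(nearer, axis=0)
    results = []
    for k, (tau0, rho0) in enumerate([(tau1, rho1), (tau2, rho2)]):
        subset = [p for p, c in zip(observed, comp) if c == k]
        if not subset:
            results.append(FitResult(tilt_deg=tau0, rho0_deg=rho0, rmsd=0.0,
                                     profile=np.empty((0, 3)), n_peaks=0))
            continue
        ftau = np.arange(max(0.0, tau0 - coarse_tau_step),
                         min(tau_max, tau0 + coarse_tau_step) + 1e-9, 0.25)
        frho = np.arange(rho0 - coarse_rho_step,
                         rho0 + coarse_rho_step + 1e-9, 2.0) % 360.0
        results.append(fit_tilt(subset, h, t15n, b, nu_parallel=nu,
                                residues=res.tolist(), tau_grid=ftau,
                                rho_grid=np.unique(frho), scale=scale))
    results.sort(key=lambda fr: fr.tilt_deg)
    return results[0], results[1]
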