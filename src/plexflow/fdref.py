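"""Finite-difference reference solver for tissue oxygen.

A deliberately independent numerical route used to validate the
Green's-function solver: second-order 7-point finite differences for

    D·α·∇²P = M(P)          (Michaelis–Menten consumption)

on a regular grid with no-flux outer faces. Vessels are rasterized
geometrically: every cell whose center lies inside a lumen becomes a
Dirichlet cell at the wall PO₂ of the nearest element, so the grid spacing
must resolve the lumen radius (h ≲ r_lumen/2) for the effective vessel
radius to be faithful. The element PO₂ comes from the same convective
closure as the main solver, iterated against the grid efflux until
self-consistent. Deterministic.

Intended for small domains (≤ 10⁶ cells); larger requests are refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .errors import ConfigurationError, ConvergenceError
from .hemodynamics import FlowSolution
from .network import VesselNetwork
from .oxygen import UM_TO_CM, VesselElements, build_elements, convective_march
from .params import OxyParams

_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


class GridPoisson:
    """Reusable factorized 7-point Laplacian with Dirichlet cells.

    Solves Dα∇²P = M(P) by damped Picard iteration; the operator depends
    only on the Dirichlet mask, so one factorization serves every call.
    """

    def __init__(
        self,
        shape: tuple[int, int, int],
        spacing_um: float,
        dirichlet_mask: np.ndarray,
        d_tissue: float,
        alpha_tissue: float,
    ):
        n_cells = int(np.prod(shape))
        if n_cells > 1_000_000:
            raise ConfigurationError(f"fd domain too large: {n_cells} cells (max 1e6)")
        self.shape = shape
        self.h_cm = spacing_um * UM_TO_CM
        self.d_alpha = d_tissue * alpha_tissue
        self.mask = np.asarray(dirichlet_mask, dtype=bool)
        self.unknown = ~self.mask
        self.n_unknown = int(self.unknown.sum())
        self._dirichlet_index = -np.ones(shape, dtype=np.int64)
        self._dirichlet_index[self.mask] = np.arange(int(self.mask.sum()))
        if self.n_unknown == 0:
            return
        uidx = -np.ones(shape, dtype=np.int64)
        uidx[self.unknown] = np.arange(self.n_unknown)
        coords = np.argwhere(self.unknown)
        my_idx = uidx[self.unknown]
        rows, cols, vals = [], [], []
        diag = np.zeros(self.n_unknown)
        b_rows, b_cols = [], []
        for off in _NEIGHBOR_OFFSETS:
            nb = coords + off
            inb = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
            nb_in = nb[inb]
            src = my_idx[inb]
            nb_flat = uidx[nb_in[:, 0], nb_in[:, 1], nb_in[:, 2]]
            nb_dir = nb_flat < 0
            # in-bounds neighbors enter the stencil; absent ones are no-flux
            np.add.at(diag, src, 1.0)
            rows.extend(src[~nb_dir])
            cols.extend(nb_flat[~nb_dir])
            vals.extend(np.full(int((~nb_dir).sum()), -1.0))
            if np.any(nb_dir):
                d_cells = nb_in[nb_dir]
                b_rows.extend(src[nb_dir])
                b_cols.extend(self._dirichlet_index[d_cells[:, 0], d_cells[:, 1], d_cells[:, 2]])
        a = sp.coo_matrix((vals, (rows, cols)), shape=(self.n_unknown, self.n_unknown)).tocsr()
        a = a + sp.diags(diag)
        self._lu = spla.splu(a.tocsc())
        n_dir = int(self.mask.sum())
        self._bmat = sp.coo_matrix(
            (np.ones(len(b_rows)), (b_rows, b_cols)), shape=(self.n_unknown, max(n_dir, 1))
        ).tocsr()

    def solve(
        self,
        dirichlet_values: np.ndarray,
        consumption,
        p_init: float | np.ndarray,
        picard_tol: float = 1e-8,
        max_picard: int = 400,
    ) -> np.ndarray:
        dvals = np.asarray(dirichlet_values, dtype=float)
        if np.ndim(p_init) == 0:
            p = np.full(self.shape, float(p_init))
        else:
            p = np.asarray(p_init, dtype=float).copy()
        p[self.mask] = dvals[self.mask]
        if self.n_unknown == 0:
            return p
        rhs_fixed = self._bmat @ dvals[self.mask]
        for _ in range(max_picard):
            m_grid = np.asarray(consumption(p), dtype=float)
            b = rhs_fixed - m_grid[self.unknown] * self.h_cm**2 / self.d_alpha
            p_new_u = self._lu.solve(b)
            delta = float(np.max(np.abs(p_new_u - p[self.unknown])))
            # damped update: plain Picard oscillates when P approaches P_m
            p[self.unknown] = 0.5 * p_new_u + 0.5 * p[self.unknown]
            if delta < picard_tol:
                p[self.unknown] = p_new_u
                return p
        raise ConvergenceError(
            f"fd Picard iteration did not reach {picard_tol} mmHg in {max_picard} steps"
        )


def fd_core(
    shape: tuple[int, int, int],
    spacing_um: float,
    dirichlet_mask: np.ndarray,
    dirichlet_values: np.ndarray,
    consumption,
    d_tissue: float,
    alpha_tissue: float,
    p_init: float,
    picard_tol: float = 1e-8,
    max_picard: int = 400,
) -> np.ndarray:
    """One-shot wrapper around :class:`GridPoisson` (see class docstring)."""
    solver = GridPoisson(shape, spacing_um, dirichlet_mask, d_tissue, alpha_tissue)
    return solver.solve(dirichlet_values, consumption, p_init, picard_tol, max_picard)


@dataclass
class FDResult:
    grid_po2: np.ndarray
    origin: np.ndarray  # μm
    spacing: float  # μm
    vessel_mask: np.ndarray  # bool grid of Dirichlet cells
    element_po2: np.ndarray  # mmHg per element
    element_q: np.ndarray  # cm³O₂/s per element
    iterations: int
    converged: bool

    def axes(self):
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.grid_po2.shape[i])
            for i in range(3)
        )

    def interp(self, points: np.ndarray) -> np.ndarray:
        f = RegularGridInterpolator(self.axes(), self.grid_po2, bounds_error=False, fill_value=None)
        return f(points)


def _rasterize_elements(
    net: VesselNetwork, elements: VesselElements, origin: np.ndarray,
    spacing: float, shape: tuple[int, int, int],
) -> np.ndarray:
    """Map grid cells inside each perfused element's lumen to that element.

    Cells within ``max(r_lumen, 0.51 h)`` of the element chord are claimed
    (the floor keeps sub-grid vessels rasterized as a connected line); ties
    go to the nearest element.
    """
    owner = -np.ones(shape, dtype=np.int64)
    best = np.full(shape, np.inf)
    axes = [origin[i] + spacing * np.arange(shape[i]) for i in range(3)]
    for k in np.where(elements.perfused)[0]:
        sid = elements.segment_ids[k]
        seg = net.segments[sid]
        a = net.nodes[seg.node_a].position
        b = net.nodes[seg.node_b].position
        r_claim = max(elements.radii[k], 0.51 * spacing)
        lo_c = np.minimum(a, b) - r_claim
        hi_c = np.maximum(a, b) + r_claim
        sl = tuple(
            slice(
                int(np.searchsorted(axes[i], lo_c[i])),
                int(np.searchsorted(axes[i], hi_c[i], side="right")),
            )
            for i in range(3)
        )
        if any(s.start >= s.stop for s in sl):
            continue
        gx, gy, gz = np.meshgrid(axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]], indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        ab = b - a
        t = np.clip((pts - a) @ ab / float(ab @ ab), 0.0, 1.0)
        dist = np.linalg.norm(pts - (a[None, :] + t[:, None] * ab[None, :]), axis=1)
        dist = dist.reshape(gx.shape)
        closer = (dist <= r_claim) & (dist < best[sl])
        best[sl] = np.where(closer, dist, best[sl])
        owner[sl] = np.where(closer, k, owner[sl])
    return owner


def fd_reference_solver(
    net: VesselNetwork,
    flow: FlowSolution,
    params: OxyParams,
    grid_spacing: float,
    consume_mask=None,
    max_outer: int = 80,
) -> FDResult:
    """Coupled FD tissue solve with convective vessel depletion.

    Same physics, independent discretization: vessels become Dirichlet line
    rasterizations with the well-radius correction; the transmural efflux of
    each element is the net grid flux out of its cells; intravascular PO₂
    follows from the convective budget. Outer fixed point damped by 0.5, as
    in the main solver.

    ``consume_mask(points) -> bool`` optionally restricts the consuming
    tissue region (mirror of the Green's solver's ``tissue_mask``), so both
    solvers can be compared on an identical domain.
    """
    lo, hi = net.bounding_box
    origin = lo - params.tissue_margin
    extent = hi + params.tissue_margin - origin
    shape = tuple(int(np.floor(extent[i] / grid_spacing)) + 1 for i in range(3))
    elements = build_elements(net, flow)
    owner = _rasterize_elements(net, elements, origin, grid_spacing, shape)
    vessel_mask = owner >= 0
    h_cm = grid_spacing * UM_TO_CM
    d_alpha = params.d_tissue * params.alpha_tissue

    consuming = ~vessel_mask
    if consume_mask is not None:
        ax = [origin[i] + grid_spacing * np.arange(shape[i]) for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        consuming &= np.asarray(consume_mask(pts), dtype=bool).reshape(shape)

    def consumption(p_grid: np.ndarray) -> np.ndarray:
        pc = np.maximum(p_grid, 0.0)
        m = params.m0 * pc / (pc + params.p_m)
        return np.where(consuming, m, 0.0)

    poisson = GridPoisson(shape, grid_spacing, vessel_mask, params.d_tissue, params.alpha_tissue)
    n_elem = len(elements.segment_ids)

    # precompute flux bookkeeping: (cell -> element, neighbor unknown cells)
    coords = np.argwhere(vessel_mask)
    flux_pairs: list[tuple[int, tuple[int, int, int]]] = []
    for i, j, k in coords:
        elem = int(owner[i, j, k])
        for off in _NEIGHBOR_OFFSETS:
            ni, nj, nk = i + off[0], j + off[1], k + off[2]
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                continue
            if vessel_mask[ni, nj, nk]:
                continue
            flux_pairs.append((elem, (int(i), int(j), int(k)), (ni, nj, nk)))

    q = np.zeros(n_elem)
    march = convective_march(net, flow, params, elements, q)
    p_grid = np.full(shape, float(params.p_inlet))
    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        wall = np.where(np.isfinite(march.element_po2), march.element_po2, params.p_inlet)
        dvals = np.zeros(shape)
        dvals[vessel_mask] = wall[owner[vessel_mask]]
        p_grid = poisson.solve(
            dvals, consumption, p_init=p_grid,
            picard_tol=1e-8 * params.p_inlet,
        )
        q_new = np.zeros_like(q)
        for elem, (i, j, k), (ni, nj, nk) in flux_pairs:
            q_new[elem] += d_alpha * (dvals[i, j, k] - p_grid[ni, nj, nk]) * h_cm
        q_prev = q.copy()
        q = 0.5 * q_new + 0.5 * q
        march = convective_march(net, flow, params, elements, q)
        if float(np.max(np.abs(q - q_prev))) <= 1e-12 + 1e-6 * max(float(np.max(np.abs(q))), 1e-30):
            converged = True
            break
    element_po2 = np.where(np.isfinite(march.element_po2), march.element_po2, np.nan)
    return FDResult(
        grid_po2=p_grid,
        origin=origin,
        spacing=grid_spacing,
        vessel_mask=vessel_mask,
        element_po2=element_po2,
        element_q=q,
        iterations=it,
        converged=converged,
    )
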