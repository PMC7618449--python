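"""Steady-state oxygen transport: convection + Green's-function diffusion.

Model
-----
Blood entering at the inlets carries oxygen bound to hemoglobin (Hill
saturation curve) plus a small dissolved fraction. Along each perfused
vessel element the convective budget ``Q·dC/dx = −q`` depletes the blood by
the element's transmural efflux ``q``. In the tissue, oxygen diffuses from
the vessels and is consumed by Michaelis–Menten kinetics
``M(P) = M0·P/(P + P_m)``.

Following the Green's-function (Secomb-style) approach, vessels act as
distributed point sources and the consuming tissue as distributed sinks in
an unbounded medium:

    P(x) = P∞ + Σ_v q_v·G(|x − x_v|) − Σ_t s_t·G(|x − x_t|),
    G(r) = 1 / (4π D α r),

with a free far-field constant P∞. The source strengths are fixed by two
conditions: tissue PO₂ at each element's wall equals the intravascular PO₂
of that element (no wall resistance), and total vessel efflux balances total
tissue consumption, Σq = Σs. The resulting bordered linear system is solved
inside a damped fixed-point loop that updates the consumption field.

The tissue-sink self-interaction is evaluated by FFT convolution on the
regular sample lattice; within-element kernel values are regularized to the
constant surface-PO₂ cylinder value, avoiding the 1/r singularity.

Units: coordinates μm; PO₂ mmHg; q, s in cm³O₂/s; D cm²/s; α cm³O₂·cm⁻³·mmHg⁻¹.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import fftconvolve

from .errors import ConfigurationError, DegenerateNetworkError
from .hemodynamics import FlowSolution
from .network import BoundaryKind, VesselNetwork
from .params import OxyParams

logger = logging.getLogger(__name__)

UM_TO_CM = 1e-4


# ---------------------------------------------------------------------------
# Closures
# ---------------------------------------------------------------------------


def hill_saturation(p, p50: float, n_h: float):
    """Oxyhemoglobin saturation S(P) = P^n / (P^n + P50^n), S(P50) = 1/2."""
    p = np.maximum(np.asarray(p, dtype=float), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (p / p50) ** n_h
        s = ratio / (ratio + 1.0)
    out = np.where(p == 0.0, 0.0, s)
    return float(out) if out.ndim == 0 else out


def blood_o2_content(p, params: OxyParams, h_d: float):
    """Blood O₂ content C(P) = C_Hb·H_D·S(P) + α_pl·P, cm³O₂ per cm³ blood."""
    p = np.asarray(p, dtype=float)
    c = params.c_hb * h_d * hill_saturation(p, params.p50, params.hill_n) + params.alpha_plasma * p
    return float(c) if c.ndim == 0 else c


def invert_content(c, params: OxyParams, h_d: float):
    """PO₂ such that blood_o2_content(PO₂) = c (vectorized bisection).

    C is strictly increasing in P, so the root is unique; contents at or
    below zero map to PO₂ = 0.
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    lo = np.zeros_like(c)
    hi = np.full_like(c, max(4.0 * params.p50, 300.0))
    # expand the bracket for very high contents
    for _ in range(60):
        too_low = blood_o2_content(hi, params, h_d) < c
        if not np.any(too_low):
            break
        hi[too_low] *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        below = blood_o2_content(mid, params, h_d) < c
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = np.where(c <= 0.0, 0.0, 0.5 * (lo + hi))
    return out if out.shape != (1,) else float(out[0])


def content_derivative(p, params: OxyParams, h_d: float):
    """dC/dP (cm³O₂·cm⁻³·mmHg⁻¹), strictly positive for P >= 0."""
    p = np.maximum(np.asarray(p, dtype=float), 1e-12)
    x = (p / params.p50) ** params.hill_n
    ds = params.hill_n * x / (p * (1.0 + x) ** 2)
    out = params.c_hb * h_d * ds + params.alpha_plasma
    return float(out) if out.ndim == 0 else out


def greens_kernel(r, d_tissue: float, alpha_tissue: float):
    """Free-space steady diffusion kernel G(r) = 1/(4π D α r).

    ``r`` in μm; result in mmHg per (cm³O₂/s). r = 0 maps to +inf; callers
    regularize within-element evaluations themselves.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        g = 1.0 / (4.0 * np.pi * d_tissue * alpha_tissue * (r * UM_TO_CM))
    return float(g) if g.ndim == 0 else g


# ---------------------------------------------------------------------------
# Vessel elements
# ---------------------------------------------------------------------------


@dataclass
class VesselElements:
    """Per-element geometry and flow, in segment-id order."""

    segment_ids: list[int]
    midpoints: np.ndarray  # (n, 3) μm
    radii: np.ndarray  # μm
    lengths: np.ndarray  # μm
    flow: np.ndarray  # μm³/s signed node_a -> node_b
    node_a: np.ndarray
    node_b: np.ndarray
    perfused: np.ndarray  # bool


def build_elements(net: VesselNetwork, flow: FlowSolution) -> VesselElements:
    sids = sorted(net.segments)
    mids = []
    for sid in sids:
        seg = net.segments[sid]
        if seg.polyline is not None and len(seg.polyline) >= 2:
            steps = np.linalg.norm(np.diff(seg.polyline, axis=0), axis=1)
            arc = np.concatenate(([0.0], np.cumsum(steps)))
            t = arc[-1] / 2.0
            i = int(np.searchsorted(arc, t)) - 1
            i = max(0, min(i, len(steps) - 1))
            frac = 0.0 if steps[i] == 0 else (t - arc[i]) / steps[i]
            mids.append(seg.polyline[i] + frac * (seg.polyline[i + 1] - seg.polyline[i]))
        else:
            mids.append(
                0.5 * (net.nodes[seg.node_a].position + net.nodes[seg.node_b].position)
            )
    return VesselElements(
        segment_ids=sids,
        midpoints=np.array(mids),
        radii=np.array([net.segments[s].diameter / 2.0 for s in sids]),
        lengths=np.array([net.segments[s].length for s in sids]),
        flow=np.array([flow.segment_flow[s] for s in sids]),
        node_a=np.array([net.segments[s].node_a for s in sids]),
        node_b=np.array([net.segments[s].node_b for s in sids]),
        perfused=np.array([flow.segment_transit_time[s] is not None for s in sids]),
    )


# ---------------------------------------------------------------------------
# Convective march
# ---------------------------------------------------------------------------


@dataclass
class MarchResult:
    element_po2: np.ndarray  # mmHg, mid-element (NaN for unperfused)
    element_content_out: np.ndarray  # cm³O₂/cm³ at the downstream end
    element_q_delivered: np.ndarray  # cm³O₂/s actually extracted (clamp-limited)
    node_content: dict[int, float]
    o2_influx: float  # cm³O₂/s entering at inlets
    o2_outflux: float  # cm³O₂/s leaving at outlets
    n_clamped: int  # elements whose efflux request exceeded the available O₂


def convective_march(
    net: VesselNetwork,
    flow: FlowSolution,
    params: OxyParams,
    elements: VesselElements,
    q: np.ndarray,
) -> MarchResult:
    """Propagate blood O₂ content downstream given per-element efflux ``q``.

    Nodes are visited in order of decreasing pressure (flow always runs down
    the pressure gradient, so all upstream contents are known when a node is
    mixed). Content leaving an element is C_in − q/Q, clamped to the physical
    range [0, C(max inlet PO₂)] — blood can neither deliver more O₂ than it
    carries nor absorb beyond the inlet ceiling; the element PO₂ is the
    inversion of the mid-element content C_in − q/(2Q).
    """
    h_d = flow.params.discharge_hematocrit if flow.params is not None else 0.45
    n = len(elements.segment_ids)
    q_cm = elements.flow * 1e-12  # μm³/s -> cm³/s

    # per-node incoming flux bookkeeping
    in_flux: dict[int, float] = {nid: 0.0 for nid in net.nodes}
    in_o2: dict[int, float] = {nid: 0.0 for nid in net.nodes}
    max_inlet_po2 = params.p_inlet
    for nid, influx in flow.boundary_influx.items():
        node = net.nodes[nid]
        po2 = node.boundary_po2 if node.boundary_po2 is not None else params.p_inlet
        max_inlet_po2 = max(max_inlet_po2, po2)
        in_flux[nid] += influx * 1e-12
        in_o2[nid] += influx * 1e-12 * blood_o2_content(po2, params, h_d)
    c_max = float(blood_o2_content(max_inlet_po2, params, h_d))

    # downstream element lists per node
    out_elems: dict[int, list[int]] = {nid: [] for nid in net.nodes}
    down_node = np.where(elements.flow >= 0, elements.node_b, elements.node_a)
    up_node = np.where(elements.flow >= 0, elements.node_a, elements.node_b)
    for k in range(n):
        if elements.perfused[k]:
            out_elems[int(up_node[k])].append(k)

    order = sorted(
        (nid for nid in net.nodes if np.isfinite(flow.node_pressure[nid])),
        key=lambda nid: -flow.node_pressure[nid],
    )
    element_po2 = np.full(n, np.nan)
    c_mid_arr = np.full(n, np.nan)
    content_out = np.zeros(n)
    q_delivered = np.zeros(n)
    node_content: dict[int, float] = {}
    n_clamped = 0
    for nid in order:
        c_node = in_o2[nid] / in_flux[nid] if in_flux[nid] > 0 else 0.0
        node_content[nid] = c_node
        for k in out_elems[nid]:
            qq = abs(q_cm[k])
            c_in = c_node
            c_out = c_in - q[k] / qq
            if not 0.0 <= c_out <= c_max:
                c_out = min(max(c_out, 0.0), c_max)
                n_clamped += 1
            c_mid_arr[k] = min(max(0.5 * (c_in + c_out), 0.0), c_max)
            content_out[k] = c_out
            q_delivered[k] = (c_in - c_out) * qq
            dn = int(down_node[k])
            in_flux[dn] += qq
            in_o2[dn] += qq * c_out
    perf = np.isfinite(c_mid_arr)
    if np.any(perf):
        element_po2[perf] = np.atleast_1d(invert_content(c_mid_arr[perf], params, h_d))
    q_delivered[~perf] = 0.0

    o2_out = 0.0
    for nid, outflux in flow.boundary_outflux.items():
        o2_out += outflux * 1e-12 * node_content.get(nid, 0.0)
    o2_in = sum(
        flow.boundary_influx[nid]
        * 1e-12
        * blood_o2_content(
            net.nodes[nid].boundary_po2
            if net.nodes[nid].boundary_po2 is not None
            else params.p_inlet,
            params,
            h_d,
        )
        for nid in flow.boundary_influx
    )
    return MarchResult(
        element_po2, content_out, q_delivered, node_content, o2_in, o2_out, n_clamped
    )


def convective_sensitivity(
    net: VesselNetwork,
    flow: FlowSolution,
    elements: VesselElements,
) -> np.ndarray:
    """W[i, j] = ∂C_mid,i/∂q_j — the convective coupling of element contents.

    Mid-element blood content falls by q_i/(2Q_i) locally and by the
    flow-fraction-weighted efflux of every strictly upstream element. W is a
    property of the flow field alone (contents are linear in q), so it is
    built once per solve and folded into the vessel-surface matching matrix;
    leaving this feedback lagged makes the fixed point violently unstable
    because the collocation matrix is ill-conditioned.
    """
    n = len(elements.segment_ids)
    q_cm = elements.flow * 1e-12
    in_flux: dict[int, float] = {nid: 0.0 for nid in net.nodes}
    d_in_o2: dict[int, np.ndarray] = {}
    for nid, influx in flow.boundary_influx.items():
        in_flux[nid] += influx * 1e-12  # inlet content is fixed: zero sensitivity
    out_elems: dict[int, list[int]] = {nid: [] for nid in net.nodes}
    down_node = np.where(elements.flow >= 0, elements.node_b, elements.node_a)
    up_node = np.where(elements.flow >= 0, elements.node_a, elements.node_b)
    for k in range(n):
        if elements.perfused[k]:
            out_elems[int(up_node[k])].append(k)
            in_flux.setdefault(int(down_node[k]), 0.0)
    order = sorted(
        (nid for nid in net.nodes if np.isfinite(flow.node_pressure[nid])),
        key=lambda nid: -flow.node_pressure[nid],
    )
    w = np.zeros((n, n))
    for nid in order:
        dc_node = (
            d_in_o2.pop(nid) / in_flux[nid]
            if nid in d_in_o2 and in_flux[nid] > 0
            else np.zeros(n)
        )
        for k in out_elems[nid]:
            qq = abs(q_cm[k])
            w[k] = dc_node
            w[k, k] -= 0.5 / qq
            dc_out = dc_node.copy()
            dc_out[k] -= 1.0 / qq
            dn = int(down_node[k])
            in_flux[dn] = in_flux.get(dn, 0.0) + qq
            if dn in d_in_o2:
                d_in_o2[dn] += qq * dc_out
            else:
                d_in_o2[dn] = qq * dc_out
    return w


# ---------------------------------------------------------------------------
# Tissue lattice
# ---------------------------------------------------------------------------


@dataclass
class TissueLattice:
    origin: np.ndarray  # (3,) μm
    spacing: float  # μm
    shape: tuple[int, int, int]
    include: np.ndarray  # bool, shape == .shape (lumen & mask exclusions)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.shape[i]) for i in range(3)
        )

    def points(self) -> np.ndarray:
        ax = self.axes()
        grid = np.meshgrid(*ax, indexing="ij")
        return np.stack([g.ravel() for g in grid], axis=1)

    @property
    def cell_volume_cm3(self) -> float:
        return (self.spacing * UM_TO_CM) ** 3


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a[None, :] + t[:, None] * ab[None, :]
    return np.linalg.norm(points - proj, axis=1)


def build_tissue_lattice(
    net: VesselNetwork,
    params: OxyParams,
    mask: Callable[[np.ndarray], np.ndarray] | None = None,
) -> TissueLattice:
    """Regular lattice over the inflated bounding box, lumen points excluded."""
    lo, hi = net.bounding_box
    origin = lo - params.tissue_margin
    extent = hi + params.tissue_margin - origin
    shape = tuple(int(np.floor(extent[i] / params.tissue_spacing)) + 1 for i in range(3))
    lat = TissueLattice(origin, params.tissue_spacing, shape, np.ones(shape, dtype=bool))
    pts = lat.points()
    include = np.ones(len(pts), dtype=bool)
    for seg in net.segments.values():
        a = net.nodes[seg.node_a].position
        b = net.nodes[seg.node_b].position
        near = np.abs(pts - 0.5 * (a + b)).max(axis=1) <= 0.5 * np.linalg.norm(b - a) + seg.diameter
        if np.any(near):
            dist = _point_segment_distance(pts[near], a, b)
            sub = include[near]
            sub[dist <= seg.diameter / 2.0] = False
            include[near] = sub
    if mask is not None:
        include &= np.asarray(mask(pts), dtype=bool)
    lat.include = include.reshape(shape)
    return lat


def _sink_kernel(lat: TissueLattice, params: OxyParams) -> np.ndarray:
    """Lattice-offset Green's kernel for the FFT sink convolution."""
    shape = lat.shape
    offs = [np.arange(-(m - 1), m) for m in shape]
    oi, oj, ok = np.meshgrid(*offs, indexing="ij")
    r = lat.spacing * np.sqrt(oi**2 + oj**2 + ok**2)
    kern = greens_kernel(np.where(r == 0, 1.0, r), params.d_tissue, params.alpha_tissue)
    # self term: center potential of an equal-volume uniform sphere
    a_cell = (3.0 * lat.cell_volume_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    kern[(shape[0] - 1, shape[1] - 1, shape[2] - 1)] = 1.5 / (
        4.0 * np.pi * params.d_tissue * params.alpha_tissue * a_cell
    )
    return kern


def _sink_field_grid(
    s_grid: np.ndarray, lat: TissueLattice, params: OxyParams,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Σ_t s_t·G on the full lattice, via FFT convolution (exact pairwise sum)."""
    if kernel is None:
        kernel = _sink_kernel(lat, params)
    return fftconvolve(s_grid, kernel, mode="valid")


def _vessel_field(
    points: np.ndarray, elements: VesselElements, q: np.ndarray, params: OxyParams,
    chunk: int = 4_000_000,
) -> np.ndarray:
    """Σ_v q_v·G(|x − x_v|) at arbitrary points, radius-regularized."""
    n_pts = len(points)
    out = np.zeros(n_pts)
    idx = np.where(q != 0.0)[0]
    if len(idx) == 0:
        return out
    rows = max(1, chunk // max(len(idx), 1))
    denom = 4.0 * np.pi * params.d_tissue * params.alpha_tissue * UM_TO_CM
    for start in range(0, n_pts, rows):
        p = points[start : start + rows]
        d = np.linalg.norm(p[:, None, :] - elements.midpoints[None, idx, :], axis=2)
        d = np.maximum(d, elements.radii[idx][None, :])
        out[start : start + rows] = (q[idx][None, :] / d).sum(axis=1) / denom
    return out


def _vessel_matrix(elements: VesselElements, idx: np.ndarray, params: OxyParams) -> np.ndarray:
    """Vessel–vessel kernel matrix with finite-line self terms (cm-consistent)."""
    mids = elements.midpoints[idx]
    radii = elements.radii[idx]
    lens = elements.lengths[idx]
    r = np.linalg.norm(mids[:, None, :] - mids[None, :, :], axis=2)
    r = np.maximum(r, radii[None, :])
    g = 1.0 / (4.0 * np.pi * params.d_tissue * params.alpha_tissue * r * UM_TO_CM)
    # diagonal: surface potential of a finite line source of length l, radius a
    l_cm = lens * UM_TO_CM
    a_cm = radii * UM_TO_CM
    diag = 2.0 * np.arcsinh(l_cm / (2.0 * a_cm)) / (
        4.0 * np.pi * params.d_tissue * params.alpha_tissue * l_cm
    )
    np.fill_diagonal(g, diag)
    return g


# ---------------------------------------------------------------------------
# Oxygen field result
# ---------------------------------------------------------------------------


@dataclass
class OxygenField:
    segment_ids: list[int]
    element_po2: np.ndarray  # mmHg
    element_saturation: np.ndarray
    element_q: np.ndarray  # cm³O₂/s
    element_midpoints: np.ndarray  # (n, 3) μm
    tissue_points: np.ndarray  # (m, 3) μm, included sample points
    tissue_po2: np.ndarray  # mmHg
    lattice: TissueLattice
    grid_po2: np.ndarray  # full lattice field (shape == lattice.shape)
    p_far: float  # P∞, mmHg
    o2_influx: float  # cm³O₂/s
    o2_outflux: float  # cm³O₂/s
    total_consumption: float  # cm³O₂/s (= Σ sinks at the final iterate)
    iterations: int
    final_change: float  # mmHg, last max PO₂ update
    converged: bool
    n_clamped_tissue: int = 0
    n_clamped_vessel: int = 0
    params: OxyParams | None = None

    @property
    def total_efflux(self) -> float:
        return float(self.element_q.sum())

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(vessel_po2.csv, tissue_po2.csv) DataFrames."""
        vessel = pd.DataFrame(
            {
                "element_id": self.segment_ids,
                "s": self.element_saturation,
                "po2": self.element_po2,
                "q": self.element_q,
            }
        )
        tissue = pd.DataFrame(
            {
                "x": self.tissue_points[:, 0],
                "y": self.tissue_points[:, 1],
                "z": self.tissue_points[:, 2],
                "po2": self.tissue_po2,
            }
        )
        return vessel, tissue


# ---------------------------------------------------------------------------
# Main solver
# ---------------------------------------------------------------------------


def solve_oxygen(
    net: VesselNetwork,
    flow: FlowSolution,
    params: OxyParams | None = None,
    tissue_mask: Callable[[np.ndarray], np.ndarray] | None = None,
) -> OxygenField:
    """Coupled convection/diffusion fixed point on a solved network.

    Preconditions: ``flow`` solved on ``net``; the network resampled so that
    no segment exceeds ``params.element_len``. Raises on unperfused networks;
    non-convergence is flagged on the result, never silent.

    ``tissue_mask`` optionally restricts consuming/sampled tissue to a
    sub-region of the lattice (used by cylinder-geometry validation tests).
    """
    params = params or OxyParams()
    max_len = max(s.length for s in net.segments.values())
    if max_len > params.element_len * (1 + 1e-9):
        raise ConfigurationError(
            f"network not resampled: max segment length {max_len:.3g} μm exceeds "
            f"element_len {params.element_len:.3g} μm"
        )
    elements = build_elements(net, flow)
    if not np.any(elements.perfused):
        raise DegenerateNetworkError("no perfused segment; cannot transport oxygen")

    lat = build_tissue_lattice(net, params, mask=tissue_mask)
    if not np.any(lat.include):
        raise DegenerateNetworkError("tissue lattice has no included sample points")
    pts_all = lat.points()
    axes = lat.axes()

    damp = 0.5
    h_d = flow.params.discharge_hematocrit if flow.params is not None else 0.45
    pidx = np.where(elements.perfused)[0]
    g_vv = _vessel_matrix(elements, pidx, params)
    nv = len(pidx)
    w_conv = convective_sensitivity(net, flow, elements)[np.ix_(pidx, pidx)]

    # cache the vessel->tissue kernel matrix when it fits comfortably
    gtv = None
    if pts_all.shape[0] * nv <= 32_000_000:
        denom = 4.0 * np.pi * params.d_tissue * params.alpha_tissue * UM_TO_CM
        gtv = np.empty((pts_all.shape[0], nv))
        rows = max(1, 4_000_000 // max(nv, 1))
        for start in range(0, pts_all.shape[0], rows):
            p = pts_all[start : start + rows]
            d = np.linalg.norm(p[:, None, :] - elements.midpoints[None, pidx, :], axis=2)
            np.maximum(d, elements.radii[pidx][None, :], out=d)
            gtv[start : start + rows] = 1.0 / (denom * d)

    def vessel_grid_field(q_vec: np.ndarray) -> np.ndarray:
        if gtv is not None:
            return (gtv @ q_vec[pidx]).reshape(lat.shape)
        return _vessel_field(pts_all, elements, q_vec, params).reshape(lat.shape)

    grid_p = np.full(lat.shape, float(params.p_inlet))
    q = np.zeros(len(elements.segment_ids))
    n_clamped_tissue = 0
    converged = False
    change = np.inf
    it = 0
    march = convective_march(net, flow, params, elements, q)
    p_far = float(params.p_inlet)
    phi_sink_grid = np.zeros(lat.shape)
    sink_kernel = _sink_kernel(lat, params)

    for it in range(1, params.max_iter + 1):
        # tissue consumption at the current iterate (clamped below zero)
        p_cons = np.maximum(grid_p, 0.0)
        n_clamped_tissue = int(np.sum((grid_p < 0) & lat.include))
        m_rate = params.m0 * p_cons / (p_cons + params.p_m)
        s_grid = np.where(lat.include, m_rate * lat.cell_volume_cm3, 0.0)
        s_total = float(s_grid.sum())

        phi_sink_grid = _sink_field_grid(s_grid, lat, params, sink_kernel)
        interp = RegularGridInterpolator(axes, phi_sink_grid, bounds_error=False, fill_value=None)
        phi_sink_v = interp(elements.midpoints[pidx])

        # vessel-surface matching with the convective feedback linearized
        # into the matrix (P_wall(q) ≈ P_wall(q⁰) + W·(q − q⁰)/C') and the
        # total-balance constraint appended. Elements whose requested efflux
        # exceeds what their blood can deliver are pinned at the deliverable
        # value (active set) and the shortfall is redistributed over the
        # free elements, so Σq tracks Σs even with clamps engaged.
        p_wall = march.element_po2[pidx]
        p_wall = np.where(np.isfinite(p_wall), p_wall, params.p_inlet)
        cprime = content_derivative(p_wall, params, h_d)
        s_conv = -w_conv / cprime[:, None]  # positive feedback-stabilizing term
        b_full = g_vv + s_conv
        rhs_base = p_wall + s_conv @ q[pidx] + phi_sink_v
        pinned = np.zeros(nv, dtype=bool)
        pin_val = np.zeros(nv)
        for _ in range(4):
            free = ~pinned
            nf = int(free.sum())
            if nf == 0:
                break
            a_sys = np.zeros((nf + 1, nf + 1))
            a_sys[:nf, :nf] = b_full[np.ix_(free, free)]
            a_sys[:nf, nf] = 1.0
            a_sys[nf, :nf] = 1.0
            rhs = np.empty(nf + 1)
            rhs[:nf] = rhs_base[free]
            if pinned.any():
                rhs[:nf] -= b_full[np.ix_(free, pinned)] @ pin_val[pinned]
            rhs[nf] = s_total - pin_val[pinned].sum()
            sol = np.linalg.solve(a_sys, rhs)
            p_far = float(sol[nf])
            q_req = np.zeros_like(q)
            q_req[pidx[free]] = sol[:nf]
            q_req[pidx[pinned]] = pin_val[pinned]
            march = convective_march(net, flow, params, elements, q_req)
            delivered = march.element_q_delivered[pidx]
            requested = q_req[pidx]
            viol = free & (
                np.abs(delivered - requested) > 1e-14 + 1e-9 * np.abs(requested)
            )
            if not viol.any():
                break
            pinned |= viol
            pin_val[viol] = delivered[viol]
        q = march.element_q_delivered

        phi_v = vessel_grid_field(q)
        grid_new = p_far + phi_v - phi_sink_grid
        change = float(np.max(np.abs(grid_new - grid_p)))
        grid_p = damp * grid_new + (1.0 - damp) * grid_p
        if change < params.tol * params.p_inlet:
            converged = True
            break
    if not converged:
        logger.warning(
            "oxygen solve did not converge in %d iterations (last change %.3e mmHg)",
            params.max_iter, change,
        )

    # final consistent field for the final q
    phi_v = vessel_grid_field(q)
    p_cons = np.maximum(grid_p, 0.0)
    m_rate = params.m0 * p_cons / (p_cons + params.p_m)
    s_grid = np.where(lat.include, m_rate * lat.cell_volume_cm3, 0.0)
    phi_sink_grid = _sink_field_grid(s_grid, lat, params, sink_kernel)
    grid_p = p_far + phi_v - phi_sink_grid
    # tolerate sub-resolution negative excursions; flag anything real
    neg = grid_p < 0
    if np.any(neg & lat.include):
        worst = float(grid_p[neg & lat.include].min())
        if worst > -1e-6 * params.p_inlet:
            grid_p = np.maximum(grid_p, 0.0)
        else:
            converged = False
            logger.warning("negative tissue PO₂ (min %.3e mmHg); solve flagged", worst)

    element_po2 = march.element_po2.copy()
    # unperfused elements equilibrate with the local tissue
    interp = RegularGridInterpolator(axes, grid_p, bounds_error=False, fill_value=None)
    unperf = ~elements.perfused
    if np.any(unperf):
        element_po2[unperf] = interp(elements.midpoints[unperf])
    h_d = flow.params.discharge_hematocrit if flow.params is not None else 0.45

    return OxygenField(
        segment_ids=elements.segment_ids,
        element_po2=element_po2,
        element_saturation=hill_saturation(element_po2, params.p50, params.hill_n),
        element_q=q,
        element_midpoints=elements.midpoints,
        tissue_points=pts_all[lat.include.ravel()],
        tissue_po2=grid_p.ravel()[lat.include.ravel()],
        lattice=lat,
        grid_po2=grid_p,
        p_far=p_far,
        o2_influx=march.o2_influx,
        o2_outflux=march.o2_outflux,
        total_consumption=float(s_grid.sum()),
        iterations=it,
        final_change=change,
        converged=converged,
        n_clamped_tissue=n_clamped_tissue,
        n_clamped_vessel=march.n_clamped,
        params=params,
    )
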