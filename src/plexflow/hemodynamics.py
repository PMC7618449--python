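"""Steady-state pore-network blood flow.

Each segment is a Poiseuille conduit with an effective viscosity from the
Fåhræus–Lindqvist effect; nodal mass conservation gives a sparse symmetric
positive-definite pressure system; segment flows, boundary fluxes and
red-blood-cell transit times follow.

Units: d, L in μm; μ in mPa·s; p in mmHg; Q in μm³/s; τ in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, DegenerateNetworkError
from .network import BoundaryKind, VesselNetwork
from .params import HemoParams

#: mPa·s expressed in mmHg·s (1 mPa·s = 1e-3 Pa·s / 133.322 Pa/mmHg).
MPAS_TO_MMHG_S = 1e-3 / 133.322

#: Segments with |Q| below this fraction of max|Q| are treated as unperfused
#: (avoids division blow-ups in transit times).
UNPERFUSED_REL_THRESHOLD = 1e-12


def relative_viscosity(d: float | np.ndarray, h_d: float) -> float | np.ndarray:
    """Relative apparent blood viscosity η_rel(d, H_D), in-vitro law.

    Empirical in-vitro diameter/hematocrit law of Pries, Neuhaus & Gaehtgens
    (1992), the standard closure for pore-network microvascular models:

        η*₀.₄₅(d) = 220·e^(−1.3 d) + 3.2 − 2.44·e^(−0.06 d^0.645)
        C(d) = (0.8 + e^(−0.075 d})·(−1 + 1/(1+10⁻¹¹ d¹²)) + 1/(1+10⁻¹¹ d¹²)
        η_rel(d, H_D) = 1 + (η*₀.₄₅ − 1)·((1−H_D)^C − 1)/((1−0.45)^C − 1)

    with d in μm. η_rel(d, 0) = 1 exactly (pure plasma); the minimum of the
    H_D = 0.45 curve lies near 7 μm and rises steeply for smaller diameters.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ConfigurationError("diameter must be > 0")
    if not 0 <= h_d < 1:
        raise ConfigurationError("discharge hematocrit must lie in [0, 1)")
    eta45 = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
    t = 1.0 / (1.0 + 1e-11 * d**12)
    c = (0.8 + np.exp(-0.075 * d)) * (-1.0 + t) + t
    eta = 1.0 + (eta45 - 1.0) * (((1.0 - h_d) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0))
    return float(eta) if eta.ndim == 0 else eta


def effective_viscosity(d: float | np.ndarray, params: HemoParams) -> float | np.ndarray:
    """μ_eff = μ_p · η_rel (mPa·s), or μ_p in constant mode."""
    if params.viscosity_law == "constant":
        return params.plasma_viscosity * np.ones_like(np.asarray(d, dtype=float))
    return params.plasma_viscosity * relative_viscosity(d, params.discharge_hematocrit)


def segment_conductance(d: float | np.ndarray, length: float | np.ndarray,
                        mu_eff: float | np.ndarray) -> float | np.ndarray:
    """Poiseuille conductance G = π d⁴ / (128 μ_eff L), μm³/(s·mmHg)."""
    d = np.asarray(d, dtype=float)
    length = np.asarray(length, dtype=float)
    mu_eff = np.asarray(mu_eff, dtype=float)
    if np.any(d <= 0) or np.any(length <= 0) or np.any(mu_eff <= 0):
        raise ConfigurationError("d, L and μ_eff must all be > 0")
    g = np.pi * d**4 / (128.0 * mu_eff * MPAS_TO_MMHG_S * length)
    return float(g) if g.ndim == 0 else g


@dataclass
class FlowSolution:
    """Result of a pressure solve on a vessel network."""

    node_pressure: dict[int, float]  # mmHg (NaN on isolated components)
    segment_flow: dict[int, float]  # μm³/s, signed node_a -> node_b
    segment_viscosity: dict[int, float]  # mPa·s
    segment_transit_time: dict[int, float | None]  # s; None if unperfused
    boundary_influx: dict[int, float]  # μm³/s entering at boundary nodes
    boundary_outflux: dict[int, float]  # μm³/s leaving at boundary nodes
    total_inflow: float  # μm³/s
    unperfused_segments: list[int] = field(default_factory=list)
    isolated_nodes: list[int] = field(default_factory=list)
    params: HemoParams | None = None

    @property
    def total_inflow_nl_min(self) -> float:
        """Q_total in nl/min (1 nl/min = 1e6/60 μm³/s)."""
        return self.total_inflow * 60.0 / 1e6

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(flows.csv, pressures.csv) DataFrames."""
        flows = pd.DataFrame(
            {
                "segment_id": sorted(self.segment_flow),
                "Q": [self.segment_flow[s] for s in sorted(self.segment_flow)],
                "mu_eff": [self.segment_viscosity[s] for s in sorted(self.segment_flow)],
                "tau": [self.segment_transit_time[s] for s in sorted(self.segment_flow)],
            }
        )
        pressures = pd.DataFrame(
            {
                "node_id": sorted(self.node_pressure),
                "p": [self.node_pressure[n] for n in sorted(self.node_pressure)],
            }
        )
        return flows, pressures


def solve_flow(net: VesselNetwork, params: HemoParams | None = None) -> FlowSolution:
    """Solve nodal mass conservation Σ G·Δp = 0 for pressures and flows.

    Boundary nodes are Dirichlet (their annotated pressures, falling back on
    ``params.p_in`` / ``params.p_out``). Components without any boundary node
    are reported and assigned zero flow; at least one component must connect
    an inlet to an outlet.
    """
    params = params or HemoParams()
    net.validate(require_boundaries=True)

    seg_ids = sorted(net.segments)
    node_ids = sorted(net.nodes)
    node_idx = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)

    d = np.array([net.segments[s].diameter for s in seg_ids])
    length = np.array([net.segments[s].length for s in seg_ids])
    mu = np.asarray(effective_viscosity(d, params)) * np.ones_like(d)
    g = np.asarray(segment_conductance(d, length, mu))
    ia = np.array([node_idx[net.segments[s].node_a] for s in seg_ids])
    ib = np.array([node_idx[net.segments[s].node_b] for s in seg_ids])

    # Dirichlet values
    dirichlet = np.full(n, np.nan)
    for nid, node in net.nodes.items():
        if node.boundary_kind == BoundaryKind.INLET:
            dirichlet[node_idx[nid]] = (
                node.boundary_pressure if node.boundary_pressure is not None else params.p_in
            )
        elif node.boundary_kind == BoundaryKind.OUTLET:
            dirichlet[node_idx[nid]] = (
                node.boundary_pressure if node.boundary_pressure is not None else params.p_out
            )
    is_dirichlet = ~np.isnan(dirichlet)

    # connected components; drop those without a boundary node
    lap = sp.coo_matrix(
        (np.concatenate([g, g]), (np.concatenate([ia, ib]), np.concatenate([ib, ia]))),
        shape=(n, n),
    ).tocsr()
    n_comp, comp = sp.csgraph.connected_components(lap, directed=False)
    comp_has_bc = np.zeros(n_comp, dtype=bool)
    comp_has_in = np.zeros(n_comp, dtype=bool)
    comp_has_out = np.zeros(n_comp, dtype=bool)
    for nid, node in net.nodes.items():
        c = comp[node_idx[nid]]
        if node.boundary_kind == BoundaryKind.INLET:
            comp_has_bc[c] = comp_has_in[c] = True
        elif node.boundary_kind == BoundaryKind.OUTLET:
            comp_has_bc[c] = comp_has_out[c] = True
    if not np.any(comp_has_in & comp_has_out):
        raise DegenerateNetworkError(
            "no connected component contains both an inlet and an outlet"
        )
    active = comp_has_bc[comp]
    isolated_nodes = [nid for nid in node_ids if not active[node_idx[nid]]]

    pressure = np.full(n, np.nan)
    pressure[is_dirichlet] = dirichlet[is_dirichlet]
    free = active & ~is_dirichlet
    if np.any(free):
        deg_g = np.zeros(n)
        np.add.at(deg_g, ia, g)
        np.add.at(deg_g, ib, g)
        a_full = sp.diags(deg_g) - lap
        f_idx = np.where(free)[0]
        b_idx = np.where(is_dirichlet)[0]
        a_ff = a_full[f_idx][:, f_idx].tocsc()
        a_fb = a_full[f_idx][:, b_idx]
        rhs = -a_fb @ dirichlet[b_idx]
        try:
            p_free = spla.spsolve(a_ff, rhs)
        except Exception as exc:  # pragma: no cover - scipy raises rarely here
            raise DegenerateNetworkError(f"singular pressure system: {exc}") from exc
        if not np.all(np.isfinite(p_free)):
            bad = comp[f_idx[~np.isfinite(p_free)][0]]
            raise DegenerateNetworkError(
                f"singular pressure system on component {bad}"
            )
        res = a_ff @ p_free - rhs
        rhs_norm = np.linalg.norm(rhs)
        if rhs_norm > 0 and np.linalg.norm(res) > 1e-12 * max(rhs_norm, 1.0) * 1e3:
            raise DegenerateNetworkError(
                f"pressure solve residual too large: {np.linalg.norm(res):.3e}"
            )
        pressure[f_idx] = p_free

    q = np.where(active[ia], g * (pressure[ia] - pressure[ib]), 0.0)
    q = np.nan_to_num(q, nan=0.0)
    q_max = np.max(np.abs(q)) if len(q) else 0.0
    perfused = np.abs(q) > UNPERFUSED_REL_THRESHOLD * q_max if q_max > 0 else np.zeros_like(q, dtype=bool)

    # interior-node residual check (mass conservation)
    residual = np.zeros(n)
    np.add.at(residual, ia, -q)
    np.add.at(residual, ib, q)
    interior = active & ~is_dirichlet
    if q_max > 0 and np.any(interior):
        worst = np.max(np.abs(residual[interior]))
        if worst > 1e-9 * q_max:
            raise DegenerateNetworkError(
                f"interior mass-conservation residual {worst:.3e} exceeds 1e-9·max|Q|"
            )

    volume = np.pi * d**2 * length / 4.0
    tau: dict[int, float | None] = {}
    for k, sid in enumerate(seg_ids):
        tau[sid] = float(volume[k] / np.abs(q[k])) if perfused[k] else None

    influx: dict[int, float] = {}
    outflux: dict[int, float] = {}
    for nid, node in net.nodes.items():
        if not is_dirichlet[node_idx[nid]]:
            continue
        inj = -float(residual[node_idx[nid]])  # net flow injected into the network
        if inj > 0:
            influx[nid] = inj
        elif inj < 0:
            outflux[nid] = -inj

    return FlowSolution(
        node_pressure={nid: float(pressure[node_idx[nid]]) for nid in node_ids},
        segment_flow={sid: float(q[k]) for k, sid in enumerate(seg_ids)},
        segment_viscosity={sid: float(mu[k]) for k, sid in enumerate(seg_ids)},
        segment_transit_time=tau,
        boundary_influx=influx,
        boundary_outflux=outflux,
        total_inflow=float(sum(influx.values())),
        unperfused_segments=[sid for k, sid in enumerate(seg_ids) if not perfused[k]],
        isolated_nodes=isolated_nodes,
        params=params,
    )


@dataclass
class TransitSummary:
    per_segment: dict[int, float]  # s, perfused segments only
    flow_weighted_mean: float  # s
    flow_weighted_median: float  # s
    n_unperfused: int


def transit_time_distribution(flow: FlowSolution, net: VesselNetwork) -> TransitSummary:
    """Per-segment RBC transit times τ = volume/|Q| and flow-weighted summary.

    Each segment's τ is weighted by its share of |Q|; unperfused segments are
    excluded and counted.
    """
    taus, weights = [], []
    per_segment: dict[int, float] = {}
    for sid, t in flow.segment_transit_time.items():
        if t is None:
            continue
        per_segment[sid] = t
        taus.append(t)
        weights.append(abs(flow.segment_flow[sid]))
    if not taus:
        raise DegenerateNetworkError("network is fully unperfused")
    taus_arr = np.array(taus)
    w = np.array(weights)
    w = w / w.sum()
    order = np.argsort(taus_arr)
    cum = np.cumsum(w[order])
    median = float(taus_arr[order][np.searchsorted(cum, 0.5)])
    return TransitSummary(
        per_segment=per_segment,
        flow_weighted_mean=float(np.sum(w * taus_arr)),
        flow_weighted_median=median,
        n_unperfused=len(flow.unperfused_segments),
    )
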