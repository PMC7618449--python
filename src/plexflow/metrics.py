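"""Integral quantities and morphometrics of solved capillary networks.

The three whole-network readouts of interest for early diabetic-retinopathy
modelling are

* **Q_total** — total flow rate perfusing the network,
* **extraction coefficient E** — mass fraction of oxygen crossing the
  capillary walls, ``E = 1 − (outgoing O₂ flux)/(incoming O₂ flux)``,
* **hypoxia susceptibility HS** — fraction of tissue sample points below a
  PO₂ threshold (default 15 mmHg), a scalar summary of tissue oxygenation;
  a threshold sweep is provided so other scalarizations can be recovered,

plus image-style morphometrics: line-scan vessel density (vessels crossing
an arbitrary line, per mm) and length-weighted diameter statistics.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .hemodynamics import FlowSolution, TransitSummary, transit_time_distribution
from .network import VesselNetwork
from .oxygen import OxygenField

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Integral quantities
# ---------------------------------------------------------------------------


def extraction_coefficient(flow: FlowSolution, oxy: OxygenField) -> float:
    """E = 1 − Σ_outlet Q·C_out / Σ_inlet Q·C_in ∈ [0, 1].

    By global O₂ conservation this equals total tissue consumption divided
    by total O₂ inflow (checked by :func:`o2_conservation_gap`).
    """
    if oxy.o2_influx <= 0:
        raise UndefinedMetricError("zero O₂ inflow; extraction undefined")
    return float(1.0 - oxy.o2_outflux / oxy.o2_influx)


def o2_conservation_gap(oxy: OxygenField) -> float:
    """Relative gap |(influx − outflux) − consumption| / max(influx, consumption)."""
    delivered = oxy.o2_influx - oxy.o2_outflux
    scale = max(oxy.o2_influx, oxy.total_consumption, 1e-300)
    return float(abs(delivered - oxy.total_consumption) / scale)


def hypoxia_susceptibility(oxy: OxygenField, p_h: float = 15.0) -> float:
    """Fraction of tissue sample points with PO₂ < p_h (volume fraction)."""
    if not p_h > 0:
        raise UndefinedMetricError("hypoxia threshold must be > 0")
    if len(oxy.tissue_po2) == 0:
        raise UndefinedMetricError("no tissue sample points")
    return float(np.mean(oxy.tissue_po2 < p_h))


def hypoxia_curve(oxy: OxygenField, thresholds: np.ndarray) -> pd.DataFrame:
    """HS as a curve over the threshold, for threshold-sweep reporting."""
    return pd.DataFrame(
        {"p_h": thresholds, "hs": [hypoxia_susceptibility(oxy, t) for t in thresholds]}
    )


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------


@dataclass
class LinescanResult:
    per_line: np.ndarray  # crossings per mm for each line
    counts: np.ndarray  # raw crossing counts per line
    offsets: np.ndarray  # μm, perpendicular offset of each line
    mean_per_mm: float
    sd_per_mm: float


def linescan_density(
    net: VesselNetwork,
    n_lines: int = 10,
    line_axis: str = "x",
    rng_seed: int = 0,
    offsets: np.ndarray | None = None,
) -> LinescanResult:
    """Vessels crossing straight lines cast across the planar field of view.

    Lines run parallel to ``line_axis`` (in the xy projection) at offsets
    drawn uniformly over the field from a seeded RNG (or given explicitly).
    A segment is counted when its endpoints straddle the line; a chain
    passing exactly through a node on the line counts once (half-open rule),
    and a segment lying exactly on the line counts once.
    """
    if n_lines < 1 and offsets is None:
        raise UndefinedMetricError("n_lines must be >= 1")
    if not net.segments:
        logger.warning("linescan_density on empty network: returning 0")
        z = np.zeros(max(n_lines, 1))
        return LinescanResult(z, z.copy(), z.copy(), 0.0, 0.0)
    along = 0 if line_axis == "x" else 1
    across = 1 - along
    lo, hi = net.bounding_box
    length_mm = (hi[along] - lo[along]) / 1000.0
    if length_mm <= 0:
        raise UndefinedMetricError("degenerate field of view")
    if offsets is None:
        rng = np.random.default_rng(rng_seed)
        offsets = rng.uniform(lo[across], hi[across], size=n_lines)
    offsets = np.asarray(offsets, dtype=float)

    pa = np.array([net.nodes[s.node_a].position[across] for s in net.segments.values()])
    pb = np.array([net.nodes[s.node_b].position[across] for s in net.segments.values()])
    counts = np.empty(len(offsets))
    for i, c in enumerate(offsets):
        straddle = (pa < c) != (pb < c)
        on_line = (pa == c) & (pb == c)
        counts[i] = straddle.sum() + on_line.sum()
    per_line = counts / length_mm
    return LinescanResult(
        per_line=per_line,
        counts=counts,
        offsets=offsets,
        mean_per_mm=float(per_line.mean()),
        sd_per_mm=float(per_line.std(ddof=1)) if len(per_line) > 1 else 0.0,
    )


@dataclass
class DiameterStats:
    mean: float  # μm, length-weighted
    median: float  # μm, length-weighted
    cv: float  # dimensionless
    table: pd.DataFrame = field(repr=False, default=None)


def diameter_stats(net: VesselNetwork) -> DiameterStats:
    """Length-weighted diameter mean/median/CV plus the per-segment table."""
    if not net.segments:
        raise UndefinedMetricError("diameter statistics undefined on empty network")
    d = np.array([s.diameter for s in net.segments.values()])
    w = np.array([s.length for s in net.segments.values()])
    w = w / w.sum()
    mean = float(np.sum(w * d))
    order = np.argsort(d)
    cum = np.cumsum(w[order])
    median = float(d[order][np.searchsorted(cum, 0.5)])
    var = float(np.sum(w * (d - mean) ** 2))
    table = pd.DataFrame(
        {
            "segment_id": sorted(net.segments),
            "diameter": [net.segments[s].diameter for s in sorted(net.segments)],
            "length": [net.segments[s].length for s in sorted(net.segments)],
        }
    )
    return DiameterStats(mean=mean, median=median, cv=float(np.sqrt(var) / mean), table=table)


# ---------------------------------------------------------------------------
# Per-network report and group summaries
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """All integral quantities of one solved network, plus a parameter echo."""

    label: str
    q_total_um3_s: float
    q_total_nl_min: float
    extraction: float
    hypoxia_susceptibility: float
    hypoxia_threshold: float
    tissue_po2_mean: float
    tissue_po2_min: float
    tissue_po2_p10: float
    linescan_mean_per_mm: float
    linescan_sd_per_mm: float
    diameter_mean: float
    diameter_median: float
    diameter_cv: float
    transit_mean_s: float
    transit_median_s: float
    n_segments: int
    n_unperfused: int
    oxygen_converged: bool
    oxygen_iterations: int
    o2_conservation_gap: float
    hemo_params: dict = field(default_factory=dict)
    oxy_params: dict = field(default_factory=dict)
    provenance: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


#: metrics aggregated by group_summary / compare_presets
SUMMARY_METRICS = [
    "q_total_nl_min",
    "extraction",
    "hypoxia_susceptibility",
    "tissue_po2_mean",
    "tissue_po2_min",
    "linescan_mean_per_mm",
    "diameter_mean",
    "transit_mean_s",
]


def compute_metrics(
    net: VesselNetwork,
    flow: FlowSolution,
    oxy: OxygenField,
    label: str = "",
    p_h: float = 15.0,
    n_lines: int = 10,
    linescan_seed: int = 0,
) -> MetricsReport:
    """Assemble the full per-network report from solved flow and oxygen."""
    transit: TransitSummary = transit_time_distribution(flow, net)
    lines = linescan_density(net, n_lines=n_lines, rng_seed=linescan_seed)
    dstats = diameter_stats(net)
    return MetricsReport(
        label=label,
        q_total_um3_s=flow.total_inflow,
        q_total_nl_min=flow.total_inflow_nl_min,
        extraction=extraction_coefficient(flow, oxy),
        hypoxia_susceptibility=hypoxia_susceptibility(oxy, p_h),
        hypoxia_threshold=p_h,
        tissue_po2_mean=float(np.mean(oxy.tissue_po2)),
        tissue_po2_min=float(np.min(oxy.tissue_po2)),
        tissue_po2_p10=float(np.percentile(oxy.tissue_po2, 10)),
        linescan_mean_per_mm=lines.mean_per_mm,
        linescan_sd_per_mm=lines.sd_per_mm,
        diameter_mean=dstats.mean,
        diameter_median=dstats.median,
        diameter_cv=dstats.cv,
        transit_mean_s=transit.flow_weighted_mean,
        transit_median_s=transit.flow_weighted_median,
        n_segments=len(net.segments),
        n_unperfused=transit.n_unperfused,
        oxygen_converged=oxy.converged,
        oxygen_iterations=oxy.iterations,
        o2_conservation_gap=o2_conservation_gap(oxy),
        hemo_params=flow.params.model_dump() if flow.params is not None else {},
        oxy_params=oxy.params.model_dump() if oxy.params is not None else {},
        provenance=net.provenance,
    )


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with pooled SD; NaN when SD is zero."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        return float("nan")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def group_summary(
    reports: list[MetricsReport], labels: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean ± sem and pairwise Cohen's d for each summary metric.

    Groups with fewer than 2 reports are excluded with a warning. Returns
    ``(summary, effects)`` DataFrames; row order is independent of report
    order.
    """
    if labels is None:
        labels = [r.label for r in reports]
    df = pd.DataFrame([r.to_dict() for r in reports])
    df["group"] = labels
    counts = df.groupby("group").size()
    keep = counts[counts >= 2].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.warning("group_summary: excluding group(s) with <2 reports: %s", dropped)
    df = df[df["group"].isin(keep)]
    if df.empty:
        raise UndefinedMetricError("no group has >= 2 reports")

    rows = []
    for group in sorted(keep):
        sub = df[df["group"] == group]
        for metric in SUMMARY_METRICS:
            vals = sub[metric].to_numpy(float)
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "n": len(vals),
                    "mean": vals.mean(),
                    "sem": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0,
                }
            )
    summary = pd.DataFrame(rows)

    eff_rows = []
    groups = sorted(keep)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            for metric in SUMMARY_METRICS:
                a = df[df["group"] == g1][metric].to_numpy(float)
                b = df[df["group"] == g2][metric].to_numpy(float)
                eff_rows.append(
                    {"group_a": g1, "group_b": g2, "metric": metric, "cohens_d": cohens_d(a, b)}
                )
    effects = pd.DataFrame(eff_rows)
    return summary, effects
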