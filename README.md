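# plexflow

Blood flow and tissue oxygenation modelling for retinal capillary networks,
built for studying how early microvascular changes in diabetic retinopathy —
subtle capillary narrowing and loss of vessel density in the deep vascular
plexus — translate into hemodynamic and metabolic consequences that cannot
be measured directly in tissue: total perfusion, red-blood-cell transit
times, oxygen extraction, and hypoxia susceptibility.

It is aimed at researchers who segment retinal vasculature from confocal
stacks (e.g. Imaris filament exports) and want whole-network functional
readouts, and at modellers who need a compact, validated pore-network +
Green's-function oxygen solver with a reproducible synthetic-network
generator for method development.

## Model

**Hemodynamics (pore network).** Each capillary segment is a Poiseuille
conduit with conductance

    G = π d⁴ / (128 μ_eff L),

where the effective viscosity μ_eff = μ_p · η_rel(d, H_D) follows the
empirical in-vitro diameter/hematocrit law of Pries et al. (1992)
(Fåhræus–Lindqvist effect). Nodal mass conservation ΣG·Δp = 0 with Dirichlet
pressures at inlets/outlets gives a sparse SPD system for the nodal
pressures; segment flows, boundary fluxes, and RBC transit times
τ = π d² L / (4|Q|) follow.

**Oxygen transport (Green's functions).** Intravascular O₂ content
C(P) = C_Hb·H_D·S(P) + α_pl·P with Hill saturation
S(P) = Pⁿ/(Pⁿ + P50ⁿ) is depleted convectively, Q·dC/dx = −q, by the
transmural efflux q of each vessel element. Vessel elements act as point
sources and the consuming tissue (Michaelis–Menten, M(P) = M0·P/(P+P_m))
as distributed sinks of the free-space diffusion kernel
G(r) = 1/(4π D α r):

    P(x) = P∞ + Σ_v q_v G(|x − x_v|) − Σ_t s_t G(|x − x_t|).

Source strengths are fixed by matching tissue PO₂ to intravascular PO₂ at
each vessel wall and by global balance Σq = Σs, solved in a damped fixed
point with the convective feedback folded into the matching matrix. An
independent finite-difference reaction–diffusion solver (`plexflow.fdref`)
validates the method on small fixtures, and the analytic Krogh cylinder
provides a closed-form oracle.

**Metrics.** Per network: Q_total (μm³/s and nl/min), oxygen extraction
coefficient E = 1 − outflux/influx ∈ [0,1], hypoxia susceptibility HS
(tissue fraction below a PO₂ threshold, default 15 mmHg, with a full
threshold sweep available), tissue PO₂ summaries, line-scan vessel density
(vessels crossing an arbitrary line, per mm), and length-weighted diameter
statistics. Group summaries report mean ± sem and Cohen's d.

**Synthetic networks.** `plexflow.synthetic` generates seeded deep-plexus
stand-ins: a jittered planar lattice over a 581 × 581 μm field with
log-normal diameters (mean 5.5 μm, CV 0.15) and connectivity-protected edge
pruning. The *diabetic* preset applies subtle capillary narrowing
(diameters ×0.9) and sparsification (25% of edges pruned vs 10%).

## Worked example

```python
import plexflow as pf
from plexflow.pipeline import RunConfig, process_network

net = pf.generate_plexus(pf.healthy_spec(seed=0))
config = RunConfig(mode="synthetic", design=pf.make_group_design(n_per_group=1),
                   oxy=pf.OxyParams(element_len=15.0, tissue_spacing=8.0))
report = process_network(net, config, label="healthy")
print(f"Q_total   = {report.q_total_nl_min:.2f} nl/min")
print(f"E         = {report.extraction:.4f}")
print(f"HS(15)    = {report.hypoxia_susceptibility:.3f}")
print(f"tissue PO2 mean/min = {report.tissue_po2_mean:.1f} / {report.tissue_po2_min:.1f} mmHg")
print(f"mean transit = {report.transit_mean_s*1e3:.2f} ms")
```

prints

```
Q_total   = 28.07 nl/min
E         = 0.0142
HS(15)    = 0.000
tissue PO2 mean/min = 58.5 / 57.2 mmHg
mean transit = 8.84 ms
```

i.e. this healthy synthetic plexus is perfused at ~28 nl/min, extracts
~1.4% of the delivered oxygen (consumption-limited, not supply-limited),
and keeps all tissue far above the 15 mmHg hypoxia threshold. Under the
diabetic preset the same seeds give roughly one-third the flow, ~60% longer
transit times and a ~3× higher extraction coefficient — the compensatory
pattern expected when narrowed, sparser capillaries slow red-cell transit.

The same pipeline is scriptable from the shell:

```bash
plexflow compare --n-per-group 6 --base-seed 0 --out out/
plexflow ingest --hoc retina.hoc --out out/   # Imaris .hoc skeletons
plexflow run --config run.yaml
```

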