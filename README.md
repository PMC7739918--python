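# strokeflow

One-dimensional pulsatile arterial blood flow from the heart to the pial
surface, with Murray's-law perfusion-territory mapping — a simulation
toolkit for *in silico* studies of acute ischaemic stroke.

## Who this is for

Computational physiologists and stroke modellers who need (a) pressure and
flow waveforms throughout an extended cerebral arterial network, (b) the
redistribution of flow when a vessel is occluded by a clot, and (c) a
principled map from arterial outlets to the brain-surface regions they
perfuse, as the coupling interface to tissue-perfusion models.

## The model

**Network.** A packaged table of 55 named large vessels (aorta, subclavian/
brachial, carotid and vertebro-basilar systems, the circle of Willis with
its communicating-artery loops, cerebellar and pontine branches) is wired
by anatomy and extended at the six major cerebral arteries with donor
cerebral trees — tabulated centreline data, or synthetic bifurcating trees
generated from Murray's law (`r_p³ = r₁³ + r₂³`) and a length-to-radius
ratio, terminating at ~0.4 mm pial outlets.

**Blood flow.** On every vessel the averaged 1D equations

    ∂A/∂t + ∂(Av̄)/∂x = 0
    ∂v̄/∂t + (2α−1)v̄ ∂v̄/∂x + (α−1)(v̄²/A) ∂A/∂x + (1/ρ)∂p/∂x = −2απμv̄/((α−1)ρA)

are closed by the elastic tube law `p = p_ref + (β/A₀)(√A − √A₀)`,
`β = √π E h/(1−ν²)`, and integrated with the second-order MacCormack
scheme.  Junctions couple through Riemann invariants, mass conservation and
total-pressure continuity (Newton–Raphson); the heart prescribes a periodic
inflow scaled to stroke volume and heart rate; every outlet carries a
three-element windkessel (R₁ = characteristic impedance, R₂, C) calibrated
from total peripheral resistance `R_tot = ((1/3)P_sys + (2/3)P_dia)/(SV·HR)`
and compliance `C_tot = τ/R_tot`, distributed by cardiac-output fractions
and cubed-radius (Murray) weighting.  A clot is a reflective face
(`v̄ = 0`, `∂p/∂x = 0`) that severs its downstream subtree.

**Territories.** Each cerebral outlet claims a connected set of triangles
on a labelled pial-surface mesh, sized by `f_i = r_i³/Σr_j³` within its
major-artery region, grown by geodesic (Dijkstra) distance and iterated
with 1-centre root updates; outlet mean flows are spread uniformly over
their territories.

See `docs/methods.md` for numerics, calibration details and limitations.

## Worked example

```python
from strokeflow import (
    ExperimentConfig, build_network, CardiacParameters,
    allocate_outlets, run_pulsatile_simulation, velocity_pulsatility_index,
)

net = build_network(ExperimentConfig(seed=1))     # 55 vessels + synthetic trees
cardiac = CardiacParameters()                     # HR 60, SV 70 ml, 17.3/10.1 kPa
outlets = allocate_outlets(net, cardiac)          # windkessel per outlet
res = run_pulsatile_simulation(net, cardiac=cardiac, outlets=outlets)

print(f"converged in {res.cycles} cycles")
for v in ("ascending aorta", "thoracic aorta", "R. brachial", "R. MCA"):
    print(f"{v:16s} {res.segment_mean_flow_mlmin(v):8.1f} ml/min")
print(f"R. MCA velocity PI {velocity_pulsatility_index(res.velocity_waveform('R. MCA')):.2f}")
```

prints

```
converged in 8 cycles
ascending aorta    4199.9 ml/min
thoracic aorta     2917.8 ml/min
R. brachial         223.0 ml/min
R. MCA              110.3 ml/min
R. MCA velocity PI 1.08
```

The ascending-aorta mean equals SV × HR = 4200 ml/min (mass conservation);
65% of cardiac output leaves through the thoracic aorta and 5% through each
brachial artery, modulated by the resolved network resistance; the
right-MCA velocity pulsatility index is the quantity transcranial Doppler
reports.  Adding `clot="R. MCA"` to the run zeroes every right-MCA-descended
outlet and redistributes its flow to the rest of the circulation.

A command-line interface wraps the same pipeline:

```bash
strokeflow run --config config.yaml --out results/
strokeflow simulate --network net.json --clot "R. MCA" --out occluded/
strokeflow map-territories --mesh pial.vtk --results results/ --out territories/
```

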