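# tdesens

**How much does a misplaced rectal thermometer change an estimated time of
death?** `tdesens` answers this question in silico for forensic scientists
and modellers: it simulates postmortem cooling of a synthetic multi-tissue
body phantom, samples cooling curves at the intended rectal measurement
point `C` and at six octahedrally displaced probe positions `SP_1..SP_6`
(radius R = 0.5, 1 or 2 cm), and quantifies the resulting deviation of the
temperature-based death-time estimate in **hours**, not degrees.

## Model

Cooling follows the heat conduction equation inside the body,

```
c ρ ∂T/∂t = ∇·(κ ∇T),
```

with a Robin boundary condition on the skin, `n·κ∇T = γ (T_A − T)`, where
the effective coefficient `γ = h + 4 ε σ T_A³` lumps convection and
linearised surface-to-ambient radiation (with h = 3.3 W/(m² K) and
ε = 0.95 this gives γ = 7.93 / 8.45 / 9.00 W/(m² K) at
T_A = 5 / 15 / 25 °C). The initial field at the time of death is either a
physiological core-to-skin gradient or the steady Pennes bioheat equation

```
−∇·(κ ∇T₀) + ρ_b c_b w (T₀ − T_core) = 0,
```

whose perfusion term w couples living tissue to the core blood
temperature. The solver is a 7-point finite-volume scheme on the voxel
grid with harmonic-mean interface conductivities and implicit-Euler
adaptive time stepping (max 1 K change per step, 0.1 s initial step).

Given two cooling curves T₁(t), T₂(t), the deviation metric inverts both
into time-since-death estimators t_i(T) and takes the maximum time
distance along the pointwise-mean reference curve T_R on a regular
K-point grid over the joint domain [t_MIN, t_MAX]:

```
D_MAX(T₁, T₂) = max_k | t₁(T_R(t^k)) − t₂(T_R(t^k)) |.
```

Local variants `D_MAX,Qi` restrict the maximum to the four Q-intervals of
normalised excess temperature Q = (T_R − T_A)/(T₀ − T_A) with boundaries
1, 0.5, 0.3, 0.2, 0.1 — the classical normed temperature ranges of
death-time nomograms.

Three phantom variants emulate typical study conditions: `free`
(left-right symmetric body floating in air), `on_substrate` (the same body
supine on a wet-soil slab, κ = 2 W/(m K), c = 2200 J/(kg K),
ρ = 1900 kg/m³) and `asymmetric` (perturbed organ layout with a bioheat
initial field).

## Worked example

```python
import tdesens as td
from tdesens import thermal

phantom = td.build_phantom(td.PhantomSpec(spacing=0.02))
bc = thermal.BoundaryCondition(T_A=15.0, h=3.3, emissivity=0.95)
T0 = thermal.gradient_initial_field(phantom, T_core=37.2, T_skin=28.0)
probes = td.make_octahedron_probes(phantom.rectal_probe, R=0.02)
curves = {c.probe_id: c for c in
          thermal.simulate_cooling(phantom, T0, bc, probes, t_end=45.0)}
res = td.d_max(curves["C"], curves["SP_4"], K=1000)
print(f"D_MAX(C, SP_4) = {res.d_max_global:.2f} h")
```

prints (2 cm grid, T_A = 15 °C, ventral probe at R = 2 cm):

```
D_MAX(C, SP_4) = 0.42 h
```

i.e. misplacing the thermometer 2 cm ventrally shifts the death-time
estimate by up to ~25 minutes; the Q-local maxima
(`Q1: 0.42, Q2: 0.38, Q3: 0.38, Q4: 0.38` h) show the error is largest
early in the cooling process. The central curve itself cools from 37.2 °C
through 24.8 °C at 12 h to 15.8 °C at 45 h.

The same pipeline is scriptable from the shell:

```
tdesens phantom build --spacing 0.01 --out phantom.h5
tdesens cool simulate --variant on_substrate --ta 5 --out curves.csv
tdesens metrics dmax curves.csv --probe2 SP_3@0.02 --out dmax.json
tdesens study run --config study.yaml --out table.csv
tdesens study summarize table.csv --out summary.csv
```

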