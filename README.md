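# gpmyo — integrative guinea-pig ventricular myocyte model

`gpmyo` is a whole-cell simulation model of the guinea-pig ventricular
myocyte that couples four subsystems that are usually modeled separately:

* **membrane electrophysiology** (fast Na⁺ current, inward and delayed
  rectifiers, pumps and exchangers, an ATP-sensitive K⁺ current),
* **local-control Ca²⁺-induced Ca²⁺ release**: 339,000 Ca²⁺ release units,
  each a single L-type Ca²⁺ channel (LCC) coupled to a cluster of five
  ryanodine receptors (RyRs) across a dyadic subspace whose Ca²⁺
  concentration is resolved algebraically under rapid equilibrium,
* **mitochondrial energetics** (Ca²⁺-regulated TCA cycle, oxidative
  phosphorylation, ΔΨ, Ca²⁺ uniporter, Na⁺/Ca²⁺ and Na⁺/H⁺ exchangers),
* **isometric force** (tropomyosin/crossbridge model fed back through
  troponin Ca²⁺ buffering and the acto-myosin ATPase).

The release unit is the scientific core.  Each unit's joint LCC × RyR
gating is a 40-state Markov chain (10 LCC states × 4 RyR states, indexed
`lcc_state * 4 + ryr_state`), and the dyadic Ca²⁺ for each open/closed
configuration is the root of the linear rapid-equilibrium balance

    0 = J_LCC(Ca_ss) + J_RyR(Ca_ss) + (Ca_i − Ca_ss) / τ_ss,

with a GHK-form unitary LCC flux and a gradient-driven RyR flux
`J_RyR = J_R (Ca_NSR − Ca_ss)`.  Because single-channel trigger flux falls
with depolarization while open probability rises, excitation–contraction
coupling gain `peak J_RyR / peak J_LCC` decreases monotonically with
voltage and SR release is a smooth, graded function of trigger influx —
the two signatures of local control that common-pool models cannot
reproduce together with stable action potentials.  A direct consequence,
and the model's central prediction, is that the guinea-pig Ca²⁺ transient
peaks late in the AP plateau: at strongly depolarized early-plateau
potentials LCC openings are plentiful but individually weak triggers, so
release builds up only as the plateau repolarizes into the high-gain
voltage range.

Who this is for: cardiac electrophysiology and systems-biology groups who
need a deterministic (non-stochastic) myocyte model with mechanistic
CICR, metabolite coupling, and force — e.g., to study how AP morphology
reshapes Ca²⁺ and force timing, or how mitochondrial Ca²⁺ handling feeds
back on the cytosolic transient.

## Quick start

```python
import gpmyo
from gpmyo import cell, analysis, protocols

p = gpmyo.load_reference()            # provenance-tagged parameter set
y0 = cell.load_initial_state()        # versioned 1 Hz end-diastolic state

res = protocols.run_protocol(protocols.pacing(bcl=1000.0, n_beats=1), p, y0)
print("APD90 [ms]:", analysis.apd(res.t, res.v, 0.9))
print("fractional SR release:", analysis.fractional_release(res))
```

The command-line interface exposes the same protocols
(`gpmyo pace`, `vclamp`, `apclamp`, `restitution`, `staircase`,
`workload`, `gain`, `reproduce`); each run writes CSV results, a metrics
JSON, and a provenance log (parameter-file hash + solver settings).

## Worked example

Recompute the steady-state 1 Hz beat and its headline metrics:

```bash
gpmyo reproduce steady-1hz --out out/
```

which paces the reference cell to its 1 Hz steady state (the shipped
initial state is already converged, so one verification beat suffices),
records one beat at 1-ms resolution, and prints the derived metrics next
to the model's published values:

```
apd90_1hz_ms                             190.64149167707933   (published: 189.0)
ca_delay_ms                              120.93950000000001   (published: 119.0)
ca_time_to_peak_ms                           131.4345
ryr_po_peak_pct                          2.908436652795645    (published: 2.9)
fractional_release_pct                   33.052823535809075   (published: 33.0)
subspace_oo_max_um                       42.56772125547739    (published: 45.0)
avg_subspace_peak_um                     1.5286022070723908
ca_peak_um                               0.6628054703807491
ca_dia_um                                0.11801917640489447
serca_removal_pct                        66.51669775966455    (published: 65.9)
ncx_removal_pct                          28.372834430957944   (published: 28.9)
sl_pump_removal_pct                      5.110467809377494    (published: 5.1)
mito_bolus_pct                           12.718503601064654   (published: 12.7)
recirculation_pct                        71.30486177245186    (published: 69.0)
```

Reading the output: the steady-state action potential lasts ~191 ms to
90% repolarization, and the cytosolic Ca²⁺ transient peaks ~121 ms after
the voltage peak (~131 ms after the stimulus) — the late, plateau-phase
release that local control produces in this species.  At the release
peak, only ~2.9% of RyR clusters are open, yet a third of the total SR
Ca²⁺ load leaves the store on each beat.  During relaxation, SERCa
resequesters about two-thirds of the cytosolic Ca²⁺, NCX extrudes a bit
under a third, the sarcolemmal pump handles ~5%, and the mitochondria
return a bolus ~13% the size of the net removal flux.

## Layout

```
src/gpmyo/
  caru.py          40-state coupled LCC-RyR release unit + Gillespie oracle
  sarcolemma.py    membrane currents and transporters
  ca_cycling.py    SERCa, buffers, Ca2+ balances
  mitochondria.py  TCA cycle, oxphos, mito Ca2+/Na+ handling
  contraction.py   crossbridge/troponin force model
  cell.py          state layout, jitted RHS, stiff integration, pacing
  protocols.py     declarative experiment definitions + runners
  analysis.py      APD, transient metrics, gain curves, flux fractions
  cli.py           command-line interface
  data/            reference parameters (YAML) + initial state (JSON)
docs/methods.md    model description, assumptions, numerical choices
tests/             unit/property tests and headline-output checks
```
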