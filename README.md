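# v1micro

Models of how the three major inhibitory interneuron classes — PV, SST
and VIP cells — shape contextual visual processing in mouse primary
visual cortex (V1).  The package is aimed at computational
neuroscientists who want to probe cell-type-specific inhibition in a
columnar circuit: it implements, end to end,

1. a **four-population firing-rate model** of the layer-2/3 microcircuit
   (Pyr, PV, SST, VIP), with steady-state enumeration, stability
   classification and input-threshold analysis, and
2. a **13-column spiking network** of 19,294-neuron cortical columns
   (leaky integrate-and-fire neurons, exponential postsynaptic currents,
   cell-type-specific superficial-layer connectivity, Poisson background
   and thalamic drives), plus the stimulus protocols and response
   statistics used to study figure-ground contrast, inter-object
   competition and top-down gain control.

## The model in brief

Layer-2/3 rates follow Wilson–Cowan-type dynamics with a square-root gain
fitted to the LIF F-I curve,

```
tau_m df_x/dt = -f_x + 5.33 * sqrt(net_x - theta) * H(net_x - theta)
```

with `theta = 360 pA`, `tau_m = 10 ms` and the structural sign pattern of
the interneuron circuit: PV inhibits Pyr and itself, SST inhibits all
other classes, VIP mainly inhibits SST.  The spiking column inherits the
layered-microcircuit lineage (layers 2/3, 4, 5, 6; identical LIF
parameters everywhere; cell-type-specific PSC amplitudes and decay
constants in layer 2/3), and columns interact through four superficial
pathways only — short-range Pyr→Pyr, Pyr→PV, PV→Pyr and long-range
Pyr→SST — on a periodic ring.

## Worked example

```python
import numpy as np
from v1micro import (RateModelParams, enumerate_steady_states,
                     scan_input, sst_silencing_threshold,
                     vip_activation_threshold)

params = RateModelParams()          # the published defaults

for ss in enumerate_steady_states(params, seed=0):
    print(ss.stability, np.round(ss.rates, 2), sorted(ss.active_set))

print("SST silencing threshold:", sst_silencing_threshold(params), "pA")
print("VIP activation threshold:", vip_activation_threshold(params), "pA")

grid = np.arange(360.0, 411.0, 5.0)
fe = scan_input(params, "v", grid, detect_cycles=False).max_stable_pyr()
print("Pyr rate vs VIP drive:", np.round(fe, 1))
```

prints

```
stable [10.63  3.01  1.22 18.87] ['e', 'p', 's', 'v']
unstable [ 1.62  1.24  0.   17.08] ['e', 'p', 'v']
stable [ 0.    0.87  0.   16.49] ['p', 'v']
SST silencing threshold: 365.0 pA
VIP activation threshold: 360.0 pA
Pyr rate vs VIP drive: [ 0.   6.5 10.6 13.6 16.2 15.7 14.9 13.9 12.7  0.   0. ]
```

Reading this: at the default inputs the circuit is bistable — a fully
active state (Pyr at 10.6 Hz) coexists with a Pyr-silent state in which
PV and VIP fire alone.  Driving SST cells beyond 365 pA abolishes every
Pyr-active attractor (the published silencing point); VIP cells, when cut
off from the recurrent circuit, turn on exactly at the 360 pA gain
threshold.  The last line is the disinhibition signature: raising VIP
drive first *increases* the best attainable Pyr rate (VIP suppresses
SST), peaks once SST falls silent, and beyond ~400 pA VIP's direct
inhibition wins — the only stable states left have silent pyramids.

Spiking-network protocols run the same way from presets:

```python
from v1micro import make_pulse_experiment, run_experiment, psth

spec = make_pulse_experiment(trials=20, scale=0.5, seed=11)
records = run_experiment(spec)           # 20 independent simulations
vip = psth(records, "L23_VIP", bin_width=1.0)
```

or from the command line:

```bash
v1micro build-check --scale 0.1
v1micro rate-scan --vary s --start 340 --stop 400 --step 2
v1micro reproduce-figure 4 --scale 0.1 --trials 10
```

## Layout

```
src/v1micro/
  params.py      # every printed model constant
  rate_model.py  # four-population rate model + fixed-point analysis
  network.py     # column/ring construction, budgets, validation
  lif.py         # exact-propagator LIF engine (numba)
  protocols.py   # background/thalamic drives, experiment presets
  analysis.py    # rates, PSTHs, onset latencies, column profiles, spectra
  io.py          # configs, spike/graph round-trip, run manifests
  cli.py         # build-check / rate-scan / run / analyze / reproduce-figure
docs/methods.md  # modelling and numerical choices, limitations
```
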