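# bbfse — black-blood 3D fast-spin-echo simulation toolkit

`bbfse` models the physics of black-blood whole-heart MR imaging with a 3D
variable-flip-angle fast spin echo (FSE) sequence. In this technique a
slab-selective 90° excitation is followed by a long train of non-selective
refocusing pulses whose flip angles are modulated so that a target tissue
(vessel wall / myocardium, T1 = 880 ms, T2 = 40 ms at 1.5 T) produces a
*constant* echo amplitude across the train. Blood is suppressed not by
preparation pulses but by flow: spins moving along the readout gradient
accumulate velocity-dependent phase during the startup echoes and dephase
before the centre of k-space is acquired.

The package provides:

- an **extended-phase-graph (EPG) engine** (`bbfse.epg`) tracking transverse
  (F\_k) and longitudinal (Z\_k) configuration states on an integer or
  half-integer dephasing-order lattice, with RF, relaxation, gradient-shift
  and constant-velocity flow-phase operators, plus an independent
  moving-isochromat Bloch oracle that the engine is verified against to
  < 1e-8;
- a **variable-flip-angle train designer** (`bbfse.vfa`) that inverts the EPG
  recursion echo by echo (bisection on the flip angle) to hold a constant
  plateau for the design tissue, with an automatic search for the largest
  feasible plateau;
- **protocol arithmetic** (`bbfse.sequence`): effective echo time, matrix
  sizing with SENSE and slice oversampling, centric view ordering, scan-time
  estimation;
- **flow experiments** (`bbfse.flowsim`): k0-signal velocity sweeps,
  echo-train curves, and the outer-volume experiment showing that tissue
  experiencing only the refocusing pulses contributes *exactly zero* echo
  signal (its FID pathways sit on the half-integer order lattice at echo
  times);
- a **2D double-inversion-recovery washout comparator** (`bbfse.dirmodel`):
  suppressed fraction = min(1, v·TI/W);
- a **synthetic cardiothoracic phantom** (`bbfse.phantom`) and the **local
  SNR/CNR metrics** (`bbfse.metrics`): SNR_l = I/SD(L), CNR_l = ΔI/SD(L)
  with a lung-air ROI (≥ 100 voxels) as the noise reference;
- a **CLI** (`bbfse …`) running reproducible experiment bundles.

## Worked example

```python
import numpy as np
from bbfse import *

timing = default_timing()                      # ESP2 3 ms, 8 startup + 35 acquired, TE_eff 30 ms
train  = design_vfa(WALL_TISSUE, timing, "auto")
sweep  = velocity_sweep(train, timing)         # blood 1600/250 ms, 0-100 mm/s
table, summary = compare_fse_dir(sweep)

print(f"TE_eff            : {compute_te_eff(timing):.1f} ms (k0 at echo {timing.k0_echo_index})")
print(f"plateau level     : {train.target_level:.4f} of M0")
print(f"first angles (deg): {np.round(train.angles[:10], 1)}")
print(f"residual at 30 mm/s : {sweep.residual_fraction[30]:.3f}")
print(f"FSE 75% crossing    : {summary['fse_crossing_mm_s']} mm/s")
print(f"DIR 75% crossing    : {summary['dir_crossing_analytic_mm_s']:.1f} mm/s")
print(f"outer-volume signal : {simulate_outer_volume(train, timing).max():.1f}")
```

prints

```
TE_eff            : 30.0 ms (k0 at echo 9)
plateau level     : 0.2315 of M0
first angles (deg): [180.  146.  100.6  76.7  60.7  49.   39.7  32.4  26.5  27. ]
residual at 30 mm/s : 0.800
FSE 75% crossing    : 84.0 mm/s
DIR 75% crossing    : 30.0 mm/s
outer-volume signal : 0.0
```

The designed train holds the vessel-wall signal at 23% of M0 for every
acquired echo (first pulse 180°, all later pulses < 180°); the k-space
centre is read at the 9th echo, 30 ms after excitation. The velocity sweep
shows how much blood signal survives at k0 as a function of constant
readout-axis velocity; under the default per-interval gradient moment of one
dephasing cycle per 1.3 mm voxel, 75% suppression is reached at 84 mm/s,
whereas the geometric DIR washout model (16 mm slice, TI 400 ms) reaches it
at 30 mm/s. The suppression scale depends directly on the per-interval
gradient moment `dk` — a configuration parameter of `SequenceTiming` — and
on it alone through the product `dk·v`; see `docs/methods.md` for the
sensitivity analysis. Outer-volume tissue contributes exactly zero signal at
every echo, which is why the sequence tolerates a low slice-oversampling
factor.

The phantom pipeline renders black-blood and bright-blood volumes of a
torso-like digital phantom and recovers SNR_l/CNR_l from label-mask ROIs:

```bash
bbfse run-experiment phantom_metrics --out out/
bbfse scan-time            # matrix sizing + nominal scan time for the protocol card
```

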