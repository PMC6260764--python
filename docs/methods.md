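# Methods

## The physical model

The package simulates a single voxel (or an ensemble of labelled voxels, in
the phantom) through a 3D fast-spin-echo train using the extended phase
graph (EPG) formalism. Magnetisation is decomposed into configuration
states: transverse F\_k and longitudinal Z\_k, where k counts accumulated
units of the per-interval gradient dephasing Δk (rad/mm). The operators are

- **RF pulse** (flip α, phase φ): each triple (F\_k, F\*\_{-k}, Z\_k) is
  rotated by the standard unitary EPG mixing matrix; phase 0 is a
  right-handed rotation about x, phase 90 about y.
- **Relaxation** over dt: F states scale by exp(−dt/T2), Z by exp(−dt/T1),
  with M0 regrowth into Z\_0.
- **Gradient shift**: F\_k → F\_{k+s}; Z unchanged.
- **Constant-velocity flow**: a state whose spatial frequency ramps linearly
  from k·Δk to (k+s)·Δk during dt acquires the first-moment phase
  exp(+i·Δk·(k+s/2)·v·dt/1000); longitudinal states advect with their
  constant frequency, exp(+i·Δk·k·v·dt/1000). v = 0 is an exact no-op, so
  static and flow-disabled simulations are bit-identical.

**Sequence timeline.** Echo n occurs at ESP1 + (n−1)·ESP2 after the 90°(x)
excitation; refocusing pulses are about y (CPMG). The per-interval dephasing
of one order unit is split as a half shift before and a half shift after
each echo read point (balanced crushers), so the engine always runs on the
half-integer order lattice. This placement has a structural consequence:
excited pathways occupy integer orders at echo times and half-integer orders
at pulse times, while pathways seeded from pure Z (tissue outside the
excitation slab, which sees only the non-selective refocusing pulses)
occupy exactly the opposite parity. Outer-volume FID signal at the echoes is
therefore *exactly* zero — not small, zero to machine precision — which is
the model's account of why the sequence needs only mild slice oversampling.

**Verification.** The engine is checked against an independent
moving-isochromat Bloch oracle: spins spread uniformly over one period of
the finest configuration frequency, rotated with rotation matrices (scipy
`Rotation`), relaxed in closed form, and phased by each gradient segment
using their midpoint positions while being advected at v. EPG and oracle
agree to < 1e-8 (typically ~1e-15) over random trains, tissues and
velocities, including the flow phases of both F and Z states. The all-180°
train with negligible T1 loss reproduces exp(−t/T2) to < 1e-9.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| ESP2 | 3.0 ms | inter-echo spacing |
| TE_eff | 30.0 ms | excitation → k0 echo; fixes ESP1 = TE_eff − n_startup·ESP2 = 6.0 ms |
| n_startup | 8 | simulated, non-acquired echoes; k0 at echo 9 |
| n_acquired | 35 | data echoes per shot |
| Δk (`dk`) | 2π/1.3 rad/mm | per-interval readout dephasing: one cycle per 1.3 mm readout voxel per echo spacing |
| design tissue | T1 880 / T2 40 ms | vessel-wall-like target of the constant-signal design |
| blood | T1 1600 / T2 250 ms | 1.5 T arterial blood for the velocity sweeps |
| max_angle / sub_cap | 180° / 175° | first refocusing pulse fixed at the cap; later pulses strictly below 180° |

## Train design

The designer prescribes per-echo amplitudes — a geometric ramp from the
(fixed 180° first-pulse) first-echo amplitude down to a plateau over the
startup echoes, then the constant plateau for every acquired echo — and
solves for each flip angle by scanning the amplitude-vs-angle curve for the
first bracket and refining with Brent's method (amplitude residual
< 1e-10). When two angles reach the target, the smaller is taken (lower RF
power). `target_level="auto"` bisects on the plateau to find the largest
feasible level (default resolution 1e-5). The resulting schedule dips from
180° to a minimum (~26°) at the plateau onset and rises smoothly towards
the train end to counter relaxation, with a predicted acquired-echo
coefficient of variation at round-off level.

## Flow suppression, and the gradient-moment caveat

The velocity sweep runs one EPG simulation per velocity and normalises the
k0 magnitude to the v = 0 run. Because every flow phase enters through the
product Δk·v, the residual curve obeys an exact scaling law —
residual(Δk, v) = residual(2Δk, v/2) — which the tests pin to 1e-12. The
default Δk (one dephasing cycle per readout voxel per interval) is the
moment of the readout gradient alone: at the protocol's pixel bandwidth the
readout occupies only ~0.6 ms of the 3.0 ms interval, and a scanner
implementation adds crusher lobes around each refocusing pulse whose areas
are not public. Under the readout-only default the model reaches 75% blood
suppression at 84 mm/s; reproducing 75% suppression at 30 mm/s — the regime
reported for this sequence family on hardware — requires an effective
per-interval moment near three cycles per voxel, i.e. substantial crushers.
`dk` is therefore an explicit configuration parameter rather than a hidden
constant. Two further modelling caveats: (i) strictly constant plug flow is
coherent, so the residual-vs-velocity curve shows interference oscillations
and is not monotone — real vessels with velocity spread and pulsatility
dephase more smoothly and more strongly; (ii) only the first moment of
constant-velocity motion is modelled; acceleration and higher-order motion,
which add further dephasing in vivo, are not.

## DIR comparator

The 2D double-inversion-recovery model is purely geometric: with ideal
inversion and exact nulling, the suppressed fraction at plug velocity v
perpendicular to the slice is min(1, v·TI/W). With the default W = 16 mm and
TI = 400 ms, 75% suppression falls exactly at 30 mm/s. Relaxation of
imperfectly nulled inflowing blood is deliberately out of scope — the
comparison is between the *geometric* washout mechanism and the
*gradient-dephasing* mechanism.

## Phantom and metrics

The phantom is a labelled 80×80×64 volume at 2.5 mm isotropic voxels
(torso-scale FOV at desk-scale memory cost): an elliptical chest-wall shell,
air interior standing in for lung, a myocardial shell around a ventricular
blood pool (50 mm/s along the readout axis, diastolic-filling scale), a
descending-aorta tube along the readout axis at 100 mm/s and an arch tube
perpendicular to it at the same speed. Rendering looks up the k0 EPG signal
per (tissue, readout-projected speed) — so readout-aligned flow renders
black while the same speed perpendicular to the readout renders like static
blood — scales chest wall by a static SPIR fat-suppression factor (0.1),
and adds Gaussian noise (SD 0.005 of M0, seeded). The bright-blood
comparator uses the closed-form on-resonance bSSFP steady state
(TR 4.2 ms, flip 60°) with an optional phenomenological dephasing factor
for fast blood (off by default). Gaussian rather than Rician noise is used:
the metrics divide ROI means by a lung-air SD, and modelling the Rician
floor of magnitude images is out of scope, so phantom SNR values are
internally consistent but not directly comparable to scanner magnitudes.
What passing phantom tests show is that the metric estimators recover the
constructed contrast and noise; they do not certify anatomical realism,
reconstruction effects, or parallel-imaging noise amplification.

SNR_l/CNR_l use ROI means over label masks and the sample SD (ddof = 1,
the convention chosen here) of a lung ROI of at least 100 voxels; bright
mode takes blood as signal, black mode myocardium, and the two CNR signs
are exact negations on the same image.

## Numerical choices and degenerate inputs

- Configuration ladders track orders up to (echo count + 2); amplitude
  shifted beyond is dropped into a leaked-norm diagnostic that errors above
  1e-9 (the bound is never reached with the built-in timing).
- The isochromat oracle warns below 4 spins per tracked half-order
  (aliasing).
- T1 < T2 warns but does not fail (pathological test values allowed);
  dt = 0 relaxation and v = 0 flow are exact identities; zero-length trains
  predict empty sequences; matrix sizing ceils at every stage (vendor
  rounding unknown); nominal scan time assumes one shot per RR interval
  (1000 ms default) at 100% gating efficiency.
- Problem sizes in the test suite (short trains for property tests, 100
  oracle instances at ≤ 20 echoes, the 101-point sweep) were chosen as
  desk-scale statements of each property.

## Known limitations

Constant-velocity plug flow only; no off-resonance, B1 inhomogeneity,
diffusion, or slice-profile effects; no k-space acquisition/reconstruction
of the phantom (intensity lookup only); no navigator-efficiency or
arrhythmia modelling; the unprinted crusher moment discussed above is the
dominant uncertainty when comparing flow-suppression numbers to hardware.
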