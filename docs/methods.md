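# Methods

`mtswarm` is an in-silico reconstruction of an autonomous molecular
system: a DNA-based chemical controller that sequentially produces an
assembly signal (*linker*) and a disassembly signal (*dissociator*), a
population of DNA-functionalized microtubules gliding on surface kinesins
whose cross-linking those signals drive, and the two movie analyses —
pixel colocalization and windowed differential dynamic microscopy (DDM) —
that quantify the resulting transient swarming.  This note records the
models, the calibrated parameters, and the design decisions that were
genuinely open.

## 1. Controller kinetics

### Model

The controller is a three-step isothermal cascade of three DNA complexes
(Template, Converter, Transducer) and three enzymes (polymerase, nickase,
restriction enzyme).  Each multi-enzyme cycle is lumped into a single
mass-action pseudo-reaction; the network keeps the cascade's causal
structure with the fewest free parameters:

| step | reaction | rate law |
|------|----------|----------|
| R1 | Template → Template + signal | k_amp·pol·nick·[T] |
| R2 | signal + Converter → linker + waste | k_conv·[S][C] |
| R3 | signal + Transducer → updater + waste | k_trans·[S][Tr], k_trans < k_conv |
| R4 | updater + Template → Template·updater | k_upd·[U][T] |
| R5 | Template·updater → Template_cut | k_cut·restr·[TU] |
| R6 | Template_cut → Template_cut + dissociator | k_damp·pol·nick·[Tc] |
| R7a/R7b | linker + receptor-1/2 → complexes → full bridge | k_bridge, both orders |
| R8 | dissociator + (any linker-containing species) → waste (+ freed receptors) | k_rem |

k_trans < k_conv encodes the shorter signal-complementary region of the
Transducer (a slower toehold), which is what delays shutdown relative to
linker production; R5's restriction gate is what makes the disassembly
timing programmable.  Enzyme "activities" are dimensionless multipliers
standing in for enzyme concentrations in U/ml (no turnover numbers are
available); activity 0 exactly silences the gated reactions.  Thermal
dissociation versus polymerase displacement of the nicked strand is not
distinguished — both live inside lumped R1/R6.  Receptor bridging is
modeled well-mixed in solution; the spatial consequences of receptors
sitting on filaments are delegated to the swarm simulator.

Units are fixed package-wide: nM and minutes (frame intervals and
relaxation times are reported in seconds, lengths in μm).

### Calibration

No rate constants are published for this cascade; the defaults in
`src/mtswarm/data/controller_defaults.yaml` are a documented fit, chosen
once so that with all activities at 1 the free-linker pulse peaks near
15 min and decays below 5% of its peak by ~60 min, and with the
restriction enzyme disabled the pulse plateaus instead of decaying.  With
these defaults the pulse peaks at 15.3 min; halving restriction activity
moves it to 17.4 min, quartering to 19.8 min.  Initial conditions are
Template 10 nM, Converter and Transducer 100 nM, receptors 25 nM each;
receptors are kept below the Converter load so that, with the restriction
enzyme disabled, receptor binding cannot drain the free-linker plateau
below half its peak.

### Numerics and validation

The ODE system is integrated with a stiff-capable solver (LSODA,
rtol 1e-8, atol 1e-12 nM).  Two strand pools are conserved exactly by the
topology and checked to 0.1% on every trajectory: total Template material
(T + T·updater + T_cut) and total linker material (Converter-bound + free
+ receptor-complexed + waste).  An exact Gillespie sampler
(`mtswarm.stochastic`, numba-accelerated when available) provides an
independent stochastic cross-check: at a volume of 400 molecules/nM and
1000 runs the ODE means agree with the SSA means within 3 standard errors
at five checkpoints.  The volume is chosen so that the O(1/volume)
mean-field gap of the bimolecular steps sits below sampling error — at
much smaller volumes the comparison measures that gap, not implementation
correctness; a one-molecule discreteness floor (1/volume nM) is added for
species whose sampled variance is zero.

## 2. Swarm synthesis

### What the generator emulates

Rigid rods glide at constant speed on a periodic 2-D arena.  Lengths are
drawn from N(6.2, 2.2²) μm truncated at 0.5 μm (the measured GMPCPP
filament distribution); orientations diffuse slowly (0.02 rad²/min).
The default speed is 29.4 μm/min = 0.49 μm/s: the gliding velocity of the
emulated system is printed as 490 ± 20 with μm/s units, three orders of
magnitude above any kinesin-1 gliding assay, so it is read as a nm/s typo;
the value is configurable.

Cross-channel pairs closer than 0.5 μm (minimum segment–segment distance,
tip-agnostic) bind with probability 1 − exp(−k_on·[linker]·dt); bonds
break with probability 1 − exp(−k_off·[dissociator]·dt).  Bundles are
connected components of the bond graph: members co-translate with the
component's mean velocity (immobilized members contribute zero, anchoring
the bundle) and relax orientations toward the component's nematic mean at
2 /min.  Free filaments immobilize ("stick" to the surface) as a Poisson
process at 0.008 /min, emulating the slow growth of the immobile fraction
seen in long recordings; the stuck fraction follows 1 − exp(−rate·t)
when binding is off.  k_on = k_off = 0.004 /(nM·min) were chosen once so
the controller's default pulse drives the bound fraction up to ~75% around
30 min and back to zero by 55 min.

Rendering: each rod is rasterized as a ~2-px-wide uniform line by
bilinear (triangle-kernel) splatting, blurred with an isotropic Gaussian
PSF (σ 0.6 μm, periodic wrap), scaled to expected photon counts, then
Poisson shot noise plus rounded Gaussian read noise are applied and the
result is quantized to non-negative integers (16-bit camera model).
Bilinear splatting matters: nearest-pixel snapping adds independent
per-frame position jitter of variance pixel²/12, which measurably inflates
DDM relaxation rates; the triangle kernel preserves the exact sub-pixel
phase of every deposit.  Quantizing at render time makes the in-memory
stack equal its 16-bit TIFF round-trip, so analyses of the saved movie
byte-match analyses of the live run.

Defaults: 64×64 μm arena (128×128 px at 0.5 μm/px), 80 filaments per
channel, 180 frames at 20 s (a ~60-min movie — the frame interval and
pixel size are package choices; the source states neither).

One master seed expands into independent substreams (placement, motion,
binding, sticking, noise), so identical configs reproduce movies bitwise
and changing e.g. only the noise stream cannot perturb trajectories.

### What it does not emulate

No filament flexibility, steric or hydrodynamic interactions,
photobleaching, kinesin-density heterogeneity, 3-D effects, or filament
detachment/loss.  Bundles have no internal mechanics — co-translation
plus orientation relaxation is the simplest model that produces coherent
moving structures for the analyses to detect.  Passing tests therefore
show that the analysis chain correctly quantifies this class of dynamics,
not that the generator predicts real gliding-assay imagery.

## 3. Colocalization

Implemented exactly as defined: per frame and per channel the threshold is
the mean plus the population (divide-by-N) standard deviation of the pixel
brightness distribution; a pixel strictly above both thresholds is white
(W), above one is green (G) or magenta (M); the ratio is W/(M+G+W).
Conventions fixed for reproducibility: "exceeds" is strict (at-threshold
pixels are background), a constant channel is flagged degenerate, an
all-background frame yields NaN (undefined), never 0.  A fixed-threshold
mode exists for comparisons across images on a common intensity scale
(the linker-titration use case, whose thresholds are unspecified at the
source).  No background subtraction or flat-field correction is applied.
The ground-truth counterpart is the Jaccard overlap of the two channels'
unblurred occupancy masks.

## 4. DDM

The image structure function D(q, Δt) is the squared modulus of the 2-D
FFT of frame differences, averaged over all valid start times in the
window and radially averaged into q bins one Fourier-grid spacing wide
(full-plane spectrum, so conjugate modes are counted naturally; the
normalization |FFT|²/N_pix makes the count-weighted q-average of D equal
the spatial mean-square frame difference — a Parseval identity checked to
0.1% in the tests).

The ISF is F = 1 − (D − B)/A with F(q,0) ≡ 1.  B(q) is the median of D
over the top 10% of q (camera-noise plateau).  A(q) defaults to twice the
radially averaged static spectral power minus B, which is exact for
statistically stationary fields and, crucially, remains valid when F has
not decayed within a 25-frame window (the swarm-scale bins rarely
saturate); the large-lag-plateau estimator is available as an alternative
(`amplitude_mode="plateau"`, falling back to the static estimate where the
plateau is non-positive).  Bins with A ≤ 0 are flagged unusable and
propagate as missing values, never zeros.

Windowing: start indices 0…N−26, i.e. N−25 windows (180 frames → 155);
each window's elapsed time T is that of its 13th frame.  τ is extracted
from the first four ISF points (lag 0 included): an anchored
single-parameter exponential is least-squares fitted; τ is the time of
decay to 1/e — by log-linear interpolation between the bracketing
measured lags when the data cross 1/e inside the fitted range, by
extrapolation with the fitted exponential otherwise.  The hybrid rule is
deliberate: on ideal ballistic data (F = J₀(qvΔt)) the pure anchored-fit
τ is biased between −35% and +190% depending on sampling, while the
hybrid stays within ±9% of the true crossing for q·v·Δt ∈ [0.6, 1.0].
Non-decaying fits return inf; unusable bins NaN.  The q bin "nearest" a
requested wavelength minimizes |q − 2π/λ| with ties toward lower q.
Per-window τ values are block-averaged over every 16 consecutive windows
(trailing partial block kept, non-finite values excluded), per channel.

`relaxation_trace` shares one table of per-pair radial power profiles
across all windows (each consecutive window re-uses the same frame-pair
spectra), which makes the 155-window × 2-channel analysis a few seconds;
it is tested to agree exactly with the per-window `structure_function`
path.

### Benchmarks

Two synthetic fields with closed-form ISFs calibrate the chain end to end:

- **Ballistic**: non-interacting rods at one known speed v, zero
  rotational diffusion and sticking, lengths ≈0.5 μm so the
  orientation-dependent rod form factor is flat at the probed q (long
  rods weight the radial average toward q ⊥ v and destroy the J₀ form).
  q·v·τ must be constant over the mid-band — defined a priori as the bins
  whose expected 1/e crossing falls inside the fitted lags,
  q·v·Δt ∈ [0.58, 0.95] — and equal the root of J₀(x) = 1/e, which the
  tests recompute by root-finding (1.7520; it is not 1.4977, which is
  sometimes misquoted: J₀(1.4977) ≈ 0.51, not 1/e ≈ 0.368).
- **Brownian**: independent point emitters with known D₀; the
  through-origin regression of 1/τ on q² over the bins with
  D₀q²Δt ∈ [0.15, 1.0] recovers D₀ (within 10%; measured ≈0.4%).

## 5. Pipeline

`run_full` executes controller → movie → colocalization + DDM from one
config, writing CSV/TIFF artifacts plus a manifest containing the SHA-256
of the canonical config serialization (any numeric change, including a
default, changes the hash), the package version, the master seed, and
per-stage status; a stage failure records a failure marker and aborts
with the stage name.  `analyze_only` runs both analyses on an existing
calibrated TIFF.  The CLI subcommands (`simulate-controller`,
`generate-movie`, `coloc`, `ddm`, `run-full`, `analyze`) are thin
wrappers; logs are line-delimited JSON on stderr.

## 6. Problem sizes

Default study conditions: 180-frame, 128×128-px, two-channel movie
(~60 simulated minutes), 80 filaments per channel, 90-min controller
trajectory on a 0.1-min grid.  The benchmark movies are 45 frames
(ballistic, 300 rods total) and 60 frames (Brownian, 600 emitters total);
the stochastic cross-check uses 1000 Gillespie runs at 400 molecules/nM.
The full test suite runs in ~2 minutes on one CPU; the headline-number
script (`scripts/acceptance.py`) in ~2 minutes.

## 7. Known limitations

- The controller rate constants are a shape calibration, not inferred
  kinetics; only orderings, conservation laws, and response to enzyme
  scaling are meaningful, not absolute concentrations.
- Enzyme inactivation over long incubations is not modeled; the cascade
  runs indefinitely (the dissociator grows without bound after cutover).
- The swarm model's bundle mechanics are deliberately minimal; the
  measured colocalization peak (~20–30%) and its timing depend on the
  chosen binding/unbinding scales.
- DDM τ values depend on frame interval and pixel size, which are package
  choices; only scaling laws and trends are comparable across setups, not
  absolute τ.
- In the controller-driven movie the filament-scale (6.1 μm) relaxation
  time is dominated mid-movie by bundling, so its sticking-driven rise is
  cleanest in a binding-free movie with progressive sticking, which is
  how it is tested.
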