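# Methods

`discwave` simulates intercellular calcium spikes, waves and oscillations in
a gap-junction-coupled epithelial sheet — the ex-situ cultured *Drosophila*
wing imaginal disc — renders the dynamics as synthetic GCaMP5G time-lapse
movies, and quantifies those movies with the same operations a microscopist
would use (traces, kymographs, difference masks, wave detection, front-speed
and frequency estimation, inter-spike-interval statistics).

## Tissue model

A `TissueLattice` is a set of named regions (pouch, four hinge sectors,
peripodium) tiled by polygonal cells. Cells are generated by seeding
`round(region_area / mean_cell_area)` uniformly random points per region,
building their Voronoi diagram clipped to the region polygon, and applying
three rounds of centroidal (Lloyd) relaxation. The realized per-region mean
apical area therefore equals the requested one up to rounding, and the
realized area CV is ≈ 0.2, similar to real columnar epithelium. Adjacent
cells share polygon edges; the gap-junction weight of an edge is
`base_permeability × shared_edge_length × coupling_factor`. Edges crossing a
fold boundary (the dorsal and ventral pouch borders) carry factor 0; the
narrow anterior/posterior corridors carry a small residual conductance
(0.01 of normal) — see *Hinge rhythm* below.

The shipped wing-disc template is an elliptical pouch (65 × 55 μm
semi-axes, mean cell area 4.4 μm², ≈ 2,550 cells) inside an annular hinge
(outer semi-axes 92 × 80 μm) split into dorsal/ventral sectors and narrow
(36°) anterior/posterior corridor sectors, ≈ 3,200 cells in total. This is a
desk-scale model of the disc proper: it preserves the measured pouch cell
area, the fold topology and the region layout at roughly half the linear
size of a late third-instar disc, so that an hour of tissue dynamics
simulates in well under a minute. Hinge cell area is not reported for this
tissue; the template assumes 18 μm², between the measured pouch (4.4 μm²)
and peripodial (113.5 μm²) values. The peripodium is a separate
single-region elliptical lattice of large squamous cells (≈ 200 cells) with
no coupling to the columnar layer, since peripodial waves run independently.
The notum is omitted from the shipped template (its dynamics are not among
the quantified observations); custom regions can be supplied as polygons.

## Calcium dynamics

Each cell carries cytosolic calcium `c`, ER calcium `s`, IP3 `p` and the
slow IP3R inactivation gate `h` (all μM, s):

    open  = (p/(p+d1))³ (c/(c+d5))³ h³
    dc/dt = (v_ip3r·open + v_leak)(s−c) − v_serca c²/(k_serca²+c²)
            + v_soce k_soce²/(k_soce²+s²)·ca_ext − v_pm_out·c
            + spike_input + D_c Σ_j w_ij (c_j−c_i)/A_i
    ds/dt = −(1/β)[(v_ip3r·open + v_leak)(s−c) − v_serca c²/(k_serca²+c²)]
    dp/dt = v_plc·dose − k_deg p + D_p Σ_j w_ij (p_j−p_i)/A_i
    dh/dt = (d2/(d2+c) − h)/τ_h

This is a minimal two-gate IP3R formulation: IP3 and calcium open the
channel, calcium slowly inactivates `h` (the refractory mechanism), SERCA
refills the store, store depletion gates SOCE influx, and the plasma
membrane extrudes calcium. Both calcium and IP3 pass through gap junctions
(either can be silenced via `d_c` / `d_p` for in-silico dissection);
junctional fluxes are antisymmetric per edge, so coupling conserves total
calcium exactly. RyR and TRP currents are omitted (essentially not
expressed in this tissue).

### Dynamical regime and calibration

The defaults (`ModelParams()`) are the `pouch-18C` calibration:

| parameter | value | role |
|---|---|---|
| v_ip3r, v_leak | 6 s⁻¹, 0.002 s⁻¹ | IP3R flux, passive leak |
| v_serca, k_serca | 1.5 μM/s, 0.15 μM | store refill |
| d1, d5, d2 | 0.1, 0.3, 0.8 μM | gating constants |
| τ_h | 150 s | refractory recovery |
| v_plc, k_deg | 0.026 μM/s, 1/30 s⁻¹ | ligand-driven IP3 turnover |
| v_soce, k_soce, v_pm_out | 0.02 μM/s, 4 μM, 0.03 s⁻¹ | membrane balance |
| D_c, D_p | 3.0, 0.5 μm·s⁻¹ per unit weight | junctional transfer |
| β | 0.185 | ER/cytosol volume ratio |
| hetero_cv | 0.08 | per-cell CV on v_plc and τ_h |

All rate constants are calibration constants, tuned so that the full
pipeline reproduces the printed observations; none are measured values. At
rest (dose 0) the cell sits at c ≈ 0.025 μM with a full store (s ≈ 17 μM).
A saturating dose (`dose = 1`, the 5% fly-extract condition) puts the
median cell just above a SNIC-like oscillation threshold: it is a
relaxation oscillator with period ≈ 11.5 min whose cycle is paced by slow
store reloading through SOCE after each spike loses calcium to extrusion.
Because the threshold is of SNIC type, the period is steeply
dose-dependent near onset: log-normal heterogeneity (CV 0.08) on v_plc and
τ_h makes the most strongly driven cells substantially faster, and in the
coupled sheet these act as pacemakers whose rhythm the tissue adopts.
Waves nucleate at recurring pacemaker sites, travel as regenerative
(non-decrementing) fire–diffuse–fire fronts, and annihilate in the
refractory wake.

Ligand dose is expressed as receptor occupancy relative to the 5%-extract
reference. Because occupancy saturates, 1% extract maps to a drive of
≈ 0.3, below both the oscillation and the wave-propagation thresholds:
cytosolic calcium settles ≈ 1.4× above baseline without waves. This
under-represents the observed GCaMP rise at 1% extract — with the fixed
rate forms above, sub-threshold IP3 cannot raise steady-state calcium much
further without intermittently crossing the wave threshold — a known
limitation.

The `pouch-25C` preset models the metabolic state of larvae reared at
25 °C as a single gain applied to the ATP-dependent machinery: IP3
production (v_plc ×1.29), store-operated entry (v_soce ×1.18) and
junctional transfer (D_c ×1.25; innexin channel function is
ATP/phosphorylation-sensitive). This raises the pouch rhythm from ≈ 5/h to
≈ 9/h and the front speed from ≈ 16.4 to ≈ 17 μm/s, matching the observed
ordering (15.4 → 18 μm/s; the original study found the speed difference
insignificant).

### Hinge rhythm

The dorsal/ventral hinge oscillates at a lower frequency than the pouch
(3.3 vs 5.1 events/h at 18 °C rearing). In the model this is produced by
giving hinge cells a reduced ligand drive (×0.75) and slower IP3R recovery
(τ_h ×2), and by making the anterior/posterior corridors weakly conducting
(1% of normal): the hinge annulus then runs its own slower near-threshold
rhythm, weakly phase-pulled by pouch waves. At full corridor conductance
the pouch entrains the hinge 1:1 — a driven excitable medium this strongly
coupled cannot skip beats — so in this model most hinge events initiate
within the hinge rather than spreading in from the pouch, unlike the
interpretation in the original study. Hinge frequency is measured on the
dorsal + ventral sector mask, the positions where the original kymographs
read the hinge. Fold confinement itself (waves unable to traverse the
dorsal/ventral pouch border) is reproduced exactly, since fold edges carry
zero conductance.

### Pharmacology

Conditions act as parameter switches at scheduled times: 2-APB zeroes
v_ip3r and v_soce (stochastic spikes are unaffected), Thapsigargin zeroes
v_serca irreversibly (cytosolic calcium then rises to a sustained plateau
as the store drains and SOCE stays maximal), BAPTA sets external calcium
availability to zero (calcium then decays to baseline), Carbenoxolone
zeroes every junctional weight. After Carbenoxolone the cells' intrinsic
near-threshold periods disperse strongly (the SNIC amplifies the
heterogeneity), so coordinated events cease immediately; residual
asynchronous firing is spatially incoherent and is not classified as a
wave.

Stochastic spikes model the locally confined, IP3R-independent events seen
in plain culture medium: per-cell Poisson events (rate λ, default 0;
8×10⁻⁴ cell⁻¹s⁻¹ in the `schneider` preset) inject 1.5 μM/s of calcium
for 2 s. They persist under 2-APB and do not recruit waves at dose 0
because without IP3 the regenerative loop is closed.

## Numerics

Fixed-step Heun (RK2) integration at dt = 0.02 s, compiled with numba; the
readable numpy `derivatives` is the reference implementation and the test
suite checks one compiled step against an independently coded half-step
integrator (≤ 10⁻⁶ relative on a 10-cell lattice). States are kept
non-negative by step rejection (a failing step is retaken with 8
substeps); divergence aborts with a diagnostic naming the step size. One
`SeedSequence` per run derives independent generators for heterogeneity
and spike times, so trajectories are bit-reproducible given (inputs,
seed). Closed-system total calcium Σ A_i (c_i + β s_i) is conserved to
machine precision per step because the junctional stage sums cancel
pairwise.

## Imaging

GCaMP5G fluorescence is a Hill transform `F = f0 + (fmax−f0) cⁿ/(cⁿ+Kdⁿ)`
with Kd = 0.46 μM (the sensor's measured dissociation constant) and
n = 2.7 (literature value for GCaMP5G, configurable). Rendering assigns
each pixel the fluorescence of the cell containing its center (default
1 μm/px) plus seeded Gaussian noise (σ = 2 intensity units); intensities
use the 0–255 display scale of the recordings. Movies are multi-page TIFF
with a JSON sidecar for pixel size and frame interval; 8-bit content
round-trips losslessly. Photobleaching and PSF blur are not modeled;
intensity units are arbitrary, so analyses only use ratios, ranks and
thresholds.

## Quantification

Wave detection thresholds the smoothed ΔF/F0 stack (σ = 1 px, 0.5 s;
per-pixel F0 = 10th percentile over time) at 0.3; an event is a contiguous
episode in which ≥ 10% of the analysis region is activated (separated by
≥ 4 s of quiescence). Events are classified: *wave* (activation grows
contiguously from a compact origin), *flash* (many comparable clusters
ignite in the first active frame, or over half the region at once — the
synchronized response to a ligand step), *scattered* (the largest
space-time-connected component covers < 50% of the footprint —
desynchronized cell-autonomous firing), or *spike* (locally confined,
< 10% of the region). Only waves count toward oscillation frequency; an
event enters a region when its footprint covers ≥ 10% of that region's
pixels. These thresholds are this package's substitutes for the original
study's unavailable quantification procedures and are validated by exact
recovery on analytic phantoms (translating and radially expanding fronts)
rather than by matching the original implementation.

Front speed is the least-squares slope of the half-max front position
along a radial line through the event origin, using the expansion phase
only, requiring ≥ 4 tracked frames, and recording the peak intensity
within 10 μm behind the front per frame (the amplitude-decrement check).
Pipeline speed summaries use the median over events, robust to occasional
merged or re-nucleating fronts whose single-event fits overshoot; all
per-event values are reported. Origins are mapped and clustered within
25 μm. ISI statistics detect spikes per grid point as upward crossings of
baseline + 0.5×(max − baseline) with a 30 s lockout, and regress interval
SD on interval mean across points (ordinary least squares with the
regression F-test); uncoupled stochastic spiking gives slope ≈ 1, strongly
coupled tissue gives no significant relation. Difference masks follow the
FIJI convention exactly: `255 − max(I(t) − I(t−lag), 0)` in integer
arithmetic, inverted display, 2.5 min default lag; domain counts are
8-connected components below 255 − threshold with small components
removed.

## What the synthetic data do and do not show

The generator emulates: patterned polygonal tissue with measured pouch and
peripodial cell areas, fold-confined ligand-driven oscillatory waves at
the reported frequencies and speeds, cell-size-dependent conduction
velocity, locally confined stochastic spikes, the onset sequence after a
ligand step (uniform rise → fluctuating domains → few coordinated waves),
and the four pharmacological abolition phenotypes. It does not emulate:
optical blur and bleaching, irregular disc outlines, growth, the z
dimension, trailing-edge fluctuation statistics (reported but not
asserted, as no quantitative target exists), paracrine signaling or
mechanotransduction. Passing tests therefore show that the quantification
pipeline recovers known ground truth from movies with realistic geometry,
kinetics and noise — not that it is robust to every artifact of real
microscopy.

## Problem sizes

Tissue runs use the ≈ 3,200-cell template for 60 min of model time at
dt = 0.02 s, recorded at 0.5–1 s and rendered at 1 μm/px; pharmacology and
property experiments use a ≈ 480-cell pouch for 30–50 min. Stochastic
recovery quantities are pooled over three seeds with per-seed values
reported.
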