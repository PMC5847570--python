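# Methods

This package re-implements, as a tested pipeline, the integrative
analysis by which a trimeric enzyme (human dUTPase, hDUT) was shown to
bind a proteinaceous inhibitor (the staphylococcal repressor Stl) as
*separated monomers*, forming 3:3 and 3:2 trimer:monomer complexes.
Four experiment types feed the conclusion: solution small-angle X-ray
scattering (batch and SEC-SAXS), hydrogen–deuterium exchange mass
spectrometry (HDX-MS), isothermal titration calorimetry (ITC), and
steady-state inhibition kinetics.  Every stage is driven from synthetic
data with known ground truth, so the pipeline is testable without
external downloads.

## SAXS primary analysis (`dutstl.saxs`)

**Guinier analysis.** At low angles I(s) = I(0)·exp(−(s·Rg)²/3) for
s·Rg ≲ 1.3.  We fit ln I against s² by weighted least squares
(weights (I/σ)², the delta-method variance of ln I).  When no window is
given, the upper bound is iterated until s_max·Rg converges onto 1.3,
and leading points are dropped only when they show a same-sign residual
run longer than 4 *and* the run's mean deviation exceeds the noise
level — the magnitude condition keeps the window anchored at the lowest
angles for clean data while still skipping aggregation upturns.  On an
ideal solid sphere the s·Rg ≤ 1.3 convention itself biases Rg upward by
≈1.9%; tests therefore allow 2%.

**P(r) inversion.** The pair-distance distribution solves the
Tikhonov-regularized least squares ‖(I − T·p)/σ‖² + α‖D₂p‖² with
T_ij = 4πΔr·sinc(s_i r_j), endpoint constraints p(0) = p(Dmax) = 0
imposed by eliminating the endpoints, and D₂ the second-difference
operator with zero boundaries.  α is chosen as the largest value whose
residual is within 5% of the best achievable one over a 12-decade scan
— the corner of the L-curve located through the discrepancy rather than
through its (numerically fragile) curvature.  Rg and I(0) in real space
come from the moments of p(r): Rg² = ∫r²p dr / (2∫p dr),
I(0) = 4π∫p dr.

**Porod volume.** V_p = 2π²I(0)/Q with Q = ∫s²(I−K) ds.  The constant
background K is the slope of s⁴I against s⁴ over the highest-angle
quartile (the value that flattens s⁴(I−K)); below the first measured
point the integrand is filled with the Guinier extrapolation.  The
integral is truncated at the measured s_max, which overestimates V_p of
compact bodies by a few percent (≈6% for a sphere measured to
s_max·R = 15); the sphere test allows 10%.

**Mass estimators.** MM from forward scattering uses a reference
solution: MM = MM_ref·(I0/c)/(I0_ref/c_ref).  Volume rules: MM = V_p/1.6
by default and MM = V_ex/2 for excluded volumes.  The alternative
convention MM = 0.588·V_p is available by argument; the two published
variants differ by ~6% and the divisor form is what the benchmark
tables print.

**Debye model intensities.** Residue-level bead models are scored by
the Debye formula I(s) = f(s)²[N + 2Σ sinc(s·r_ij)] with a single
Gaussian bead form factor f(s) = exp(−s²σ_b²/2), σ_b = 3 Å by default.
Pair distances are histogram-binned at 0.5 Å with *per-bin mean
distances*, which makes few-body cases exact and keeps the binning
error on 500-bead models below 0.5% out to s = 0.5 Å⁻¹.  This
residue-level scorer replaces an all-atom spherical-harmonics treatment
(no hydration shell); it is adequate for the shape-fitting range
s ≲ 0.25 Å⁻¹ where the complex models are scored.

**Model-data discrepancy.** χ² = (1/(N−1))·Σ[(I_exp − c·I_calc)/σ]²
with the analytically optimal scale c = Σ(I_exp·I_calc/σ²)/Σ(I_calc²/σ²);
it is exactly invariant under rescaling either curve.

**SEC-SAXS pooling.** The buffer average is subtracted from every
frame; frames whose integrated signal exceeds 3× the buffer noise form
the elution peak.  Walking through the peak, a frame joins the current
region while its scale-free reduced χ² against the region's first frame
— computed with *both* frames' σ columns propagated — stays below 1.5;
pools shorter than 3 frames (mixture/transition frames between
co-eluting species) are dropped, and each region is averaged with
inverse-variance weights.  The χ² criterion replaces a rank-based
correlation-map statistic with the same intent; the threshold is
configurable.

## HDX-MS interface mapping (`dutstl.hdx`)

Differences are bound − free centroid mass shifts per peptide and
labelling time, averaged over (by design three) replicates.  The 95%
confidence band is z₀.₉₇₅ times the pooled standard error
√(SD_f²/n_f + SD_b²/n_b), averaged in quadrature over peptides; the
band for the time-accumulated difference adds the per-time half-widths
in quadrature.  Projection to residues spreads each peptide's
accumulated Δmass uniformly over its span *minus the first two
residues* (fast back-exchangers), then averages over covering peptides.
Residues beyond the band are called protected/deprotected; maximal
same-direction runs, bridged across gaps of ≤2 residues or missing
coverage, become interface segments.  Small global shifts below the
band never enter a segment.

Per-peptide (not per-residue) resolution limits boundary sharpness:
a peptide that overlaps an interface edge by a single residue carries
its full Δmass across its whole footprint, so recovered segment
boundaries can exceed the true interface by up to roughly one peptide
length.  Tests assert full coverage of the seeded interface and bound
the excess by the peptide length; sub-peptide boundary accuracy is not
achievable under uniform spreading and is not claimed.

Solvent accessibility uses Shrake–Rupley sampling (960 sphere points by
default, biotite's implementation) on one-bead-per-residue models with
a 3.4 Å effective residue radius and a 1.4 Å probe; interface residues
with ≤10 Ų accessible area are removed from the restraint-eligible
set (buried residues cannot form the binding surface), while the
reported segments stay unchanged.

## Hybrid rigid-body modelling (`dutstl.modeling`)

A fixed trimer core (3-fold axis aligned on z via the chain-centroid
plane normal) and k rigid monomer copies are sampled by Metropolis
simulated annealing.  The energy is

    E = χ²(Debye(model), target) + w_r·E_restraint + w_c·E_clash

with w_r = w_c = 10.  Restraints are ambiguous flat-bottom terms: one
per monomer copy, satisfied when *any* surface-eligible residue pair
between the (SASA-filtered) trimer segments and the monomer segment is
within 10 Å, with quadratic growth beyond; the interface is projected
equally across all subunits.  Clashes cost (3.5 − d)² per cross-unit
bead pair closer than 3.5 Å; intra-unit geometry is frozen.

Moves mix small pose perturbations (rotations σ = 10°, translations
σ = 3 Å, both shrinking with √(T/T₀) as the system cools), occasional
large jumps (re-drawing the pose on a shell just outside the core, or
re-drawing the orientation about the copy's own centroid) that let the
chain escape the deep local minima of low-noise χ² landscapes, and
crankshaft/tail-pivot moves on dummy-residue linkers.  Under P3 (P2)
symmetry a single pose is sampled and replicated by 120° (180°)
rotations about z.  Cooling is geometric; with `t0=None` the start
temperature scales to a tenth of the initial energy and γ is set so the
end temperature is 0.05, after which a 2000-step greedy quench with
small mixed-scale moves polishes the best state.  Annealing is
bit-reproducible for a fixed seed, and the best-energy trace is
non-increasing by construction.

The 3:2 complex is derived from the refined 3:3 model by deleting one
copy with the remaining poses frozen (strict "interface fixed"
reading); only dummy termini/linkers are re-annealed against the
region-2 curve, and the result is recorded as P1 with a
P2-compatibility flag.

Missing termini and inter-domain linkers are self-avoiding chains of
dummy beads at 3.8 Å virtual-bond spacing (3.0 Å exclusion), grown by
discard-and-retry; two-anchor gaps bias the growth direction toward the
far anchor as the leash tightens and must close within 0.5 Å of a bond
length.

Solutions are clustered by the distances of the monomer N- and
C-domain centroids to the nearest interface-patch centroid (proxy for
the substrate pocket), single linkage, 10 Å cut, ranked by best-member
χ².  Ensemble flexibility of the free two-domain monomer dimer follows
the ensemble-optimization idea: a pool of conformers with re-grown
flexible N-domains, a genetic algorithm (population 40, 60 generations,
swap mutation + uniform crossover) selecting the 20-member sub-ensemble
whose average curve best fits the data.  Flexibility is summarized as
R_flex, here the Shannon entropy of the Rg histogram normalized by the
uniform-histogram entropy (an entropy surrogate for the published
metric, which is not specified in closed form): 100% = maximally broad,
0% = rigid.

## Binding thermodynamics (`dutstl.thermo`)

**ITC.** The forward model tracks per-injection cell composition with
displacement (M_i = M_{i−1}(1 − v/V₀); X likewise plus the injected
titrant) and computes each injection's heat as V₀·ΔH times the newly
formed complex, with the bound concentration from the one-site
quadratic.  Fitting subtracts the apparent dilution heat (mean of the
last three injections) and then treats any residual constant offset as
a nuisance parameter, so the end-of-titration estimate cannot bias N,
Kd or ΔH; parameters are bounded (N ∈ [10⁻³, 100], Kd ∈ [10⁻¹³, 10⁻²] M)
and multi-started over four decades of Kd.  ΔG = RT·ln Kd and
−TΔS = ΔG − ΔH are derived at the stated temperature and the identity
is verified on every returned fit.  A c-value (N·[cell]/Kd) outside
[1, 5000] flags low confidence.  In the benchmark orientation the cell
holds the inhibitor and the syringe the enzyme, so N counts enzyme
protomers per inhibitor protomer and 3/N is the inhibitor load per
enzyme trimer.

**Inhibition.** Initial velocities are the regression slope over the
first 10% of the progress-curve amplitude (window widened to 4 points
when needed).  Fractional activities follow the Morrison tight-binding
form v/v₀ = 1 − A·([E]+[I]+K_i − √(([E]+[I]+K_i)² − 4[E][I]))/(2[E])
with the enzyme protomer concentration fixed and the maximal-inhibition
amplitude A free (the benchmark system saturates at ~70%, not 100%);
A is bounded to [0, 1] and a pinned fit is flagged.  The model reduces
to the classical hyperbola 1 − A·[I]/([I]+K_i) for E ≪ K_i.

**Native MS.** Neutral mass per peak is z·(m/z) − z·m_H with the proton
mass (no adduct handling); mean ± SD over the assigned charge states.

## Synthetic data (`dutstl.synth`)

The generator mirrors the real system.  Globular domains are random
sphere packings at one bead per 120 ų with ≥3.4 Å separation; default
sizes copy the real proteins (trimer 3×152 residues, monomer 84+183
residues) so the published segment numbers (34–50, 89–110, 98–113) can
be reused as fixture coordinates.  Interface patches are assigned to
surface beads facing the binding partner (bead positions inside a blob
are random, so the numbering is free), and the monomer is slid radially
until the patches are in contact (≤10 Å, clash-free); the trimer axis
is on z and the two remaining copies are 3-fold images.  SAXS noise is
counting-statistics-like, σ(s) = a·√I + b, with the σ column filled
truthfully — χ² of the truth against its own simulation averages 1.0.
SEC-SAXS series superimpose Gaussian elution profiles of the 3:3
(leading, smaller amplitude) and 3:2 (main) species on a flat buffer.
HDX uses the two-state uptake model u = 1 − exp(−k_int·t/P) with
sequence-independent log-normal intrinsic rates (median 1 min⁻¹),
protection factor 50 on interface residues in the bound state,
triplicates at 1/10/100 min, peptides of length 10 tiled at step 5
(≥90% coverage, 2-fold redundancy), and 0.05 Da centroid noise.  ITC
and inhibition generators share the exact forward models of the fitting
code, with the published designs as defaults (0.5 µL + 19×2 µL
injections; inhibitor series 0–500 nM around 50 nM enzyme).

What the generators do *not* emulate: sequence-resolved exchange rates,
back-exchange, EX1 kinetics, chromatographic dispersion, detector
geometry, hydration-shell scattering contrast, and inter-domain linker
dynamics within a bound monomer.  Passing tests therefore demonstrate
correctness of the estimators and the search, not instrument realism.

## Problem sizes and numerical choices

Annealing-based tests run on a reduced complex (3×36-bead trimer,
52-bead monomers, 12 000 + 2 000 steps) where one seed takes ~30 s;
the analysis driver uses 3×48/64 beads.  The full-size generator
defaults are exercised by the construction and determinism tests.  The
HDX null calibration uses 200 seeded repeats on a 150-residue protein;
the ITC noise study 100 seeds.  Degenerate inputs are rejected
explicitly (non-monotone s grids, zero heats, empty models, overlapping
beads, unbridgeable gaps, out-of-range symmetry/copy combinations), and
ties in the Guinier auto-window resolve toward the lowest usable angle.

## Known limitations

Residue-level Debye scattering has no hydration shell, so absolute-
scale I(0) comparisons require an external reference.  The Porod
background fit assumes the measured range reaches the s⁻⁴ regime.
Segment boundaries in HDX maps carry peptide-footprint uncertainty (see
above).  The annealing search is stochastic: the acceptance-style test
requires 3 of 5 seeds to recover the pose, not every seed.  R_flex is
an entropy surrogate, comparable within this package but not numerically
identical to the metric printed by the original ensemble-optimization
software.
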