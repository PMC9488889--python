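# Methods

## Single-cycle SPR kinetics (`compskit.spr`)

**Model.** The 1:1 Langmuir interaction `dR/dt = k_a·C·(R_max − R) − k_d·R`
is solved analytically per constant-concentration phase:
`R(t) = R_eq + (R₀ − R_eq)·exp(−(k_a·C + k_d)·t)` with
`R_eq = k_a·C·R_max/(k_a·C + k_d)`. A single cycle concatenates contact and
dissociation phases, each starting from the end response of the previous
phase, which is exactly the single-cycle protocol (increasing analyte
concentrations injected without regeneration). `K_D = k_d/k_a`.

**Defaults.** Five injections at 0.5, 2.5, 10, 20, 40 nM (the published
protocol states only the 0.5–40 nM window; this series spans it with roughly
log spacing), 120 s contacts, 60 s inter-injection dissociations, 6000 s
final dissociation (the lower bound of the instrument protocol's
6000–14400 s window, chosen to bound runtime). Sampling interval: 1 s for
production use; tests and generators use 5 s, which leaves ~1400 points per
cycle and does not change noiseless recovery.

**Fitting.** Global nonlinear least squares (lmfit/`leastsq`) over
(k_a, k_d, R_max), shared across all segments, parameterized on log10 scale
because the rates span decades. Auto-initialisation: k_d from a log-linear
regression of the final dissociation tail, R_max = 1.2× the peak response,
k_a back-solved from the end response of the highest-concentration contact.
Standard errors are delta-method transforms of the log-scale errors.
Mass-transport limitation, baseline drift and bulk refractive-index jumps
are *not* modeled — input is assumed reference/blank-subtracted, as in the
instrument workflow.

**No-binding guard.** A fit is refused when the dynamic range of a smoothed
copy of the trace (moving average, window = max(5, n/100) samples) is below
3× a robust noise estimate (median absolute deviation of first differences
÷ √2). Smoothing matters: the raw range of a long pure-noise record grows
with record length and would otherwise always clear the threshold.

**Replicate summaries.** Per-parameter mean ± sample sd (ddof = 1), in the
conventional table units (K_D nM, k_a 10⁶ M⁻¹s⁻¹, k_d 10⁻³ s⁻¹). Identical
replicates snap to sd = 0 exactly. Both the mean of per-replicate k_d/k_a
ratios and the ratio of the rate means are reported, because published
summary tables are not always internally consistent between the two
conventions (e.g. rate means of 1.0·10⁶ and 0.7·10⁻³ imply 0.7 nM against a
printed 0.8 ± 0.2 nM). Fold changes use half-up rounding, matching how
"~n-fold" statements are printed.

## Calorimetric isotherms (`compskit.itc`)

**Model.** Single-site Wiseman isotherm with stoichiometry `N` expressed as
sites per titrate (cell) molecule:
`Q = (N·Mt·ΔH·V₀/2)·[x − √(x² − 4At/(N·Mt))]`, `x = 1 + At/(N·Mt) + K_D/(N·Mt)`,
the closed-form root of the mass-action quadratic (verified in tests against
a brute-force root finder). The discriminant is clamped at zero with a
warning for numerically extreme inputs, which corresponds to the
stoichiometric-limit heat.

**Dilution.** Perfusion (overfill) convention: after cumulative injected
volume V, `Mt = Mt₀·exp(−V/V₀)` and `At = A₀·(1 − exp(−V/V₀))`. The observed
per-injection heat corrects for the heat content displaced during the
injection: `δq_i = Q_i − Q_{i−1} + (dV/V₀)(Q_i + Q_{i−1})/2`; summing these
telescopes to the final-composition heat plus the displaced-heat ledger,
which is the conservation identity the tests assert to 10⁻⁸ relative.

**Bivalency.** A titrant carrying two equivalent binding entities at molar
concentration A is algebraically identical to a single-site system with
(N/2, K_D/2, 2ΔH) in molar-titrant units — `q(2A, M, K) = 2·q(A, M/2, K/2)`
for the bound-complex root `q` — so fitting with free N recovers N = 0.5
*exactly* in the noiseless limit, and the fitted K_D/ΔH are the per-molecule
effective values.

**Defaults.** Cell volume 200 µl (instrument-typical; not part of the
published protocol), 5 µM titrate, 2 µl injections, 19 injections, 25 °C.
Heats of dilution enter as a constant offset nuisance parameter (fitted,
default on). First-injection discard is available but off by default. The
Wiseman c-value (`N·Mt/K_D`) is reported and the fit flagged ill-conditioned
outside [1, 1000].

## Interaction fingerprints (`compskit.fingerprint`)

**Criteria (defaults).** H-bond: donor/acceptor heavy atoms ≤ 3.5 Å and,
when explicit hydrogens exist, D–H···A angle ≥ 120°; hydrophobic contact:
two apolar heavy atoms ≤ 4.5 Å; apolar = carbon or sulfur not covalently
bonded to N or O, with bonds inferred from covalent radii (+0.45 Å
tolerance). Pairs within the same residue or separated by ≤ 2 covalent bonds
are excluded, which removes peptide-bond artefacts such as N(i+1)···O(i).
These are community-standard fingerprint values; the script used for the
original published contact tables is unpublished, so the defaults are
calibrated, not reproduced.

**Chemistry.** Donor/acceptor assignment for hydrogen-free crystal
structures uses a fixed residue-template table covering the 20 standard
amino acids, water, and the nonstandard compstatin residues: D-Tyr (DTY,
phenolic OH as in Tyr), sarcosine (SAR) and N-methyl-Ile (IML) with
methylated backbone nitrogens that cannot donate, and 1-methyl-Trp (under
the codes MTR/1MW/4IN) whose indole nitrogen is methylated. Unknown residues
fall back to "N and O are both donor and acceptor", the safe assumption
when chemistry is unknown. Hydroxyl–hydroxyl (and similar symmetric) pairs
are reported once, with the lower-index atom as donor.

**Aggregation.** Multi-model files stand in for trajectory frames: counts
are frame means, occupancy is exactly (frames with ≥ 1 intermolecular
contact)/(total frames). Bridging waters are waters with H-bond-geometry
legs to ≥ 1 ligand polar atom *and* ≥ 1 target polar atom; water-mediated
contacts do not count toward a residue's direct intermolecular tally (a
residue engaged only through a bridge is still "contactless"), matching how
direct engagement is described for the co-crystal structure.

## Convertase assay model (`compskit.convertase`)

Surface species (RU-equivalents of C3b sites): free C3b, C3bB, C3bBb,
C3:C3bBb, C3:C3b and the covalently deposited pool. Solution compositions
(FB, FD, C3, inhibitor) are constant within a timeline segment; FD acts
catalytically (not consumed, not surface-bound) by enabling C3bB → C3bBb
conversion. Deposition (`C3:C3bBb → C3bBb + C3b_dep`) is irreversible and
adds to a separate non-decreasing pool, so the non-deposited site total is
conserved exactly. Total response is the mass-weighted sum of species
densities (masses 175/93/60/185 kDa for C3b/FB/Bb/C3).

**Inhibitor.** Rapid pre-equilibrium occupancy θ = I/(I + K_D) of the shared
C3/C3b interface site; both C3 association terms (to C3bBb and to free C3b)
are scaled by (1 − θ)² because the interface must be free on the substrate
and the surface side. Assembly and decay terms are untouched — the model
asserts, by construction, that the inhibitor blocks substrate binding but
not convertase formation or stability. The catalytically dead FB mutant mode
(`active=False`) zeroes only the deposition step: the stabilized convertase
still assembles and binds C3 reversibly, which is the behaviour the
inactive-enzyme control shows experimentally.

**Defaults are illustrative.** No rate constants for these steps are
published; the default set reproduces the qualitative phenomenology:
convertase half-life ≈ 2.3 min (k_decay = 0.005 s⁻¹), C3→C3bBb K_D = 50 nM
versus C3→C3b K_D = 5 µM (preference ratio 100 in the low-concentration
limit), inhibitor K_D = 0.5 nM. Integration: LSODA per segment,
rtol 10⁻⁸/atol 10⁻¹⁰; tightening tolerances tenfold changes traces by
< 10⁻⁴ RU. `deposition_delta` is the experimental observable (baseline after
the final dissociation minus baseline before the C3 injection);
`deposited_delta` is the model-level truth (change in the deposited pool).
With a saturating but finite inhibitor concentration a residual deposition
of order 10⁻³ RU leaks through the (1−θ)² factor; "abrogated" is asserted
at 0.01 RU against signals of hundreds of RU.

## Species mapping (`compskit.species`)

Global alignment is an in-package Gotoh dynamic program with EMBOSS-style
affine penalties (a gap of length L costs open + L·extend; defaults
BLOSUM62, open 10, extend 0.5, end gaps penalized) and a documented,
deterministic traceback tie-break: diagonal, then gap-in-second-sequence,
then gap-in-first. Optimality is cross-checked in tests against an
independent affine-gap implementation. Conservation classes use the Clustal
strong/weak residue groups; identity is computed over alignment length.
Contact positions are mapped through the alignment in reference numbering
with a configurable offset between author and sequence numbering
(out-of-range positions are reported, not dropped).

Percent inhibition: `100·(1 − (S − B)/(S₀ − B))` with background B and
no-inhibitor reference S₀, clamped to [0, 100] — signals above the reference
are defined as zero inhibition, signals below background as complete
inhibition. The degenerate case S₀ ≤ B is rejected.

## Synthetic data (`compskit.synthetic`)

Generators are deterministic functions of (config, seed): re-running yields
byte-identical files, and ground truth is written alongside the data.
Noise models: i.i.d. Gaussian for sensorgrams (default 0.5 RU, the scale
suggested by replicate scatter in the published SAR table) and ITC heats;
optional multiplicative lognormal for ELISA signals.

The toy-complex generator plants each interaction in an isolated slot
(25 Å spacing) using real residue geometries (Ser–OG donor to Asn–OD1
acceptor at 2.9 Å; Ala CB–CB pair at 3.8 Å; a water equidistant at 2.8 Å
from ligand and target polar atoms whose direct separation exceeds the
H-bond cutoff plus guard margin). Specs that cannot be realized within the
detection criteria and a 0.75 Å guard margin are rejected. Frames in which
a plant is "absent" displace the target-side group by 6 Å.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: instrument drift, bulk refractive-index jumps and
mass-transport limitation in SPR; baseline/power-trace processing and
titrant impurities in ITC; crystallographic disorder, alternate locations
and occupancies below 1 in structures; plasma matrix effects in ELISA.
Closed-loop recovery on synthetic data validates the estimators under the
stated noise model, not the instrument corrections upstream of them.

## Known limitations

- The fingerprint calibration against the deposited co-crystal structure
  (RCSB 7BAG) needs those coordinates; everything else runs from synthetic
  data. Energy decomposition (MM/GBSA-style per-residue energies) is out of
  scope — fingerprints are geometric counts.
- The convertase model is mechanism-faithful but quantitatively
  illustrative; it is not intended to be fitted to real sensorgrams.
- Cross-species contact mapping needs the real ortholog sequences (e.g.
  UniProt entries for human and mouse C3); the package ships the machinery
  and toy-sequence tests only.
- The SPR module fits the 1:1 model only; two-state, bivalent-analyte and
  mass-transport models are out of scope.
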