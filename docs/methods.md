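# Methods

## The molecular model

UQ-n and MK-n topologies are generated from internal coordinates
(Z-matrix-style placement). Geometry is idealized: regular six-membered
rings with 1.40 Å sides, Csp³–Csp³ 1.53 Å, Csp³–Csp² 1.50 Å, C=C 1.34 Å,
C=O 1.22 Å, C(ar)–O 1.36 Å, O–CH₃ 1.43 Å, C–H 1.09 Å; tetrahedral (109.5°)
and trigonal (120°) angles. Sub-0.1 Å geometric fidelity is immaterial here
because the NOE calibration resolves distances only into 1 Å-wide bins.
Double bonds in the isoprenyl chain are fixed in the E configuration; the
rotatable coordinates are the backbone torsions (φ about the ring-to-chain
bond, the allylic and linker torsions of each isoprene unit) plus
methyl/methoxy rotors, which are sampled for distance averaging but never
optimized. Embedding a torsion assignment is exact and deterministic:
requested torsions are realized to 1e-6°.

The dihedral φ(C2C3CβCγ) is the primary conformational coordinate. The
taxonomy is: **folded** iff |φ| ∈ 90° ± 30° (configurable window); among
folded conformers, **U-shaped** iff the closer terminal methyl group lies
within d_U = 6.0 Å (arithmetic-mean H···H distance) of the ring methyl H_W,
else **folded-extended**; everything else **flat-extended**. The window and
d_U are package conventions: the experimental literature gives "~90°" and
describes terminal methyls "directly above the headgroup" without numeric
cutoffs.

Three fixed-torsion reference conformers define the classes for the
two-isoprene chain. The flat-extended reference is the all-anti chain in
the ring plane. The U-shaped and folded-extended ("open-U") references
were calibrated once, by grid search over clash-free torsions at φ = 90°,
to the inter-proton distances reported for these classes: the U-shaped
reference reproduces the reverse-micelle contact pattern (H_W–H_X 2.4 Å,
H_W–H_Z 3.6 Å, H_W–H_Y 4.6 Å vs reported 2.6/3.7/4.6 Å), and the open-U
reference places the nearer terminal methyl at the reported ≈ 5.1 Å from
H_W. Note a deliberate boundary case: at 5.1 Å the open-U reference falls
inside d_U = 6.0 Å and therefore classifies as U-shaped — consistent with
reading a detectable H_W–H_Y contact as an open U. Tests pin this
reference by its distance, not by a folded-extended label.

## Volume → distance calibration

Cross-peak volumes are standardized per (spectrum, environment) block
against the reference pair H_W ↔ H_M/H_N, whose "known" separation anchors
the scale at r_ref = 3.5 Å. Classes and bins follow the standard scheme:
strong (> 1.5) → (1.8, 3) Å, medium (0.6–1.5, boundaries inclusive) →
(3, 4) Å, weak (< 0.6) → (4, weak_upper) Å. The contact floor 1.8 Å is the
van der Waals H···H limit; weak_upper defaults to the 5 Å NOE detection
limit and can be disabled (observed cross peaks have been modeled at larger
separations; see "conflicts" below). ROESY tables use identical arithmetic;
the spectrum type is metadata. Duplicate NOESY/ROESY observations of a pair
merge by bound intersection; an empty intersection warns and retains the
widest compatible bound, flagged in the restraint's source field.

The continuous ISPA relation r = r_ref·V_norm^(−1/6) is the analytic
cross-check. Bins and the exact r⁻⁶ law cannot agree everywhere: with the
class boundaries at r_ref·1.5^(−1/6) and r_ref·0.6^(−1/6) but hard bin
edges at 3 and 4 Å, the disagreement set is the symmetric difference of the
two partitions — two thin slivers around the bin edges
(`calibration_discrepancy_intervals` computes them for any r_ref). Round
trips and bracketing are asserted exactly outside the slivers and the
slivers themselves are pinned as the known exception set.

**Group distances.** Equivalent protons (methyls, the overlapping
methylene pair, the two methoxys) are handled as named groups. Two
conventions exist for a group pair's effective distance: the arithmetic
mean over member protons, and the NOE-physics pooling ⟨r⁻⁶⟩^(−1/6). The
calibration's premise — the reference pair sits at its "known distance"
of ≈ 3.5 Å — is a mean-distance statement: true ⟨r⁻⁶⟩ pooling over a
methyl–methylene pair gives an effective ≈ 2.25 Å and would detach the
volume scale from the printed bins entirely. The simulator and the
restraint evaluation therefore default to the single-representative
(mean) distance per group pair, with `mode="r6"` available where the raw
physics is wanted. Classification always uses mean distances.

## Restrained fitting

The fitter is deliberately not a force field: published workflows in this
area use distance-restrained model building with geometry held ideal, so
the optimizer searches torsion space only. Objective: flat-bottom quadratic
restraint penalty (weight 10 per Å² of bound violation, evaluated on the
group's effective distance) plus a soft-sphere steric penalty. The steric
term applies a 3.0 Å cutoff with a quadratic ramp to heavy-atom pairs at
least three bonds apart *whose separation actually varies with the backbone
torsions* — rigid pairs (ring geometry, cis-fixed substituents) are
excluded numerically at setup, so a clash-free conformer scores exactly
zero. The 3.0 Å value matters: a looser cutoff lets the optimizer satisfy
fold restraints with physically impossible in-plane curls at φ far from
90°; 3.0 Å is the shortest nonbonded C···C approach a real conformer
tolerates, and with it the fold restraints force |φ| into the 60–120°
window on their own.

Search: best-of-n multi-start Powell refinement. Start k draws uniform
random torsions from substream (seed, k) — a prefix-stable stream, so
increasing n_starts can only improve the result — with start 0 always the
all-anti conformer. Ties keep the earliest start. Defaults: n_starts 16
(8 in the bulk recovery experiments), maxfev 600 (400), xtol 0.5°. These
sizes keep a single fit around a second and the 100-fit recovery
experiments around two minutes on one CPU.

**Absence restraints.** Within a monitored group roster, a pair with no
observed cross peak is assigned a lower bound at the detection limit
(5.0 Å). Absence-of-NOE evidence is used cautiously in practice, but it is
exactly what distinguishes an extended chain from a folded one when every
observed contact is short-range; the synthetic recovery experiments (known
ground truth, the same detection limit in the generator) are the setting
where this inference is sound.

**Restraint/model conflicts.** Observed cross peaks whose refined-model
distances fall far outside the NOE range (the pyridine H_W–H_Y contact,
modeled at 8.1 Å) are flagged and excluded from fitting rather than
adjudicated; the pipeline reports them alongside the restraint set.

## Chemical-shift localization

Per probe proton, Δδ magnitudes between each reverse-micelle environment
and the two endpoints are averaged over the RM series. With
τ_small = 0.03 ppm, τ_large = 0.05 ppm: **aqueous** iff the mean distance
to the aqueous endpoint is ≤ τ_small while the organic one is ≥ τ_large;
**organic** iff the mean offset from the organic endpoint is below
τ_zero = 0.005 ppm (indistinguishable at the 0.01 ppm precision of a
printed peak list) while the aqueous one is ≥ τ_large; **interface** iff
the organic offset is real but small (τ_zero < offset ≤ τ_small) and the
aqueous separation is ≥ τ_large; otherwise **indeterminate**. All probe
protons must agree. τ_zero is this package's refinement: without it,
"on the organic endpoint" and "near the organic endpoint" are the same
predicate and bulk-organic and interfacial probes cannot be told apart.
The rule is invariant under re-referencing (adding a constant to one
proton's shifts). Depth *within* the interface is deliberately not graded —
the RM-size series shifts are too small to support it.

## Isotherm analysis

Surface pressure is π = γ₀ − γ with γ₀ = 72.8 mN/m for the aqueous
subphase; negative pressures are legal but flagged. The compression branch
orders points by decreasing area and keeps the last-visited area at
duplicated pressures. Replicates are interpolated onto a shared 0.25 mN/m
pressure grid; sample SDs of the area are evaluated at every 5 mN/m (absent
for a single replicate). Mixed-film areas normalize per phospholipid as
A_N = A/x.

Derivative quantities use a Savitzky–Golay filter (order 2, 11-point
window) — raw second derivatives of trough data are noise-dominated.
Cs⁻¹ = −A·(dπ/dA) by central differences (one-sided at endpoints);
collapse is the grid argmin of d²A/dπ², accepted only as a pronounced
interior feature (curvature below −1 Å²/(mN/m)²; a straight line yields
none). The detection is invariant under uniform area rescaling up to that
absolute threshold. Band overlap between a normalized mixed film and its
control is formalized as mean ± 1 SD disjointness at every 5 mN/m
checkpoint in the window — a declared convention standing in for a
judgment usually made by eye. The expansion metric averages
(A_N(mixed) − A(pure))/A(pure) over a pressure window, 30–35 mN/m
(physiological) by default.

## Synthetic generators

All generators are pure functions of (parameters, seed). NOE volumes
follow the r⁻⁶ law on the effective group-pair distance, scaled to the
reference pair, with multiplicative lognormal noise of specified cv
(volumes are positive with roughly proportional error) and a 5 Å detection
cut; emitted plus suppressed pairs exhaust the roster. Isotherms are
piecewise-linear in (area, pressure) knots with independent Gaussian area
scatter per replicate; the default phase model places gas, liquid and
condensed segments and a collapse plateau at 21 mN/m. The plateau carries
a small residual pressure creep (2 mN/m over the final segment), as real
collapsed films do — this also keeps A(π) single-valued and the collapse
kink an interior feature of the pressure grid. Shift tables place RM
values on or near the configured endpoints (interface offset 0.015 ppm,
read jitter 0.002 ppm) and round to the 0.01 ppm precision of a printed
peak list.

What the generators do *not* emulate: spin diffusion and mixing-time
build-up in the NOE volumes, peak overlap and integration error beyond a
scalar cv, trough mechanics (hysteresis, leakage, barrier effects),
temperature and subphase composition effects on shifts. Passing recovery
tests therefore demonstrate that the analysis chain inverts its own
generating model at realistic noise — not that real spectrometer or trough
data would behave this well.

## Experiment sizes and numerical conventions

Recovery experiments use 50 seeds per conformation class (volume cv 0.2),
50 seeds for collapse (area sd 0.5 Å²) and 100 seeds per location for
localization — sizes at which the asserted ≥ 90%/95% rates are stable and
the whole suite completes in a few minutes on one CPU. Dihedrals are
reported in (−180°, 180°]; unordered pair identity is canonicalized
lexicographically; all stochastic stages take explicit integer seeds and
per-item substreams are spawned as (seed, index) so result prefixes are
stable under enlarging an experiment.

## Known limitations

* The restrained optimizer explores ~5 torsions with tens of starts; it is
  a construction tool for desk-scale models, not a conformational-ensemble
  sampler, and reports a single best conformer per restraint set.
* Bins and the r⁻⁶ law disagree inside two known distance slivers; restraint
  brackets are only asserted outside them.
* The published per-environment cross-peak sets encode qualitative
  "detected" observations where no distances were printed; the resulting
  restraints are upper bounds at the detection limit, so the fitted
  conformers for those environments are representative, not unique.
* MK support covers topology, groups and fitting; the published restraint
  tables shipped in `datasets` are for the UQ-2 system.
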