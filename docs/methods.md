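# Methods

`cadmech` analyses the mechanics of tandem extracellular cadherin (EC)
repeats, centred on the case of a calcium-free inter-repeat linker that is
bent at rest and unbends under force — the situation found near the lower
end of the inner-ear tip link, where protocadherin-15's EC9–10 junction is
thought to contribute the filament's only soft elasticity. This note
records the models, conventions and numerical choices the package makes,
and what its synthetic-data tests do and do not establish.

## Sequence-level linker classification

Canonical cadherin linkers bind three Ca²⁺ ions through five motifs: XEX
(base) and DYE from the first repeat, DXNDN at the linker, DXD and XDX
(top) from the second repeat. `linker_motifs` scores each motif at a fixed
anchor rather than searching, because motif position within the repeat is
structurally conserved. Anchors are measured from the repeat-pair
boundary (negative offsets into the first repeat, positive into the
second), which makes classification invariant to flanking sequence. The
default offsets (−98, −35, −5, +33, +70 for a ~100-residue repeat) are a
convention, user-overridable per `MotifSpec`; only the DXNDN anchor (the
last five residues of the first repeat) is structurally forced.

Required-position sets are deliberately minimal: XEX requires only the
central E; DYE requires D1 and E3; DXNDN requires D1, N3 and D4 with N5
optional — this is what admits the naturally occurring DMNDY variant as
intact; DXD requires both aspartates; XDX requires the central D. A
linker is *canonical* with all five motifs intact (three predicted
sites), *calcium-free* with at most two (no predicted sites), and
*degenerate* in between (predicted sites = intact − 2). The degenerate
band exists because sequence evidence alone cannot force a binary call;
three-dimensional site geometry is the geometry module's job.

## Structure and trajectory geometry

* **Principal axes** are the top eigenvector of the Cα coordinate
  covariance, oriented from the N-terminal-half centroid to the
  C-terminal-half centroid. If the top two eigenvalues differ by less
  than a factor 1.2 the axis is declared degenerate and an error is
  raised rather than returning a noise-dominated direction.
* **Bend angle** is the angle between the oriented axes of two domains;
  0° is the straight tandem arrangement, so a bent calcium-free linker
  reads ~90°. Whether a crystallographic "bend" should be an axis angle
  or a chain-trace angle is genuinely ambiguous; the axis convention is
  implemented and tolerances on bent-structure checks are wide (±15°).
* **Orientation maps** align the reference domain's principal axis to +z
  per frame, fix the azimuth gauge with its second principal axis (sign
  pinned by the first Cα), and histogram the probe axis's x–y projection
  on a 50×50 grid over the unit square. The gauge is a convention; any
  fixed reference structure can replace it without changing the map's
  shape, only its rotation.
* **RMSD** uses Kabsch superposition via
  `scipy.spatial.transform.Rotation.align_vectors`; the test suite
  cross-checks it against an independent quaternion-grid search refined
  by Nelder–Mead.
* **Calcium sites** at a linker are HETATM Ca ions within 8 Å of any
  linker-residue atom, labeled 1→3 by projection along the first
  repeat's axis (site 1 nearest the repeat base). The site-2/site-3
  distance d23 is reported only when all three sites are present, since
  with fewer ions the labels are ambiguous. The canonical-linker
  reference mean (6.84 Å) ships as a constant for comparison; the
  reference structure set itself is not redistributed.
* **R_g** is the mass-weighted radius of gyration; masses come from a
  packaged element table and an unknown element is an error, never a
  silent zero.
* **Buried surface area** uses Shrake–Rupley SASA (biotite
  implementation; probe 1.4 Å, 1000 points/atom, element-based radii)
  with the interface convention BSA = (SASA_A + SASA_B − SASA_AB)/2; the
  full-sum variant is available by flag. Interface residues are those
  losing >1 Å² (unhalved). Because the sphere-point grids are fixed in
  the lab frame, BSA is rotation-invariant only to the discretization
  error (~1%); the exact-invariance tolerance applies to bend angle,
  d23 and R_g, not to BSA.

## Force-curve analysis

Traces are reduced the way steered-MD pulling data is reduced: a 50 ps
centered running average (edges truncated), then force binned against
extension in 1 Å bins; empty bins are absent, never zero. The two
elastic phases are segmented by exhaustive two-segment least-squares
breakpoint search with at least 4 bins per phase, the breakpoint bin
assigned to phase II. The search is preferred over eyeballing "linear
regions" because it is deterministic and testable; a fit that improves
the single-line SSE by less than 5% is flagged single-phase. Slopes are
reported in mN/m (1 pN/nm ≡ 1 mN/m). Peaks are prominence-based (default
50 pN — a choice, configurable); ruptures on distance monitors use a
4.0 Å heavy-atom cutoff sustained ≥0.5 ns (also a choice; re-formation
re-arms the detector). Spring-unit conversions are exact, using
kcal = 4184 J and Avogadro's number; 1 kcal mol⁻¹ Å⁻² = 69.479 pN/Å.

## The three-state linker model

The mechanical model abstracts a tip-link fragment as rigid segments
(axial stiffness 570 mN/m per repeat — the straight-repeat value measured
at 0.1 nm/ns, explicitly an upper bound for slower rates) joined by a
three-state linker: native (bent), intermediate (+Δx₁ = 2 nm) and
extended (+Δx₁+Δx₂, Δx₂ = 2.5 nm). Three states rather than two because
the bent linker shows a reversible ~2 nm partial excursion distinct from
full unbending. The total Δx = 4.5 nm splits the difference between the
~4 nm constant-force extension and the ~5 nm working distance quoted for
the same transition; it is flagged, not resolved.

Kinetics are Bell-type with the barrier at x‡ along the pulling
coordinate:

    k₊(F) = k₀ exp(−(ΔGᵢ − F·x‡ᵢ)/k_BT),   k₋(F) = k₀ exp(−F(Δxᵢ − x‡ᵢ)/k_BT)

so k₊/k₋ satisfies detailed balance and long Gillespie runs converge to
the Boltzmann occupancies of the tilted energies (verified to 3 SE in the
suite). The default calibration ΔG₁ = 7 k_BT, ΔG₂ = 8 k_BT,
x‡ = 1 nm, k₀ = 10⁷ s⁻¹ is *chosen, not derived*: no kinetic parameters
exist for this transition, and the calibration is fixed by requiring the
observed behavioural dichotomy — at a ~10 pN resting tension the linker
essentially never unbends fully within a microsecond, while at ≥25 pN it
typically does. All parameters are overridable.

Quasi-static force–extension Boltzmann-weights the three states under the
tilted energies and adds the Hookean segment term; with N parallel
strands each strand carries F/N, so two identical strands exactly double
the effective stiffness. The constant-velocity simulator balances a
machine spring (default 1 kcal mol⁻¹ Å⁻² ≈ 695 pN/nm) against the chain
quasi-statically each step — no inertia or hydrodynamics, because the
target observables are slopes and thresholds, not dynamics. The emitted
trace records the *protein's* end-to-end extension, the quantity
force-versus-distance analyses plot; in the Hookean limit its slope is
the chain stiffness (the machine spring cancels out of that plot). The
fixed step must satisfy dt·k_total ≤ 0.1 and the simulator errors
otherwise rather than silently under-resolving transitions; rate
overflow at extreme force is likewise an error advising a parameter
change.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of (parameters, seed), with one named
RNG stream per generator, and serializes a truth record sufficient to
re-derive every expected downstream result.

* **Two-domain structures** are prolate clouds (aspect ratio ≥ 4, 45 Å
  default segment length — the canonical repeat length) whose transverse
  scatter is decorrelated from the long axis, so the constructed
  principal axes, bend angle and calcium-site spacings are recovered
  exactly, not just on average. Pseudo-Ca ions sit on the first domain's
  axis at configurable (d12, d23) spacings within coordination reach of
  the linker residues.
* **Trajectories** re-orient the second domain rigidly per frame by a
  Gaussian perturbation of its axis direction — per-axis dispersion
  ≈ `bend_sd` for small values, wrapping to an exactly isotropic
  distribution for large ones. Unbending events translate the domain
  along the end-to-end direction by exactly the stated extra extension
  (orientation unchanged), so the plateau oracle is exact by
  construction.
* **Force traces** are piecewise-linear means (defaults 30/445 mN/m,
  breakpoint 4.5 nm) plus i.i.d. Gaussian noise, with rise-then-drop
  triangular peaks.
* **Sequences** carry textbook motifs at the default anchors, ablated per
  class with substitutions patterned on the real calcium-free linker.

What passing these tests shows: the measurement and fitting machinery is
correct on inputs whose truth is known exactly, at the study's stated
parameter values. What they do not show: behaviour on real,
heterogeneous data — real domains are not Gaussian clouds, real force
noise is correlated, real motif anchors drift with indels. The checks
against deposited crystal structures in `tests/test_acceptance.py` close
part of that gap but require the real PDB entries in `data/deposited/`
(see the README there); they fail cleanly when the files are absent,
since the coordinates are neither redistributed nor downloadable in an
offline environment.

## Problem sizes

Default test and acceptance problem sizes are chosen as the smallest that
make the statistical assertions sharp: 5,000-point traces for slope
recovery, 10⁴–10⁵ Gillespie events for occupancy and dwell checks,
2×2,000 frames for isotropy (two independent replicates, requiring one
1%-level pass, bounds the false-alarm rate at 10⁻⁴), 60–301 stochastic
replicates for the unbending dichotomy (the 25 pN first-passage median
needs ~300 replicates before its sampling error is small next to the
1 μs threshold). Stochastic assertions use 3-SE tolerances against
closed-form expectations throughout.

## Known limitations

* Sequence classification is anchor-based; it does not align, so indels
  between the anchor and the boundary shift motifs out of frame.
* The stiffness ladder of the coarse model (570 mN/m per repeat) is an
  in-silico upper bound; phase-II stiffness at physiological rates is
  expected lower, and phase-I stiffness from the model is a sawtooth
  average, not a material constant.
* No unfolding states: forces beyond ~400 pN, where repeat unfolding and
  complex unbinding compete, are outside the model's validity.
* No calcium allostery; motif classification and mechanics are coupled
  only through the user's choice of linker type.
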