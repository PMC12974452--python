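# Methods

## Scope and data model

`hydroshell` analyses three kinds of input around one scientific object — the
pH response of a protein's hydration shell:

- **Atomic models per condition** (`core`): PDB/mmCIF files parsed with gemmi
  into `StructureModel`s, ordered collections of `AtomRecord`s partitioned
  into protein atoms, water oxygens (residue HOH and synonyms) and
  monoatomic ions (by residue name). Alternate locations collapse to the
  highest-occupancy conformer; insertion codes are dropped. Coordinates are
  Å everywhere; no unit conversion happens at I/O boundaries.
- **Trajectories** (`trajectory`): a topology plus a dense
  (frames × atoms × 3) array, read from multi-model PDB or multi-frame XYZ
  next to a single-frame PDB topology. Atom identity must be constant across
  frames; only water *oxygens* enter any water statistic.
- **λ traces** (`titration`): two-column (time, λ) text files, one per
  (residue, pH), tied together by a JSON manifest.

## Solvent chain assignment and symmetry

Waters and ions are assigned to the chain of the globally nearest protein
atom. When several chains tie within a tolerance *and* the tying atoms sit at
the same ordinal position within their chains — the signature of a symmetry
axis — the molecule is shared: occupancy 0.5, 0.33 or 0.25 for two-, three-
or fourfold multiplicity (stored as printed in deposited files, i.e. 0.33
rather than 1/3) on the alphabetically first tying chain. Ties between
unrelated atoms keep occupancy 1.0. The tie tolerance defaults to 1e-3 Å:
deposited coordinates carry three decimals, so exact float equality would
miss real symmetry sites. This tolerance is our choice; no published value
exists for it.

## Superposition

Kabsch/SVD least-squares rigid-body fitting on atoms paired by
(chain, residue id, atom name), Cα atoms by default. When some selected atoms
fail to pair, the fit proceeds with a logged warning as long as ≥90% pair;
below that the first unmatched atom is reported as an error. The resulting
transform is applied to all atoms including solvent, and models carry a
`superposed` flag that the cross-condition clustering requires (data
generated directly in a shared frame may set `require_superposed=False`).

## Water persistence across conditions

Clustering is single-linkage agglomeration: water oxygens from all superposed
models link when their distance is strictly below the cutoff (default
1.0 Å); clusters are the connected components. Single linkage was chosen
because it is parameter-free beyond the cutoff, deterministic, and coincides
with DBSCAN at min-samples 1 — the variant used for density-peak merging.
Distances exactly at the cutoff do **not** link; the boundary convention is
tested explicitly. A cluster may contain two waters of the same condition
(bridged by linkage); the persistence count is over *distinct* condition
labels. Output order is deterministic (descending condition count, then
centroid), so results are independent of input model order.

Nearest-residue annotation uses protein heavy atoms only (deposited models
carry no hydrogens) with a 3.6 Å cutoff; a centroid farther than that is
*unassigned*, a value rather than an error.

Nearest water–water distances are computed within each condition's realized
waters (the physically meaningful spacing), then pooled by the persistence
category of the site each water belongs to. Category pairs are compared with
the exact two-sample KS statistic — the supremum of |ECDF₁ − ECDF₂| evaluated
on the pooled sorted values — implemented directly and cross-checked in tests
against scipy's independent implementation.

## Trajectory hydration sites

Sampling windows of 500 frames (1 ns at the 2 ps default frame interval) end
at each interval multiple — a 100-ns trajectory with 10-ns intervals yields
the ten windows ending at 10, 20, …, 100 ns; the scaled-down test runs use a
10-ns trajectory with 1-ns intervals, which preserves the ten-window
averaging structure at desk scale. Each frame is rigid-body aligned on
protein heavy atoms to a common reference (first window's first frame).

Density accumulation: per voxel of a 0.5 Å grid,
ρ = m_water · ⟨count per frame⟩ / V_voxel with m_water = 18.015 u =
2.9915e-26 kg and V_voxel = 0.125 Å³ = 1.25e-28 L, so one stationary water
in one voxel gives 239.3 kg/L and bulk water at 0.0334 Å⁻³ gives 1.00 kg/L.
Voxels whose centers lie beyond 5 Å of any protein heavy atom are zeroed
(the shell mask); masking can be disabled to check mass conservation.

Smoothing replaces each voxel by the unweighted mean of itself and its
face-adjacent neighbors (7-point stencil; an 18-neighbor variant adds the
edge diagonals behind a config switch — which neighborhood "sharing an edge"
denotes in 3-D is genuinely ambiguous, and 6 is the minimal reading).
Boundary voxels average over existing neighbors only, which makes a uniform
grid a fixed point of the smoother; the price is that the global sum is
conserved only for mass at least two voxels from the grid boundary (tested
there exactly). Since the grid pads the protein by the shell cutoff plus one
voxel, real density never sits on the boundary.

Site detection keeps voxels ≥ all 26 neighbors (plateau ties kept) at or
above 6 kg/L, then merges maxima closer than 1 Å by the same
strict-< single linkage and replaces each group by its density-weighted mean
position (unweighted variant behind a config switch; weighting was chosen for
stability under grid jitter). The threshold is applied to maxima *before*
merging. The site density is the maximum member density; when sites from
several windows are combined, positions and densities are averaged over
windows, making the result independent of window order. Each site's residue
is the one whose heavy atom is closest most often across frames, ties going
to the lower residue id; its occupancy is the fraction of frames with a
water oxygen within the residue cutoff of the site.

## Residence times

S(t) is **continuous** survival: of the waters inside the shell (minimum
oxygen-to-selected-heavy-atom distance ≤ cutoff, default 3.6 Å) at an origin
frame, the fraction still inside at *every* frame up to lag t, averaged over
origins; a water that exits and re-enters does not survive. Continuous
survival is the standard definition and consistent with the picosecond-scale
lifetimes of interest; an intermittent variant is deliberately not
implemented. The maximum lag defaults to half the window length to bound
origin-count attrition, and origins with an empty shell are skipped — a
window whose shell is never occupied yields an *undefined* curve whose τ
propagates as NaN rather than a silent zero. τ is the trapezoidal integral
of S over its lags, truncated without tail extrapolation; when S at the last
lag exceeds 0.05 a lower-bound caveat is logged.

## Titration

λ < 0.2 counts as protonated, λ > 0.8 as deprotonated, intermediates are
discarded. The deprotonation fraction defaults to
n_deprot/(n_prot + n_deprot) — the quantity that rises with pH and feeds the
fit — with the complementary n_prot numerator available via
`literal_deprotonation=True`; the two conventions sum to one on any trace and both are
exposed because published formulas sometimes print the complementary form.
With no countable samples the fraction is undefined (flagged, not zero). The
Henderson–Hasselbalch/Hill fit initializes pKa at the pH of the point
nearest S = 0.5 with n = 1, bounds n to [0.2, 4], warns when the points do
not bracket the transition, and flags all-0/all-1 data as unbounded rather
than fitting. Fitted pKa values are binned into [2, 4) (deprotonated
throughout the usual pH window), [4, 5) (mid-transition) and > 7 (anomalous),
with everything else left unclassified.

## Residue statistics

Bound-water counting is multi-assignment by default: a water within 3.6 Å of
heavy atoms of two residues counts once for each, so per-type totals add over
contacts; a nearest-only mode matches the clustering module's convention.
Total water inventories report both the record count and the
occupancy-weighted sum, because symmetry-axis waters carry fractional
occupancies and either can be the right inventory depending on the question.
The desolvation trend is unweighted OLS of totals on pH — slope in waters
per pH unit, positive when acidification sheds waters.

ASA is Shrake–Rupley with golden-spiral sphere points (960 by default,
probe 1.4 Å) over a shipped Bondi-style element radius table (metals use
working values); unknown elements raise rather than guess. The default
hydrophilicity covariate is the Hopp–Woods scale, switchable, since no single
scale is canonical.

## Metal geometry

The assembly's geometric center is the unweighted mean of protein heavy
atoms (solvent and ions excluded), computed per condition; ion-to-center
distances summarize channel-metal displacement across pH. Ion–water contact
lists tag each nearby water with its persistence category and flag distances
≤ 3.5 Å as hydrogen-bond range (a conventional threshold; no published value
accompanies the qualitative statement it implements). Magnesium controls run
through the same code path parameterized by element.

## Synthetic data

The generators plant statistics, not physics — no water–water interactions,
no excluded volume for bulk:

- **Condition ensembles**: a deterministic toy-protein scaffold (all 20
  amino-acid types on a ring, identical across conditions so superposition is
  exact; a 24-chain octahedral variant exists for symmetry-occupancy tests).
  Shared sites appear in every condition with Gaussian jitter (default 0.2 Å,
  below half the 1.0 Å cutoff for clean recovery); lone and shared sites are
  rejection-sampled within the 5 Å shell at ≥2×cutoff separation, with an
  explicit packing error when infeasible. When a desolvation slope is
  requested, unconstrained filler waters bring each condition's total to
  base + slope·(pH − mean pH) + N(0, σ); defaults (base 600, slope 100,
  σ = 30 over pH 3.5/4/5/7/9) put totals in the several-hundred range
  typical of a high-resolution pH series.
- **Trajectories**: static scaffold; each planted site owns one water
  following a two-state memoryless chain — bound with mean continuous
  lifetime τ (so its survival is exactly exponential and the discrete
  sampling introduces no lifetime bias), unbound with mean off-time
  τ(1−occupancy)/occupancy, teleporting to a uniform box position. Bulk
  background is resampled uniformly every frame at the number density of the
  requested mass density. Teleporting bulk decorrelates instantly, which is
  fine for density grids but meaningless for survival analysis — residence
  recovery therefore runs on sites-only trajectories, and that is what
  passing tests demonstrate; diffusive bulk, hydrogen-bond geometry and
  protein flexibility are *not* emulated.
- **λ traces**: per (residue, pH), states drawn Bernoulli(S(pH; pKa, n)),
  λ ~ N(0.05, 0.03²) protonated / N(0.95, 0.03²) deprotonated clipped to
  [0, 1], plus a 5% intermediate fraction λ ~ U(0.2, 0.8) mimicking
  transition dwell; the default grid is pH 1–10.5 in steps of 0.5 with 2000
  samples per point.

All generators are bit-reproducible from (parameters, seed) and write their
ground truth as JSON beside the data, so tests exercise the file path, not
in-memory shortcuts.

## Problem sizes and numerical choices

Test and example trajectories use 10 ns at 2 ps/frame (5000 frames, ten
500-frame windows) over a compact 20-residue scaffold — large enough for
ten-window averaging and sub-0.5 Å site recovery, small enough to run in
seconds. Tie-breaks are deterministic everywhere (alphabetical chains, lower
residue ids, sorted outputs); cutoff boundaries are strict `<` for linkage
and `≤` for shells and contact counting; degenerate inputs (empty shells,
all-intermediate traces, all-saturated titrations) produce flagged values,
not exceptions, wherever a value is a legitimate outcome.

## Known limitations

- Clustering variant (single vs complete vs centroid linkage) and the
  at-cutoff convention are documented choices; reproducing another group's
  site counts exactly may require matching their variant.
- No density-map handling, atom-level map validation, electrostatic surface
  potentials, or MD engine — trajectories and λ traces are consumed, never
  produced.
- ASA radii for metals are working values; per-atom ASA of exotic ligands
  needs radius-table extension.
- The survival estimator averages ratios over origins, which is slightly
  right-skewed for sparse shells; window averaging keeps this well inside
  the per-window standard error at the tested scales.
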