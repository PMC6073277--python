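# Methods

Units throughout: Ångström for length, picoseconds for time,
kcal·mol⁻¹ for energy, Kelvin for temperature. Residues are identified
by `(chain, resid)` with 1-based PDB numbering; insertion codes are
rejected. Reports use chain-prefixed labels such as `L:R113`.

## Superposition and fluctuation metrics

Rigid superposition solves the weighted Wahba/Kabsch problem through
scipy's `Rotation.align_vectors`; reflections are excluded, degenerate
(collinear) point sets are rejected. RMSD is the plain coordinate
root-mean-square deviation after superposition, evaluated on the same
selection used for fitting (a separate fit selection can be supplied).

RMSF is referenced to the *iterated mean structure*: frames are
superposed on a running average until the mean moves by less than
10⁻⁶ Å (at most 10 passes), then
RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩. Mean-structure referencing is what makes the
crystallographic conversion B = (8π²/3)·RMSF² meaningful; a frame-1
reference mode exists for comparison with tools that fit to the first
snapshot. Per-residue values aggregate atomic mean-square fluctuations
before the square root. The B-factor comparison to experiment is an
ordinary least-squares fit reporting R², N and the slope (R² alone is
sign-blind).

Time-windowed RMSF slides a fixed-length window (the heat-map view of
mobility trends); a single full-length window reproduces the global
profile exactly, which the tests assert.

Backbone dihedrals follow the standard definitions
φ = C(i−1)–N–CA–C and ψ = N–CA–C–N(i+1), IUPAC sign convention, reported
in (−180°, 180°] with a [0°, 360°) display mode for circular plots.
Chain-terminal angles are absent (`None`), never zero. The sign
convention is cross-checked against biotite on constructed geometries;
note that reversing the atom order of a proper dihedral leaves the
angle unchanged — it is mirror reflection that flips the sign.

## Contact maps and comparison statistics

Two residues are in contact when their minimum inter-atomic distance is
strictly below the cutoff (default 4.5 Å). "Distance between residues"
is the minimum over heavy atoms: a Cα–Cα reading at 4.5 Å would find
almost nothing at a protein–protein interface, and the min-atom reading
is the one consistent with contact totals in the hundreds on a
~115-residue interface protein. Both alternatives (`any`, `ca`) remain
selectable. Sequential-neighbour exclusion is off by default because
inter-molecular maps contain no sequence neighbours; a flag enables it
for intra-molecular maps.

Comparing an initial and a final snapshot yields

* similarity = n_common / (n_common + n_specific_initial + n_specific_final),
* reduction rate = (n_specific_initial − n_specific_final) / n_initial,

the latter reported signed: a complex that gains contacts has a negative
rate. Contact timelines report per-pair occupancy and the break frame —
the first sampled frame after which the pair never reappears.

## Geometric interaction criteria

**Hydrogen bond:** acceptor⋯hydrogen distance < 3.5 Å AND
acceptor–hydrogen–donor angle > 135°. The distance is deliberately
measured to the hydrogen, not between the heavy atoms; a
`distance_mode="donor-acceptor"` switch provides the more common
heavy-atom convention. Donor hydrogens are resolved by name tables
within each residue (no bond perception): `HG`→`OG`, `HH11`→`NH1`,
water `H1/H2`→`O`, backbone `H`→`N`, and so on. Acceptors are all
oxygens plus histidine ring nitrogens. Hydrogens must be present
(MD-style topologies); crystal structures without hydrogens are
rejected with a clear message. Occupancy is the fraction of sampled
frames in which the criterion holds; a 40 % reporting filter is
available.

**Salt bridge:** side-chain O of Asp/Glu (OD1/OD2, OE1/OE2) within 4 Å
of side-chain N of Arg/Lys/His (NH1/NH2/NE, NZ, ND1/NE2 — both
histidine nitrogens are kept because protonation is topology-dependent).
Classification per residue pair: *bidentate* when ≥ 2 distinct O–N pairs
qualify simultaneously in at least half of the frames, *single* when the
pair is present in at least half of the frames with one qualifying
O–N pair, and *half* when the criterion holds in fewer than half of the
frames. "Half salt-bridge" has no universal geometric definition; this
temporal reading is this package's documented interpretation.

**Water bridge:** a water hydrogen-bonded (same criterion, water as
donor or acceptor on either side) to one partner atom on each side in
the same frame. Besides per-water occupancies, a "dynamic relay" view
reports the occupancy of each partner pair with *any* water, because the
mediating water molecule frequently changes identity while the bridge
itself persists.

**Interface-water census:** a water counts when any of its atoms lies
within the shell cutoff (default 4 Å) of any atom of the region of
interest; reported per sampled frame with the mean.

## Surface areas

SASA uses the Shrake–Rupley construction: each atom's sphere is expanded
by the probe radius (default 1.4 Å, a water molecule) and covered with a
deterministic Fibonacci lattice (default 960 points, no random numbers,
bit-reproducible); the accessible fraction is the fraction of points
outside every neighbour's expanded sphere. Van der Waals radii are the
bundled Bondi table (`mdcompare/data/elements.json`), overridable.
Hydrogens are excluded by default. Single-sphere and two-sphere analytic
closed forms agree within 1 % at 960 points, and doubling the point
count moves totals by < 0.5 %.

Buried interface area: S_buried = (S_A + S_B − S_AB)/2 with S_A and S_B
computed on each group in isolation and S_AB on the union; the identity
is exact by construction, and swapping the groups cannot change the
result.

## PCA, free-energy landscape, clustering

PCA diagonalises the covariance of the superposed selected coordinates
(Cα-only by default; all-heavy optional). Projections are centred;
eigenvalues are clipped at zero and sorted descending; reconstruction
from all modes reproduces the superposed coordinates to 10⁻⁸ Å.

The free-energy landscape is ΔG(X) = −k_B T ln P(X) with
k_B = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹, T defaulting to 300 K, P(X) the 2-D
histogram of (PC1, PC2) over a default 50×50 grid spanning the data;
occupied bins are anchored so min ΔG = 0 and empty bins are undefined
(NaN), not zero. Basins — "relatively independent low-free-energy
regions" — are counted as connected components (8-connectivity) of bins
whose Gaussian-smoothed probability (σ = 1.5 bins) lies within a depth
threshold of the deepest bin, default 1 k_BT. Smoothing the counts
rather than the log-transformed energies keeps shot noise in sparse
bins from fragmenting one basin into many; well-separated minima still
contribute one component each. The count is reported together with the
depth parameter. At very low sampling (a few hundred frames on a 50×50
grid) the count remains noise-sensitive; the validated regime is
~2000 frames.

Clustering uses pairwise superposed RMSD with a threshold, default
1.7 Å (= 0.17 nm; both figures appear in the literature for the same
threshold and are consistent only under that unit reading). A
deterministic leader pass in time order assigns each frame to the first
cluster whose representative is within the threshold — so every frame
is within the threshold of its representative at assignment time — and
each representative is then refined to the cluster medoid. The leader
pass alone runs in O(K·n_clusters) without materialising the full RMSD
matrix; medoid refinement uses the batched-SVD pairwise matrix. An
exact complete-linkage mode (naive O(N³) agglomeration) is provided for
small frame counts and is tested against scipy's hierarchy
implementation. Cluster counts are non-increasing in the threshold.

Slow-mode ("porcupine") vectors are eigenvector components ×
√eigenvalue × scale, anchored at the mean structure.

## Binding-energy bookkeeping

The assembly implements ΔG_bind = ΔH − TΔS with
ΔH = ΔE_VDW + ΔE_ELE + ΔG_PBELE + ΔG_PBSUR. Solver outputs (the four
component means, the entropy term, per-residue decompositions) arrive as
TSV tables; no PB/GB or normal-mode computation happens here. When both
ΔH and the components are supplied they must agree within
0.02 kcal·mol⁻¹ (slack for published rounding); the assembled
ΔG_bind = ΔH − TΔS is exact arithmetic. Polar (ΔE_ELE + ΔG_PBELE) and
nonpolar (ΔE_VDW + ΔG_PBSUR) groupings carry favourable/unfavourable
flags with the convention that negative favours binding. Key residues
are those contributing less than −1 kcal·mol⁻¹ (configurable), sorted
most favourable first. Missing experimental references print `n/a`
rather than an imputed number.

## Synthetic-data generator

The generator emulates the *statistical* structure the analyses consume,
not protein physics: an idealised extended two-chain geometry
(N/CA/C/O plus one side-chain pseudo-atom per residue, 3.8 Å Cα spacing,
chains 10 Å apart, a z-zigzag that keeps the Cα trace non-collinear so
superposition is well posed), rigid 3-site waters, and per-residue
isotropic Gaussian displacements whose standard deviation is chosen so
the expected Cα RMSF equals the requested profile (σ per coordinate =
RMSF/√3). Planted features are placed with safety margins: live
contacts at 4.0 Å (vs the 4.5 Å cutoff) moved beyond 6 Å after their
break frame; hydrogen-bond triples at H⋯A = 2.2 Å, 180°, with the
acceptor displaced 5 Å in Bernoulli-off frames; salt bridges at their
target N–O distance (ASP/ARG naming for bidentate, GLU/LYS for single);
bridge waters midway between two hydroxyl acceptors, donating both
hydrogens, displaced out of plane in off frames. Residues hosting a
planted feature are pinned (zero fluctuation) so the planted geometry is
exact every frame; amplitude-recovery tests therefore read off
feature-free residues. One residue cannot host two features, and two
placements of one atom more than 0.5 Å apart raise an error.

Everything is drawn from one seeded generator in a fixed order, so a
spec plus seed is bit-reproducible. What the generator does *not*
emulate: realistic stereochemistry, correlated (collective) motions,
solvent structure, or force-field energetics — so passing recovery
tests demonstrates the correctness of the estimators on their stated
statistical model, not agreement with real MD data.

Default study conditions used by the recovery tests follow the validated
regime: 2000 frames at 1 ps spacing for amplitude/occupancy recovery
(profile recovered within ±10 %, occupancy within ±5 points),
≤ 100-frame instances for the exact complete-linkage comparison, and a
few hundred randomised frames of ~100–200 atoms for the brute-force
detector equivalences (which are exact set equalities at any scale).

## I/O and numerical choices

PDB parsing/writing goes through biotite (altloc resolved to highest
occupancy, elements inferred from atom names when the element column is
blank, one frame per MODEL). Coordinates are rounded to the format's
three decimals on both write and read so round-trips are exact at
format precision and float32 intermediates cannot flip a printed digit.
The XYZ reader pairs a plain coordinate stream with an existing
topology; frame times come from a stated stride (default 1 ps).
Distance thresholds are strict (`<`); angles strict (`>`). KD-trees
accelerate contact and shell searches; the brute-force oracles used in
tests share no code with the production paths.

## Known limitations

* No binary trajectory formats (DCD/XTC); the reader contract is
  pluggable.
* No π–π or cation–π detection, no energy-based hydrogen-bond scoring.
* Basin counts at low sampling densities are noise-sensitive (see
  above).
* The salt-bridge "half" class is a documented temporal interpretation.
* MM/PBSA numbers are bookkeeping over externally computed components;
  the package neither validates nor reproduces the solvers that made
  them.
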