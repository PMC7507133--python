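# Methods

This note records the model, the parameter choices that matter, and the
numerical decisions behind `shapecloud`, in the spirit of a software methods
section. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Surface model

The molecular shape is the van der Waals envelope: the union of atomic
spheres at Bondi (1964) radii (bundled in `constants.BONDI_RADII`,
overridable per call). Each sphere is sampled with a deterministic Fibonacci
lattice and a dot survives iff it is not strictly inside any other sphere,
with a burial tolerance of 1e−6 Å so tangent contacts survive. Normals are
analytic (radial), so no PCA normal estimation is needed anywhere
downstream. Dots inherit their parent atom's pharmacophore class:

| class | members | render color | scalar color value |
|---|---|---|---|
| 1 | nonpolar H; Cl, Br, I | white | 1.00 |
| 2 | N, O, S, F; H bonded to N/O | red | 0.00 |
| 3 | C, P, B | green | 0.50 |
| 4 | everything else | blue | 0.25 |

An H counts as polar when bonded to N or O; without a bond table (XYZ, bare
PDB) the fallback is a nearest-N/O distance below 1.3 Å, safe because
covalent H–N/H–O bonds are ≤ 1.1 Å and the next contacts exceed 1.8 Å.

**Dot density.** The registration pipeline is built around a cloud whose
mean adjacent-point spacing is ~0.3 Å — that spacing is the justification
for the 0.3 Å fitness pairing threshold. A constant per-sphere dot count
cannot deliver it: 600 dots on a hydrogen sphere (r = 1.20 Å) are spaced
~0.17 Å while the same count on carbon (r = 1.70 Å) gives ~0.24 Å, and the
resulting cloud is both non-uniform and too dense. `shapecloud` therefore
distributes dots at uniform *area density*: the nominal budget
`dots_per_atom` (default 600) is referred to a sphere of radius 2.40 Å,
giving 600 / (4π · 2.40²) ≈ 8.3 points/Å², and each atom receives
`round(4π r² · density)` dots. The reference radius was fixed once, from
surface-only measurements on the embedded fixtures, so that the default
budget reproduces the 0.3 Å mean nearest-neighbor spacing; the test suite
measures that spacing on every fixture. A consequence worth knowing: at
this density a 1.0 Å voxel grid removes ~85% of the points of a drug-like
surface, not >90% as an oversampled constant-count cloud would — the two
properties cannot hold simultaneously at uniform density, and the spacing
(which anchors the scoring threshold) was chosen as the binding one.

The scalar color values embed the four categorical classes into [0, 1] for
the colored-ICP color term. They are deliberately well separated
(1.0 / 0.0 / 0.5 / 0.25) so that every cross-class correspondence is
penalized; collapsing the display colors to gray intensity would make red,
green and blue indistinguishable.

## Downsampling

The bounding box is partitioned into cubes of edge *VS* anchored at the box
minimum; per occupied voxel the point nearest the centroid of the voxel's
points survives (ties: lowest point index). Anchoring and the
points-centroid reading make the reduction bit-reproducible for a given
cloud and *VS*; both conventions are recorded here because other anchorings
(e.g. world origin) would change which points survive, though not the
statistics that matter.

## FPFH descriptors

Per point of a reduced cloud, three angular features (α, φ, θ) are measured
against each neighbor within radius 5 · *VS* (capped at the 100 nearest), in
the Darboux frame anchored at the endpoint whose normal makes the smaller
angle with the connecting line. Each feature gets 11 uniform bins
(α ∈ [−1, 1], φ ∈ [−1, 1], θ ∈ [−π, π]); the concatenated 33-bin SPFH plus
the distance-weighted neighbor average forms the FPFH. Two numerical
decisions matter on lattice-like clouds where textbook formulations assume
generic positions:

- pairs of dots on one atomic sphere put the neighbor's normal exactly in
  the (u, d) plane, making θ exactly 0 or ±π; the ±π sign would be decided
  by rounding noise, so it is pinned to +π;
- the frame-origin rule ties exactly whenever the two normals have
  equal-magnitude projections on the connecting line; on a tie the frame
  giving φ ≥ 0 is chosen.

Both choices are pose invariant, which the suite asserts row-wise at 1e−6
after a random rigid motion. Histograms are left unnormalized: matching
uses nearest neighbors in 33-D Euclidean space, so common scalings cancel.

## Global registration (RANSAC)

Correspondences are plain 1-NN in descriptor space, precomputed once per
(cloud, *VS*). Each iteration samples N = 4 source points (N is a
configuration value; 4 gives a well-conditioned rigid fit at low cost),
checks the 10% edge-length consistency |e_s − e_t| ≤ 0.10 · max(e_s, e_t)
on all 6 edges, fits the transform by Kabsch (SVD, determinant-corrected),
and checks that every transformed sample lies within 1.5 · *VS* of its
correspondent. Validated hypotheses are ranked by the RMSE of the whole
reduced source against the target over correspondences within 1.5 · *VS*
(whole-cloud ranking is more robust than ranking on the 4 samples;
hypotheses with zero in-range pairs are discarded, not counted as
validations). Sampling stops at 400 000 hypotheses or 1000 validations.
Iterations are internally batched and the RNG is seeded, so results are
bit-identical for a given seed. Ties in RMSE keep the first hypothesis in
iteration order.

## Colored ICP

Target color gradients are fit per point over a 2 · *VS* neighborhood by
least squares on tangent-plane offsets with a g ⊥ n constraint row. Each
Gauss–Newton iteration matches transformed source points to nearest target
points within 1.5 · *VS* (the only distance scale the global stage defines),
builds point-to-plane residuals n·(p − q) and color residuals on the tangent
plane, weights them by √δ and √(1 − δ) with δ = 0.8, solves the 6 × 6
normal equations for a twist, and re-orthonormalizes the rotation via SVD.
Stopping: 100 iterations, a relative RMSE change below 1e−6, or an RMSE
below 1e−12 (numerically exact; the relative criterion is meaningless
there). If the initial pose yields no correspondence the stage reports
failure and returns the input transform unchanged.

## Scoring and sweep

Fitness is computed on the *full-resolution* clouds (the 0.3 Å threshold is
the full cloud's own spacing). Pairing is strict (<), many-to-one, and
class pairing uses the class of the nearest point only. cfit and hfit are
ratios of summed counts (micro-averages) exactly as defined; hfit is 0 by
convention when the source has no class-2/3/4 points. The sweep runs
VS = 0.2 … 1.2 in steps of 0.1, each with a sub-seed derived by CRC-32 from
(base seed, run id, VS) — deterministic, platform independent, < 2³¹ — and
selects the best gfit + hfit; ties prefer lower final RMSE, then smaller
VS. Repeated-run protocols re-sweep all eleven voxel sizes per repeat and
cluster final poses greedily at 1.0 Å heavy-atom RMSD (the clustering
threshold is a package choice; alternate alignments of interest differ by
far more).

## Synthetic data and what the tests show

Fixtures are small frozen molecules (methane → a 56-atom two-ring
benzamide/piperazine), generated once with a standard geometry builder and
shipped as SDF text; a carved carbon-chain fragment of sorbic acid serves
as the substructure analogue, and `symmetric_color_toy` builds a parabolic
sheet whose geometry has an exact 2-fold symmetry broken only by colors, to
exercise the color term in isolation. These fixtures cover rigid self- and
substructure matching with known ground truth. They do *not* cover
conformational flexibility beyond scripted torsion twists, solvent or
crystal-contact effects, tautomers/protonation, or molecules with class-4
atoms; passing tests therefore demonstrate the registration machinery, not
benchmark-level pose prediction on experimental overlays.

Problem sizes in the default suite and acceptance script (three small
molecules for self-matching, 20 repeats for the substructure protocol,
fixture surfaces of ~1–4 k points) are the package's chosen desk-scale
conditions; all stochastic assertions are made under fixed seeds.

## Known limitations

- Registration is rigid; conformer selection is by exhaustive ranking, not
  flexible alignment.
- The global stage needs enough reduced points (≥ 4) and distinctive local
  geometry; at VS ≥ 1.0 on very small molecules it can fail, which the
  sweep records and skips.
- Surface generation is equivariant only statistically: the dot lattice is
  world-axis anchored, so a rotated molecule's surface differs by a few
  boundary dots (the suite bounds this at 1%).
- hfit of hydrocarbon-only sources reflects class 3 alone; with no polar
  atoms anywhere, hfit is 0 and selection degenerates to gfit.
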