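# Methods

This note records the model, the conventions, and the deliberate numerical
choices behind `ldtk`. Units are nm, ns, amu and kcal/mol unless stated
otherwise; defect areas are in Å² (one grid cell = 1 Å²).

## System model and role maps

A `SystemModel` holds atom names, residue assignments, per-atom masses and
van-der-Waals radii, a molecule table, and per-molecule class labels
(`PL`, `CHYO`, `TG`, `WATER`, …). A YAML *role map* drives construction:
for each residue name it gives the molecule class, fnmatch patterns that
tag atoms with roles (`ESTER_O`, `GLYCEROL_O`, `STEROL_RING`, `ACYL_C`,
`HEAD`, `PHOSPHORUS`, …), and optional element/radius/mass overrides.
Bundled maps live in `src/ldtk/data/`; `load_role_map` accepts a bundled
name, a file path, or an in-memory mapping. Trajectories are read through
MDAnalysis and converted from its Å/ps internals to nm/ns.

Leaflets are assigned from the first frame: the midplane is the mean z of
all neutral-lipid atoms, and each phospholipid goes to `TOP` or `BOTTOM` by
its phosphorus position.

## Core order

The molecular long axis of a sterol ester is the first principal axis of
the gyration tensor of its sterol ring + side-chain atoms, oriented from
the ester-oxygen end toward the side chain. The nematic order parameter is
S = ⟨3/2 cos²θ − 1/2⟩ against either a fixed director or the `auto`
director, the top eigenvector of the Q-tensor (which makes S rotation
invariant). Reported S averages the per-frame values over a trailing
window (default: the last half of the trajectory).

Smectic layer spacing comes from the ester-oxygen number-density profile
along z: peaks are local maxima with prominence at least 10% of the profile
maximum (`scipy.signal.find_peaks`), and the spacing is the mean separation
of successive peaks. Up/down fractions per layer count the sign of the
oriented axis against the director *before* the v ≡ −v symmetrisation used
by S.

## Surface classification and residence filter

The phospholipid tail plane of a leaflet is the unweighted mean z of all
PL acyl-chain carbons in that leaflet. A triacylglycerol is `SURF` in a
frame iff all six of its ester + glycerol oxygens lie strictly above
(TOP; below for BOTTOM) that plane; a sterol ester needs both ester
oxygens. The residence filter then removes SURF episodes shorter than
5 ns, keeping episodes censored by the trajectory boundaries; it is
idempotent by construction. Area per lipid divides the leaflet area by
either the PL count (`PL_ONLY`) or PLs plus resident SURF molecules
(`PL_PLUS_SURF`).

## Interdigitation and hydration

Mass-density profiles use fixed-width z bins; the binning conserves mass
exactly (the integral of the profile over the box equals the summed atomic
mass). The overlap parameter between the neutral-lipid and phospholipid
profiles is

ρ_ov(z) = 4 ρ_NL ρ_PL / (ρ_NL + ρ_PL)²,

defined as 0 where both vanish. The overlap distance λ_ov integrates
ρ_ov over z with the midpoint rule (Σ values·widths), which is exact for
step profiles and makes the planted-rectangle closure tests exact; for
smooth profiles it agrees with a 10× finer Riemann sum to better than
0.5%. Relative densities are species fractions of the total density inside
the overlap region. Hydration reports the water mass density (g/cm³)
either as a z profile or averaged over the core region between the two
tail planes.

## Packing defects

For each leaflet and frame a 1 Å × 1 Å grid (anchored to the box origin)
is scanned. Candidate atoms are lipid atoms above z_thr = (mean
phosphorus z) − 20 Å (mirrored for the bottom leaflet). A cell is covered
by an atom when the 2-D minimum-image distance from the cell centre to the
atom is below r_vdW + half-diagonal; the default half-diagonal is √3/2 Å,
with √2/2 Å available as the planar alternative. The cell's type is taken
from the *outermost* covering atom, except that head-group coverage always
wins. Defect cells (everything not head-covered) are clustered with
periodic 4- or 8-connectivity (`scipy.ndimage.label` plus a union-find
merge across the periodic boundaries, including the diagonal corner
wraps); the implementation is tested against a brute-force BFS flood fill.

Cluster-size statistics are fitted with ln P(N) = ln c − N/π by weighted
least squares. The default `AUTO` window is [15 Å², largest size observed
at least 10 times]. For small pooled samples whose sizes follow the
exponential law from N = 1 (the planted synthetic systems), the fit window
is instead [1, 80th percentile of the sizes]: empty and singleton tail
bins are otherwise dropped from the log fit, which flattens the slope and
was measured to bias π upward by ~20% at n ≈ 450. The standard error of
π follows from the slope error by the delta method. The sampler used to
plant sizes draws from the discretised exponential (geometric) law with
support N ≥ 1, whose exact tail is P(N ≥ t) = e^(−(t−1)/π).

## Dihedral fitting

The model is E(φ) = Σ_n k_n (1 + cos(nφ − δ_n)) with k_n ≥ 0 and
δ_n ∈ {0°, 180°}, plus a free constant offset (handled by centring the
residuals). Metropolis simulated annealing (T₀ = 5, geometric cooling
0.95, 200 steps per temperature, T_min = 10⁻⁴, k ∈ [0, 20]) perturbs one
force constant or flips one phase per step; the best-ever solution is then
polished by non-negative least squares at the best phases, which is exact
because the model is linear in k at fixed phases. On noiseless 24-point
scans the planted constants are recovered to machine precision for every
tested annealing seed.

## Synthetic generators

`generate_trilayer` builds a PL-bounded trilayer where every observable is
planted by construction: sterol axes are drawn from the axial distribution
p(u) ∝ exp(a u²) with a solved so that E[3/2 u² − 1/2] equals the target S
(the S = 1 and S = −0.5 limits are exact); ester-oxygen planes are placed
at the requested spacing; up/down assignment interleaves deterministically
to hit the requested ratio exactly; PL tail carbons are symmetric about
the tail plane so the plane and S_CD = −0.5 are exact; SURF TGs are built
with all designated oxygens above the plane; water counts realise the
requested densities exactly given the box volume.
`generate_trilayer_trajectory` adds a correlated area/interdigitation
drive (±4% area modulation) and small positional jitter.

`generate_defect_leaflet` tiles a single leaflet with 0.1 Å-radius head
markers — each covers exactly its own grid cell — and replaces planted
near-square patches with markers of the requested defect type, with at
least one clear cell between patches (largest patches placed first so the
greedy placement stays feasible). The returned inventory is therefore the
exact expected cluster census, used for oracle-style closure tests.

Because the trilayer's sparse pseudo-surface carries no realistic
head-group coverage texture, the synthetic-input pipeline measures defect
statistics on such companion defect-leaflet systems (seeds derived from
the run seed) rather than on the trilayer itself; file-based inputs are
analysed directly.

## Limitations

- Synthetic molecules are coarse pseudo-structures: correct classes,
  roles, and geometry for the planted observables, not chemically detailed
  conformers.
- The defect grid is anchored to the box origin, so defect statistics are
  exactly translation invariant only for shifts commensurate with the
  1 Å cell.
- Density-profile resolution limits layer-spacing recovery to about one
  bin width (0.1 nm by default).
- The pipeline's Pearson correlation between APL and λ_ov is computed on
  the per-frame series without decorrelation; for short synthetic
  trajectories it is a qualitative indicator only.
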