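# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic benchmarks do and do not demonstrate.

## Data model and file handling

Configurations are flat atom lists (name, element, residue id/type, group
tag, position, optional partial charge) plus an optional orthorhombic box.
Group tags (`nucleotide`, `substrate`, `water`, `ion`) are inferred from
residue names via a rule table; unknown residues default to `substrate`
with a warning (or an error in strict mode) since mineral residue naming is
not standardized. Coordinates are kept in Å throughout; GRO files are
converted from nm on read and back on write. Triclinic boxes are rejected:
every system this package targets is cubic or orthorhombic, and supporting
skewed cells would complicate the minimum-image arithmetic for no user.

File I/O is delegated to MDAnalysis. Precision consequences worth knowing:
PDB stores 3 decimals in Å and XYZ full precision, so both round-trip to
10⁻³ Å; the fixed GRO format stores nm to 3 decimals, so GRO round-trips
are quantized at 0.01 Å. XYZ carries no residue or name metadata — only
elements and positions survive that format.

Sugar-atom prime dialects (`O3'`, `O3*`, `O3′`) are normalized to the
apostrophe form on ingestion. Hydrogen attachment is resolved by name
convention first (H3T/HO3′ etc.) and by a < 1.2 Å distance fallback, so
synthetic or minimized structures without connectivity records annotate
correctly.

## Hydrogen-bond definition

A bond is a donor–H⋯acceptor triple with heavy-atom distance ≤ `da_cutoff`
and the angle between D→A and D→H ≤ `angle_cutoff`. Defaults are 3.0 Å and
20°, the conventional geometric criteria of trajectory-visualization
tooling; there is no energetic term. Intra-residue pairs are excluded.
Candidate pairs come from a periodic k-d tree with the cutoff as search
radius; correctness is defined (and tested) against an exhaustive O(n²)
enumeration over the 27 nearest periodic images, so the data structure is
an implementation detail.

"C3′–C5′ bond" is operationalized as: 3′-hydroxyl donor (O3′ with its
hydrogen) on one nucleotide, phosphate-oxygen acceptor (O5′, OP1, OP2, OP3
when present) on a different nucleotide. Carbons cannot hydrogen-bond; the
C3′/C5′ labels name the backbone positions the bond bridges. The 2′-hydroxyl
is a donor too, but its bonds to phosphates are classified `nuc_nuc_other`
— only the 3′ side counts toward the pre-polymer statistic. Whether the
bridging O5′ should count as an acceptor alongside the terminal phosphate
oxygens is a judgment call; we include it, since at the geometric level it
is an equivalent lone-pair acceptor reachable from the same approach.

Water is excluded from donor/acceptor sets: the quantities of interest are
nucleotide–nucleotide and nucleotide–substrate bonds.

## Proximity partition and summary conventions

A nucleotide is "near" the substrate when any of its atoms is within the
cutoff (default 7 Å) of any substrate atom, inclusive at the boundary —
inclusive because a strict inequality is unstable under floating point for
planted geometries, and physically indistinguishable. Distance is measured
to substrate atoms, not to an idealized plane, so stepped or rough slabs
need no special casing. A `reference_atom` mode (C3′ marker only) exists
for sensitivity checks. A bond is near only when both partner nucleotides
are near.

The bonded percentage is bonds/nucleotides × 100. One bond involves two
nucleotides, so this is not literally "the fraction of nucleotides in a
bond"; it is the conventional way such counts are quoted and is documented
wherever it is emitted. `chain_components` (connected components of the
bond graph, sizes ≥ 2) is an exploratory extension and clearly flagged as
such: per-bond counts, not chain statistics, are the primary output.

## Radial distribution function and lattice matching

g(r) uses minimum-image distances, uniform bins (default 0.1 Å to
r_max = 12 Å; peaks of interest live at 4.3–7.3 Å, so 0.1 Å gives ≥ 2-bin
separation), and 3-D shell normalization with ideal density (N−1)/V. For
quasi-2-D monolayers a 2-D normalization would change peak *heights* only;
positions, the quantitative readout, are normalization-invariant, so one
convention serves both geometries. Raw ordered-pair counts are kept on the
result for conservation checks.

Peak detection: centered moving average (default window 3 bins) followed by
local-maximum search with a prominence threshold (default 0.5). Positions
are reported at bin centers, so a delta-like lattice peak is located to
half a bin (e.g. the hexagonal |a+b| shell at 5.957 Å reports as 5.95 with
0.1 Å bins).

Lattice matching compares peak positions against the neighbor-shell
distances |i·**a** + j·**b**| of candidate unit cells; a candidate is
eligible when every peak is within tolerance (default 0.3 Å) of some
shell, and the smallest RMS residual wins, ties broken toward fewer
distinct shells. No-match is a result, not an error: an amorphous g(r)
legitimately matches nothing.

### Monolayer boxes and the oblique-cell caveat

Monolayer generators place one marker per lattice node in a periodic box.
Along the **a** direction the box is exactly commensurate. For α ≠ 90° an
orthorhombic box cannot also be commensurate along the second axis (the
accumulated row shear n_b·b·cos α is generically not a multiple of the
a-period), and naive wrapping would fabricate spurious pair distances. The
generator therefore adds a vacuum margin (default 12 Å — at least the
r_max of any subsequent pair analysis) along that axis. The cost is edge
attenuation of peak heights; positions are unaffected, which is what the
analyses read.

## Surface maps

The probe surface is a regular x–y grid at a fixed offset (default 1.4 Å,
roughly a hydrogen-bond approach distance) above the topmost substrate
atom, spanning the substrate extent. Each vertex gets the inverse-square-
distance weighted average of the site charges; weights sum to one, so
values are bounded by the charge range and tend to the plain mean far from
the slab. A 10⁻⁶ Å guard rejects vertices coinciding with a site, where
the weight diverges. Partial charges are inputs (sidecar CSV of atom
index/charge); no electronegativity-equalization charge scheme is
implemented, and the maps are interpolations, not electrostatics — no
Coulomb sums, no solvent screening.

## Dehydration schedule

Counts interpolate linearly (optionally geometrically) between the
endpoints, rounded to integers with strict monotonicity enforced, endpoints
exact. Defaults are 12,500 → 600 waters in 10 steps around 200 nucleotides
(62.5 → 3.0 waters per nucleotide; the last step is 4.8% hydration).
Linear-in-count is a choice, not a measurement: the true per-step counts of
any particular study are rarely published, and linear reproduces the
endpoints and the usual intermediate-snapshot labels to within rounding.

## Droplet model

All formulas are the printed closed forms evaluated with SI bookkeeping
(radius accepted in μm at the interface): Stokes terminal velocity,
t_fall = H/v_t, t_life = 2r²/(q₀ΔT), volume (4/3)πr³, and the crossing
radius r\* = (9ηHq₀ΔT / 4g(ρ_water−ρ_air))^¼, cross-checked against a
bisection root of t_fall − t_life to 10⁻⁶ relative. Defaults: H = 5 m,
ΔT = 6.1 °C and q₀ = 89.84 μm²s⁻¹K⁻¹ (20 °C, 50% RH), η = 1.81×10⁻⁵ Pa·s,
ρ_water = 998, ρ_air = 1.204 kg/m³ (standard 20 °C air). The ν appearing
in some statements of the Stokes drag is treated as the dynamic viscosity
η. Known discrepancy, documented rather than patched: with these constants
the lifetime formula gives t_life(r = 100 μm) = 36.5 s and a crossing at
r\* ≈ 58 μm (t ≈ 12 s), whereas discussions of this regime often quote
"~100 s" lifetimes for ~100 μm droplets — a figure the printed formula and
constants do not reproduce (it would require, e.g., reading r as a
diameter or different ambient constants). This package follows the
formulas. No Cunningham slip, humidity-dependent q₀, or non-Stokes drag.

## Synthetic generators and what passing tests show

Generators are pure functions of (spec, seed); reruns are bitwise
identical. Nucleotides are reduced to the annotated interaction atoms
(O3′/H3T, phosphate, C3′/C5′ markers) laid out as a planar fragment; base
donor/acceptor sites are exercised through dedicated classification
fixtures instead of the packed systems. Planted-bond systems realize the
donor geometry exactly at (bond_distance, bond_angle) and keep every other
inter-nucleotide donor–acceptor distance beyond the detection cutoff plus
a 1 Å guard band (inclusive boundaries throughout), verified during
placement by rejection sampling against all previously placed atoms; a
packing that cannot satisfy the margins within the attempt budget raises
rather than degrades.

These systems validate the *machinery* — detection geometry, periodic
wrapping, classification, counting, normalization — with exact expected
answers. They do not emulate real dried nucleotide layers: there is no
thermal disorder beyond optional jitter, no water competing for bonds, no
realistic nucleotide conformations, and the bond-count ramp across a
synthetic dehydration series is imposed, not emergent. Passing tests
therefore certify that a given structure's bonds are counted correctly,
not that any particular substrate promotes or inhibits bonding.

The end-to-end pipeline (`run-all`) analyses either synthetic series or
user files. In synthetic mode water molecules are not placed explicitly —
the analyses exclude water by design, so hydration enters through the
schedule metadata and the planted-bond ramp. Problem sizes in the test
suite and reference script (20×20 monolayers, ≤ 200 nucleotides, ≤ 500-atom
brute-force comparisons) were chosen so every expected value is computable
by independent enumeration; all headline behaviors are already exact at
these sizes and larger systems add nothing but runtime.

## Numerical choices, degenerate inputs

- Minimum image via nearest-integer rounding per axis; property-tested
  against exhaustive 27-image search.
- Inclusive (≤) comparisons at every planted or physical boundary.
- Empty inputs are results where meaningful (empty bond list → zero
  counts; flat g(r) → no peaks; no substrate → all nucleotides far) and
  errors where the quantity is undefined (< 2 RDF atoms, zero nucleotides
  in a summary, r_max beyond half the box).
- Seeds: every stochastic generator takes one; derived seeds stay below
  2³¹.

## Known limitations

Orthorhombic boxes only; no binary trajectory formats (XTC/DCD); no bond
energetics or lifetimes; no automatic unit-cell search beyond a candidate
list; surface maps are not electrostatics; the droplet model is the
laminar-Stokes idealization.
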