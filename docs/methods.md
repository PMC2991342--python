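# Methods

## Fragment-based peptide assembly

A peptide ligand is assembled by concatenating rigid coordinate templates:
one beginning cap (a single hydrogen bonded to the first backbone nitrogen,
giving a neutral amine terminus), one end cap (a hydroxyl oxygen and its
hydrogen completing the carboxyl at the final backbone carbon), a
five-atom backbone fragment (N, amide H, CA, C, carbonyl O) in two
orientations, and one side-chain fragment per standard residue in two
orientations — 44 templates in all. Neutral termini are used throughout;
ionized NH3+/COO− forms are deliberately not generated, and fragments carry
polar hydrogens only (N–H, O–H, S–H) plus the caps and glycine's single
side-group hydrogen, matching the polar-hydrogen united-atom convention of
grid-based docking engines.

Because no published fragment geometry exists, the templates are generated
from idealized internal coordinates: peptide C–N 1.33 Å, N–CA 1.46 Å,
CA–C 1.52 Å, C=O 1.23 Å, N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å, aromatic edges
1.37–1.40 Å. The backbone is a planar extended zig-zag in the fragment
xy-plane (bond directions alternating ±30° about the chain axis, the
extended-conformation stand-in); side chains grow out of the backbone plane
along +z, with tetrahedral zig-zags for aliphatic stems, symmetric ±y splay
for branch pairs (valine methyls, carboxylates, amides, guanidinium), and
regular polygons for rings. CB leaves CA perpendicular to the backbone
plane, which keeps it equidistant from the flanking N and C whichever
parity the residue lands on. Generation is seed-free and byte-reproducible.

**Orientation.** "Up" means the side chain extends toward +z; the down
fragment is the exact reflection of the up fragment through the backbone
plane (z → −z). Odd-numbered residues (1-based) use up, even use down, so
neighboring side chains never crowd the same face. The two backbone files
differ by a y-reflection instead — that is the zig-zag phase, and chaining
up/down/up… files by pure translation reproduces a consistent extended
backbone. Proline is the one residue whose side-chain fragment embeds the
backbone (N, CA, C, O plus the CB–CG–CD ring closing onto N, with no amide
H); at even positions the builder applies the y-reflection to it, which
together with the file's z-reflection is a 180° rotation about the chain
axis, so chirality is preserved there. For the other side chains the
z-mirrored file is itself the correct even-parity placement; the templates
carry no CA hydrogen, so no stereocenter is inverted, and D/L chirality is
simply not modeled (a known limitation).

The proline ring is puckered — CG is pushed out of the N/CA/CB/CD plane —
both because real proline rings pucker and because ring planarity is the
criterion the atom typer uses to distinguish aromatic rings.

**Joining.** Every fragment records which atom bonds to the previous
fragment (`attach_in`), which bonds to the next (`attach_out`), and the
local-frame vector from attach_out to the next attach_in (the ideal peptide
bond). Side-chain frames are CA-relative, so placement is a translation to
the residue's CA. Assembly is therefore exact: bonded distances in the
built structure equal the template values by construction.

## Steric relaxation

The optimizer minimizes a pure clash objective,
U = Σ max(0, d₀ − d_ij)² over atom pairs separated by at least three bonds,
with d₀ = 2.0 Å (just under twice a carbon van-der-Waals-ish contact;
1-4 pairs in the extended build sit at 2.4–2.9 Å, so a clash-free build
scores exactly zero). Rotatable torsions are found from the inferred bond
graph: acyclic heavy-atom bonds whose distal side contains at least two
atoms and no backbone atoms — i.e. side-chain χ angles; proline's ring
bonds are excluded automatically because they are not graph bridges. The
search is greedy coordinate descent: sweep the torsions in a fixed order,
for each evaluate a 30° grid and refine ±25° in 5° steps, accept only
strict improvements, stop when a sweep improves nothing (at most 200
sweeps). Rotations about bonds leave all bonded distances and angles
untouched, so only dihedrals move. The procedure is deterministic by
construction — `BuildOptions.random_seed` is part of the contract and is
reserved for substitute optimizers plugged in through the `optimizer` hook
(e.g. an external conformer generator); the built-in search never consumes
randomness. The objective is steric only: this is clash removal, not a
physical force-field minimization, and the docking engine's flexible-ligand
search is expected to do the real conformational work downstream.

Bond inference uses distance cutoffs (heavy–heavy < 1.95 Å, hydrogen–heavy
< 1.45 Å, never H–H), valid for the idealized template geometry this
package builds; it is not a general-purpose perception algorithm for
arbitrary input structures.

## Grid parameter preparation

A template GPF needs only `npts` (three even integers), `spacing` (Å) and
`gridcenter`; the box edge is npts × spacing per axis. Preparation keeps
every template line verbatim except `receptor`, `ligand_types` and `map`
lines, which it owns and rewrites — making it idempotent — and appends the
receptor path, the ligand's docking atom types, and one affinity-map line
per type. Typing is element-based: C→C, N→N, O→OA, S→SA; carbons in flat
five- or six-membered C/N rings (max 0.1 Å deviation from the best-fit
plane) become the aromatic type A, which the puckered proline ring
correctly fails. Hydrogens bonded to N/O/S are the donor type HD; hydrogens
on carbon contribute no map type at all, per the united-atom convention in
which nonpolar hydrogens carry no affinity map. Partial charges and the
affinity maps themselves are out of scope — they belong to the docking
tool chain.

## Campaigns and the mock backend

The job matrix is the full cross-product of ligands × receptors × grid
boxes, job ids 1..N in ligand-major order, each defaulting to **100
docking runs** (the accuracy/speed compromise standard for this kind of
screen) and a **10-second** status-poll interval. Statuses move only along
created → queued → running → complete/failed; a failure is recorded on the
job and never propagates to its siblings, and serial execution order
defines the observable outputs.

A backend is anything implementing
`run(ligand_path, receptor_path, gpf_path, n_runs, output_dir) →
BackendResult`. The mock backend draws per-run energies from a seeded
normal distribution (mean −7.0, sd 1.5 kcal/mol — a typical peptide
docking-score range) or takes an explicit energy list, computes
K_i = exp(ΔG·1000/(R·T)) with R = 1.987 cal·mol⁻¹·K⁻¹ and T = 298.15 K,
and translates the ligand rigidly to a uniform-random centroid inside the
grid box. Energies are printed to 7 decimals and K_i to 10 significant
figures so the thermodynamic identity survives the print/parse round trip
to better than 1e-6 in ln K_i; the parser still accepts the coarser
precision ("39.87 uM") of real logs, normalizing mM/uM/µM/nM/pM (and M)
case-insensitively to molar.

What the mock emulates — run counts, score bookkeeping, file formats, pose
placement inside the box — is exactly what campaign management and result
analysis consume. What it does not emulate: any relationship between pose
geometry and energy, clustering structure in pose space, or receptor
chemistry. Tests passing against the mock therefore validate orchestration
and analysis, not docking accuracy.

**Competitive binding.** After ligand A's job completes, its rank-1
(lowest-energy) conformation — ties broken toward the lower run index — is
appended to the receptor as the next free chain letter with residue numbers
continuing past the receptor's, and the secondary ligand is docked against
the merged complex. The second job reuses the first job's grid-box
template; recentering on the bound pose is left to the user providing a
different template.

## Result analysis

Ranking is a stable ascending sort on energy with the run-index tie-break;
ranks are 1..n. Clustering walks poses best-first and joins the first
cluster whose *seed* pose is within the RMSD tolerance (default 2.0 Å, a
conventional pose-clustering radius), else founds a new cluster; RMSD is
plain coordinate RMSD without superposition, since all poses from one
docking log share the receptor frame. Raising the tolerance can only merge,
never split, so cluster count is non-increasing in tolerance.

Secondary-box screening calls a run "inside" iff its pose's unweighted atom
centroid lies within the closed box volume (a centroid exactly on a face
counts as inside — the boundary-stable reading). Best and mean energy and
K_i are computed over the inside runs only, because the point of the screen
is to characterize binding at the putative site; when no run is inside the
statistics are left unset and flagged rather than silently computed over
everything. All-atom containment would be a stricter alternative reading;
centroid containment was chosen as the least surprising one.

## Problem sizes and numerical notes

The test suite and the acceptance script work at the scale the toolkit is
designed for: pentapeptide ligands (≈ 60 atoms), campaigns of five jobs,
100 runs per job, clustering fixtures of ≤ 12 poses — everything runs in
seconds. Floating-point notes: PDB coordinates quantize to 0.001 Å, so
round-trip tests allow 0.0005 Å; the optimizer accepts improvements only
beyond 1e-12 to avoid cycling on ties; box containment uses a 1e-12
closed-bound epsilon.

## Known limitations

- Extended-conformation builds with a steric-only optimizer: starting
  structures are clash-free, not energy-minimized, and no disulfide bonds,
  cyclization, charges, or D-amino acids are modeled.
- Atom typing has no general aromaticity perception beyond the flat-ring
  test and covers H/C/N/O/S only.
- The PDB reader targets the fixed-column ATOM/HETATM subset (no altlocs,
  insertion codes, or mmCIF).
- The in-process job tracker runs jobs serially; cluster schedulers and
  remote execution are out of scope by design (the backend protocol is the
  extension point).
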