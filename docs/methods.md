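# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic fixtures do and do not emulate,
and the known limitations.

## Structure model and conventions

Structures are parsed with gemmi (PDB and mmCIF) into a flat
chain → residue → atom model. Author residue numbering is canonical
throughout because the polymerase literature cites author numbers
(D404, E580, K464, …); mmCIF label numbering is not used for lookups.
Entity classes — protein, dna, water, metal, dntp_ligand, other — are
assigned per residue from name tables plus atom-content heuristics
(triphosphate atom names PA/PB/PG or O1A…O3G mark a dNTP-like ligand; a
single metallic atom marks a metal). Every residue gets exactly one
class; unmatched residues become "other".

Alternate conformers: all are parsed, but every geometry stage runs on a
pruned model keeping the highest-occupancy conformer per atom name
(tie → altloc A), because distance-based classification must be
single-valued. Direct B-factor lookup on an atom with several altlocs is
an error unless the altloc is named — silent ambiguity would make the
reported value meaningless. Hydrogens, when present, are stripped before
any distance computation: the deposited structures carry none, and
uniformity matters more than the occasional neutron/predicted model.

## Superposition

Cα pairs come from a global alignment of one-letter sequences
(Biopython PairwiseAligner, BLOSUM62, gap open −10, gap extend −0.5 — the
defaults of the molecular viewer conventionally used for such numbers).
Pair counts depend on these parameters, so they are reported alongside
every result. Multi-chain proteins are paired greedily by best alignment
score; the polymerases here are single-chain.

The rigid fit is the closed-form Kabsch SVD solution with the usual
determinant correction; near-collinear point sets are rejected because
the rotation about the line is undetermined. Outlier rejection iterates
up to 5 cycles: fit, compute per-pair deviations, drop pairs with
deviation > 2.0 × current RMSD, refit; it stops early when nothing is
rejected. The reported RMSD covers surviving pairs only, matching the
"RMSD over N Cα atoms" convention. The test suite checks the fit against
an independent quaternion (Kearsley eigenvalue) oracle to 1e-6 Å on small
point sets.

## Domain model

Domain boundaries (N-terminal, exonuclease with its β-hairpin, finger,
palm, thumb) are configuration, not computation: no deposited polymerase
entry prints them, so the package ships implementer-derived defaults for
the archaeal numbering (palm split 369–449 + 531–588 around the finger
450–530, consistent with the catalytic aspartates D404/D542 and the
triphosphate-binding finger residues R460–S492). Users override them in
YAML, and every domain-dependent output echoes the ranges used. Pair
counts for domain-restricted RMSDs are therefore approximate targets.

## Closure angle

The mobile (finger) domain's rotation is measured on the whole
mobile-domain Cα set by default: core = all protein residues outside the
mobile domain, refined superposition on the core, Kabsch fit of the
core-superposed mobile Cαs, angle from arccos((tr R − 1)/2), axis from
the skew-symmetric part. Restricting to particular helices is possible
through the domain config but not the default, since whole-domain
measurement is better conditioned; published closure angles measured by
eye on two helices can differ by a couple of degrees, hence the ±3°
comparison tolerance used for deposited entries.

## Hydrogen-bond fingerprints

Classification is purely by heavy-atom distance — strong [2.2, 3.2] Å
inclusive, weak (3.2, 4.0] Å, below 2.2 Å a clash, not a bond — with no
donor-H angle term (no hydrogens in the data). An epsilon of 1e-6 Å
protects the inclusive boundaries from float rounding, so a pair built at
exactly 3.200 Å classifies as strong. Donor/acceptor role compatibility
is still enforced from per-residue tables (20 amino acids, 4
deoxyribonucleotides, water, triphosphate oxygens) to suppress
acceptor–acceptor artifacts such as carboxylate-O···phosphate-O.

Water bridges run through exactly one bridging water: for each water
oxygen with at least one protein polar partner and one DNA/dNTP polar
partner in range, one record per (protein atom, water, partner atom)
triple. The bridge class is the class of the weaker (longer) leg — a
chain is as strong as its weakest link; chains through two waters are
never bridges.

Moiety tables are fixed Watson–Crick edge assignments: purine N3/C2/N2 to
the minor groove, N7/O6/N6 to the major groove, N1 the WC edge;
pyrimidine O2 minor, O4/N4/C5-methyl major, N3 WC. Phosphate-group atoms
(P, OP1/OP2, O3′, O5′) are backbone; O4′ is kept as its own category
because it is a distinct acceptor presented in the minor groove; the
sugar carbons form a "sugar" category so every heavy atom maps somewhere.
Triphosphate oxygens map to α/β/γ by their bonded phosphorus (bridging
O3A with α, O3B with β); the ligand O3′ is the 3′-OH.

Strand positions are anchored at the templating base: the dNTP's
base-paired template residue is t(0), found as the template residue whose
base centroid lies nearest the ligand's base centroid (in paired
geometry this distance is well below the stacked-neighbor distance).
Template indices decrease toward the duplex/3′ end and increase toward
the 5′ overhang; the primer 3′ terminus is p(0), decreasing toward 5′.
The primer strand itself is recognised as the DNA chain whose 3′-terminal
O3′ abuts the ligand's α-phosphorus. Strand order (5′→3′) is derived
from O3′(i)–P(i+1) connectivity with a fall-back to sequence numbering.

Ring–sugar stacking (aromatic side-chain ring centroid within 4.5 Å of a
deoxyribose centroid) is recorded as a separate non-hydrogen-bond
contact. Published contact totals do not say whether they count distinct
atom pairs or distinct residue–moiety contacts, so `count_contacts`
reports either (`distinct="records"` / `"residue_moiety"`).

## Metal sites

Ligands are N/O atoms within 2.6 Å of the metal (covers Mg–O ≈ 2.1 and
Mn–O ≈ 2.2 while excluding hydrogen-bond range; per-element overrides are
accepted). Ligand kind is derived from the atom, not the residue: a
backbone O on any residue is a backbone-carbonyl ligand even when a
figure legend names the residue. Octahedricity is the mean absolute
deviation of inter-ligand angles from the octahedral ideals, with pairs
above 135° scored against 180° (trans) and the rest against 90° (cis);
it is 0 for a perfect octahedron and grows monotonically with angular
jitter. Site labels follow the canonical two-metal-plus-one picture:
B must bridge α-, β- and γ-phosphate oxygens; A contacts the α-phosphate
(nearest the primer 3′ terminus when several do); C contacts the
γ-phosphate only; everything else stays unassigned. The second shell
lists polar protein atoms within 2.2–3.5 Å of each water ligand.

## Channel volumes

The two-probe computation rasterises atoms (Bondi radii) onto a cubic
grid (0.5 Å default) padded by the large probe. For a probe r, the
accessible region is every voxel center at least r_atom + r from all
atom centers; the excluded (molecular) region is the complement of that
region dilated back by r — the standard rolling-probe closure, computed
with a Euclidean distance transform.

Two probe semantics are combined deliberately. The large-probe (7.0 Å)
envelope treats probe-unreachable pockets as interior: the accessible
region is first restricted to its boundary-connected component
(6-connected flood fill), so the envelope is what a large sphere rolled
from outside can delimit. The subtracted small-probe (2.7 Å) body is the
plain closure without the reachability constraint, so a cavity sealed
against the small probe survives the subtraction and is reported as a
component. The channel mask is then
`excluded(big, sealed) ∧ ¬excluded(small, plain) ∧ ¬(inside atoms)`,
labelled with 26-connectivity; components below 100 Å³ are dropped as
grid noise. Volumes are voxel count × spacing³.

By default only protein atoms are gridded (waters, ions, DNA and the
ligand excluded) so channels that run along the DNA and around the
triphosphate stay open; a selection flag adds other entities. Components
are annotated with their minimum distance to DNA and dNTP atoms;
components farther than 5 Å from both are flagged "outer". Reproduction
of published volumes computed with other grid tools carries a ±15%
tolerance (different radii tables, grid phase and atom selections).

Discretisation accuracy: volumes converge under spacing halving to <3%
on the shell fixtures; the grid volume of a sphere-equivalent region
carries a quantisation uncertainty modelled as √N_boundary × voxel
volume, which is combined with the Monte-Carlo σ when the tests compare
grid volumes against rejection-sampling oracles.

## Synthetic fixtures

The generators produce standard PDB files (so tests exercise the real
parser) with 3-decimal coordinates, deterministic per seed, each with a
machine-readable ground-truth JSON:

* hydrogen-bond sets: axis-aligned pairs at exact prescribed distances,
  one isolated 30 Å-spaced site per pair, so rounding cannot shift a
  boundary case;
* water bridges with prescribed leg distances, optionally chained
  through two waters as a negative control;
* an idealized primer/template duplex (11-nt primer, 16-nt template, the
  crystallisation sequences) built on fiber-model steps (rise 3.38 Å,
  twist 36°) with correct atom naming, a dATP-like DTP ligand abutting
  the primer 3′ end, and protein pseudo-residues placed per contact
  plan. The geometry supports naming, strand indexing and distance
  tests; it is not a claim about real DNA geometry, so passing tests
  show bookkeeping correctness, not force-field realism;
* hollow Fibonacci-lattice shells around cavities of analytic volume
  ((4/3)πr³), dense enough that neither probe slips between shell atoms,
  with an optional sub-probe pore;
* open/closed pseudo-protein pairs related by a known rigid rotation of
  a mobile residue range, with optional isotropic Gaussian noise;
* ideal and angularly jittered octahedral metal sites, and a
  three-metal triphosphate arrangement exercising the A/B/C labels and
  the second shell.

What the fixtures do not emulate: real side-chain chemistry and packing,
crystallographic disorder, solvent structure beyond placed bridge
waters, and realistic domain architecture. Deposited-entry comparisons
therefore remain a separate test tier that requires the entries on disk.

## Problem sizes and defaults

The shipped test and acceptance runs use a 60-residue pseudo-protein
(30-residue mobile domain), 20 noise seeds at σ = 0.3 Å for closure
recovery, 220-atom shells at 0.5 Å spacing (0.25 Å for the convergence
check), and 10⁶-point Monte-Carlo oracles — sizes chosen so each oracle's
own uncertainty is far below the tolerance it guards.

## Known limitations

* Sequence-alignment pairing means pair counts can shift by a few
  residues with alignment parameters; identity fractions are reported,
  not hard-asserted.
* Distance-only hydrogen bonds over-count relative to angle-aware
  definitions in crowded sites; this mirrors the distance-classed
  convention the fingerprints reproduce.
* The t(0) anchor requires a bound nucleotide; apo or binary complexes
  cannot be position-indexed (by design — there is no templating
  position without an incoming dNTP).
* Channel volumes depend on the atom selection; the default
  (protein-only) is stated in every output and is a modelling choice,
  not a property of the structures.
* Metal site labelling assumes a triphosphate is present; metals in
  exonuclease or surface sites stay "unassigned".
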