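# polprofiler

Comparative structural profiling of DNA-polymerase ternary complexes
(polymerase · primer/template DNA · incoming dNTP), built for the kind of
questions raised by the archaeal B-family enzymes (KOD, 9°N) and their
comparators (pol δ, RB69, KlenTaq): how similar are two polymerase folds,
how far does the finger domain close on dNTP binding, which protein
residues grip the DNA and the triphosphate and how strongly, how are the
active-site metals coordinated, and how much internal channel volume could
accommodate modified nucleotides.

## What it computes

* **Superposition / RMSD** — Cα pairs from a global sequence alignment
  (BLOSUM62, gap open −10, extend −0.5), closed-form Kabsch fit, then
  iterative outlier rejection (drop pairs deviating more than
  `cutoff_rms × RMSD`, default cutoff 2.0, 5 cycles). Reported as
  "RMSD over N Cα atoms" on the surviving pairs.
* **Domain closure** — superpose open and closed structures on the core
  (all protein residues outside the mobile domain), rigid-fit the mobile
  Cα set, and read the residual rotation: θ = arccos((tr R − 1)/2).
  Per-residue Cα displacements come from the same core frame.
* **Hydrogen-bond fingerprints** — heavy-atom, distance-classed bonds
  between protein N/O/S and DNA/dNTP N/O: direct strong 2.2–3.2 Å
  (inclusive), direct weak >3.2–4.0 Å, sub-2.2 Å flagged as clashes;
  single-water bridges classed by their weaker leg. Each bond is mapped to
  a DNA moiety (phosphate backbone, sugar, minor/major-groove or
  Watson–Crick base edge, α/β/γ-phosphate) and a strand position anchored
  at the templating base t(0).
* **Metal sites** — coordination spheres within 2.6 Å, ligand kinds,
  octahedricity (mean |deviation| of inter-ligand angles from 90°/180°),
  and canonical site labels: B bridges the α-, β- and γ-phosphates, A sits
  on the α-phosphate by the primer 3′ terminus, C contacts the γ-phosphate
  only.
* **Channel volumes** — a two-probe voxel computation: interior of the
  large-probe (7.0 Å) excluded surface minus the small-probe (2.7 Å)
  molecular body, 26-connected components reported in Å³.

A synthetic-fixture generator (`polprofiler.fixtures`) produces PDB files
with machine-readable ground truth for every stage — prescribed
donor–acceptor distances, water bridges, an idealized primer/template
duplex with a dATP-like triphosphate, octahedral metal sites, hollow
shells of analytic cavity volume, and open/closed pairs related by a known
domain rotation — so the entire pipeline is testable offline.

## Worked example

```python
from polprofiler import fixtures as fx
from polprofiler.conformation import domain_rotation
from polprofiler.domain_model import load_domain_map

open_s, closed_s, truth = fx.make_rotation_pair(24.0, noise_sigma=0.3, seed=0)
dmap = load_domain_map({"domains": {
    "helix": {"finger": [["A", 31, 60]]},
    "helix_closed": {"finger": [["A", 31, 60]]}}})
rep = domain_rotation(open_s, closed_s, dmap, mobile="finger")
print(f"closure angle: {rep.angle:.2f} deg, core RMSD {rep.core_rmsd:.2f} A")
```

prints

```
closure angle: 23.46 deg, core RMSD 0.53 A
```

i.e. the 24° rotation planted by the generator is recovered to within the
0.3 Å coordinate noise, and the core (non-mobile) residues superpose at
the noise level. The same stages run from the shell:

```sh
polprofiler inspect structure.pdb
polprofiler superpose A.cif B.cif --domain palm
polprofiler fingerprint complex.pdb --tsv-out records.tsv
polprofiler metals complex.pdb
polprofiler channels complex.pdb --big 7.0 --small 2.7
polprofiler closure open.cif closed.cif --mobile finger
polprofiler run config.yaml
```

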