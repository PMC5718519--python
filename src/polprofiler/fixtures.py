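"""Synthetic PDB fixtures with machine-readable ground truth.

Every pipeline stage can be exercised without downloading deposited
structures: donor-acceptor pairs at prescribed distances (with or without
bridging waters), an idealized primer/template duplex with a triphosphate
ligand and a protein contact plan, octahedral metal sites, hollow shells of
analytic cavity volume, and open/closed pairs related by a known rigid
domain rotation.

Fixtures are written as standard PDB files so they exercise the real
parser.  Coordinates are rounded to 3 decimals (PDB precision) before any
ground truth is computed, generation is deterministic given the seed, and
every generator returns (Structure, ground-truth dict).

The duplex uses fixed fiber-model step parameters (rise 3.38 A, twist 36
deg); its geometry is sufficient for atom naming, strand indexing and
contact tests, not for real-DNA geometry claims.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .structure_io import Atom, Residue, Structure, classify_entities, \
    write_pdb

RISE = 3.38
TWIST = 36.0
R_C1 = 5.9
C1_HALF_ANGLE = 63.5
R_BACKBONE = 8.9
PSI_OFFSET = 15.0


class FixtureError(ValueError):
    pass


def _atom(serial: int, name: str, element: str, pos, b: float = 10.0,
          occ: float = 1.0, altloc: str = "") -> Atom:
    return Atom(serial=serial, name=name, element=element,
                coords=np.round(np.asarray(pos, dtype=float), 3),
                occupancy=occ, b_factor=b, altloc=altloc)


def write_fixture(structure: Structure, truth: dict, outdir: str | Path,
                  name: str) -> tuple[Path, Path]:
    """Write <name>.pdb plus <name>.json ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pdb_path = outdir / f"{name}.pdb"
    truth_path = outdir / f"{name}.json"
    write_pdb(structure, pdb_path)
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return pdb_path, truth_path


# ---------------------------------------------------------------------------
# H-bond distance fixtures
# ---------------------------------------------------------------------------

_ROLE_RESIDUES = {
    "donor": ("LYS", "NZ", "N"),
    "acceptor": ("ASP", "OD1", "O"),
    "both": ("SER", "OG", "O"),
}


def make_hbond_fixture(distances: list[float],
                       roles: list[str] | None = None
                       ) -> tuple[Structure, dict]:
    """Isolated protein-atom / DNA-phosphate pairs at exact distances.

    Each pair sits on its own 30 A-spaced site along x, axis-aligned so the
    prescribed distance survives PDB coordinate rounding exactly.  ``roles``
    selects the protein partner per pair: donor (LYS NZ), acceptor
    (ASP OD1) or both (SER OG); the DNA partner is always a phosphate OP1
    (acceptor).
    """
    if any(not 0 < d < 10 for d in distances):
        raise FixtureError("distances must lie in (0, 10) A")
    roles = roles or ["both"] * len(distances)
    if len(roles) != len(distances):
        raise FixtureError("one role per distance required")
    s = Structure(id="hbond_fixture")
    serial = 0
    truth_pairs = []
    for i, (d, role) in enumerate(zip(distances, roles)):
        x0 = 30.0 * i
        resn, fname, felem = _ROLE_RESIDUES[role]
        prot = Residue("A", i + 1, resn)
        serial += 1
        prot.atoms.append(_atom(serial, "N", "N", (x0 - 3.5, 0, 0)))
        serial += 1
        prot.atoms.append(_atom(serial, "CA", "C", (x0 - 2.0, 0, 0)))
        serial += 1
        prot.atoms.append(_atom(serial, fname, felem, (x0, 0, 0)))
        s.residues.append(prot)
        dna = Residue("B", i + 1, "DT")
        serial += 1
        dna.atoms.append(_atom(serial, "OP1", "O", (x0 + d, 0, 0)))
        serial += 1
        dna.atoms.append(_atom(serial, "P", "P", (x0 + d + 1.6, 0, 0)))
        serial += 1
        dna.atoms.append(_atom(serial, "OP2", "O", (x0 + d + 2.2, 2.2, 0)))
        serial += 1
        dna.atoms.append(_atom(serial, "O5'", "O", (x0 + d + 3.0, -2.4, 0)))
        s.residues.append(dna)
        compatible = not (role == "acceptor")  # OP1 only accepts
        if d < 2.2:
            klass = "clash"
        elif d <= 3.2:
            klass = "strong" if compatible else "none"
        elif d <= 4.0:
            klass = "weak" if compatible else "none"
        else:
            klass = "none"
        truth_pairs.append({"distance": d, "role": role, "class": klass})
    truth = {
        "kind": "hbond_set",
        "pairs": truth_pairs,
        "n_strong": sum(p["class"] == "strong" for p in truth_pairs),
        "n_weak": sum(p["class"] == "weak" for p in truth_pairs),
        "n_clash": sum(p["class"] == "clash" for p in truth_pairs),
    }
    return classify_entities(s), truth


def make_water_bridge_fixture(legs: list[tuple[float, float]],
                              chain_two_waters: bool = False
                              ) -> tuple[Structure, dict]:
    """Protein-water-phosphate bridges with prescribed leg distances.

    With ``chain_two_waters`` each site instead carries a two-water chain
    protein-w1-w2-DNA (no single-water bridge must be reported).
    """
    s = Structure(id="water_bridge_fixture")
    serial = 0
    truth_bridges = []
    wat_index = 1000
    for i, (l1, l2) in enumerate(legs):
        x0 = 40.0 * i
        prot = Residue("A", i + 1, "SER")
        serial += 1
        prot.atoms.append(_atom(serial, "N", "N", (x0 - 3.5, 0, 0)))
        serial += 1
        prot.atoms.append(_atom(serial, "CA", "C", (x0 - 2.0, 0, 0)))
        serial += 1
        prot.atoms.append(_atom(serial, "OG", "O", (x0, 0, 0)))
        s.residues.append(prot)
        if chain_two_waters:
            positions = [x0 + l1, x0 + l1 + 2.8]
            dna_x = x0 + l1 + 2.8 + l2
        else:
            positions = [x0 + l1]
            dna_x = x0 + l1 + l2
        for wx in positions:
            wat_index += 1
            water = Residue("W", wat_index, "HOH")
            serial += 1
            water.atoms.append(_atom(serial, "O", "O", (wx, 0, 0)))
            s.residues.append(water)
        dna = Residue("B", i + 1, "DT")
        serial += 1
        dna.atoms.append(_atom(serial, "OP1", "O", (dna_x, 0, 0)))
        serial += 1
        dna.atoms.append(_atom(serial, "P", "P", (dna_x + 1.6, 0, 0)))
        serial += 1
        dna.atoms.append(_atom(serial, "OP2", "O", (dna_x + 2.2, 2.2, 0)))
        s.residues.append(dna)
        if chain_two_waters:
            truth_bridges.append({"legs": [l1, l2], "class": "none"})
        else:
            c1 = "strong" if l1 <= 3.2 else ("weak" if l1 <= 4.0 else None)
            c2 = "strong" if l2 <= 3.2 else ("weak" if l2 <= 4.0 else None)
            if c1 is None or c2 is None:
                klass = "none"
            elif c1 == c2 == "strong":
                klass = "strong"
            else:
                klass = "weak"
            truth_bridges.append({"legs": [l1, l2], "class": klass})
    truth = {
        "kind": "water_bridge",
        "bridges": truth_bridges,
        "n_bridges": sum(b["class"] != "none" for b in truth_bridges),
    }
    return classify_entities(s), truth


# ---------------------------------------------------------------------------
# B-DNA-like duplex with triphosphate ligand
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

_BASE_2D = {
    "A": {"N9": (0.0, 0.0), "C8": (0.7, 1.2), "N7": (2.0, 1.3),
          "C5": (2.4, 0.0), "C4": (1.3, -0.8), "N3": (1.5, -2.1),
          "C2": (2.8, -2.6), "N1": (3.9, -1.9), "C6": (3.7, -0.5),
          "N6": (4.8, 0.3)},
    "G": {"N9": (0.0, 0.0), "C8": (0.7, 1.2), "N7": (2.0, 1.3),
          "C5": (2.4, 0.0), "C4": (1.3, -0.8), "N3": (1.5, -2.1),
          "C2": (2.8, -2.6), "N1": (3.9, -1.9), "C6": (3.7, -0.5),
          "O6": (4.8, 0.3), "N2": (3.0, -3.8)},
    "T": {"N1": (0.0, 0.0), "C2": (1.2, -0.7), "O2": (1.2, -2.0),
          "N3": (2.5, 0.0), "C4": (2.6, 1.4), "O4": (3.7, 2.0),
          "C5": (1.4, 2.1), "C7": (1.4, 3.6), "C6": (0.2, 1.4)},
    "C": {"N1": (0.0, 0.0), "C2": (1.2, -0.7), "O2": (1.2, -2.0),
          "N3": (2.5, 0.0), "C4": (2.6, 1.3), "N4": (3.8, 1.9),
          "C5": (1.4, 2.0), "C6": (0.2, 1.4)},
}


def _pol(r: float, angle_deg: float, z: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([r * math.cos(a), r * math.sin(a), z])


def _nucleotide_atoms(base: str, rung: int, side: float, direction: int,
                      serial_start: int) -> tuple[list[Atom], int]:
    """All atoms of one nucleotide.

    ``side`` is +1 (template) or -1 (primer); ``direction`` +1 if the
    3'-neighbor sits on the next rung, -1 if on the previous one.
    """
    phi = rung * TWIST
    z = rung * RISE
    alpha = phi + side * C1_HALF_ANGLE
    psi = alpha + PSI_OFFSET
    serial = serial_start
    atoms: list[Atom] = []

    def add(name: str, element: str, pos) -> None:
        nonlocal serial
        serial += 1
        atoms.append(_atom(serial, name, element, pos))

    add("P", "P", _pol(R_BACKBONE, psi, z - direction * 0.8))
    add("OP1", "O", _pol(R_BACKBONE + 1.0, psi + 6, z - direction * 0.8))
    add("OP2", "O", _pol(R_BACKBONE + 0.5, psi - 8, z - direction * 1.6))
    add("O5'", "O", _pol(R_BACKBONE, psi, z - direction * 0.4))
    add("C5'", "C", _pol(8.3, alpha + 12, z + 0.6))
    add("C4'", "C", _pol(7.5, alpha + 6, z + 1.0))
    add("O4'", "O", _pol(6.5, alpha + 8, z + 0.8))
    add("C3'", "C", _pol(7.8, alpha - 4, z + 0.2))
    add("C2'", "C", _pol(6.8, alpha - 6, z - 0.5))
    add("C1'", "C", _pol(R_C1, alpha, z))
    # O3' abuts the 3'-neighbor's phosphorus (next rung along `direction`)
    nphi = (rung + direction) * TWIST
    nz = (rung + direction) * RISE
    nalpha = nphi + side * C1_HALF_ANGLE
    add("O3'", "O", _pol(R_BACKBONE, nalpha + PSI_OFFSET,
                         nz - direction * 0.8 - direction * 1.6))
    # base: laid out in the plane spanned by the inward direction and z
    c1 = _pol(R_C1, alpha, z)
    target = _pol(0.8, phi, z)
    u = target - c1
    u = u / np.linalg.norm(u)
    v = np.cross(u, np.array([0.0, 0.0, 1.0]))
    v = v / np.linalg.norm(v)
    glyc = c1 + 1.5 * u
    for name, (bx, by) in _BASE_2D[base].items():
        element = name[0]
        add(name, element, glyc + bx * u + by * v)
    return atoms, serial


def _ligand_atoms(rung: int, serial_start: int) -> tuple[list[Atom], int]:
    """dATP-like triphosphate on the primer side of ``rung``."""
    phi = rung * TWIST
    z = rung * RISE
    alpha = phi - C1_HALF_ANGLE  # primer side
    psi = alpha + PSI_OFFSET
    zp = z - 0.8
    serial = serial_start
    atoms: list[Atom] = []

    def add(name: str, element: str, pos) -> None:
        nonlocal serial
        serial += 1
        atoms.append(_atom(serial, name, element, pos))

    add("PA", "P", _pol(R_BACKBONE, psi, zp))
    add("O1A", "O", _pol(R_BACKBONE + 1.0, psi + 6, zp))
    add("O2A", "O", _pol(R_BACKBONE + 0.5, psi - 8, zp - 0.8))
    add("O3A", "O", _pol(R_BACKBONE + 1.5, psi, zp + 0.5))
    add("PB", "P", _pol(R_BACKBONE + 3.0, psi, zp + 0.5))
    add("O1B", "O", _pol(R_BACKBONE + 3.2, psi + 8, zp + 1.2))
    add("O2B", "O", _pol(R_BACKBONE + 3.2, psi - 8, zp - 0.5))
    add("O3B", "O", _pol(R_BACKBONE + 4.5, psi, zp + 0.5))
    add("PG", "P", _pol(R_BACKBONE + 6.0, psi, zp + 0.5))
    add("O1G", "O", _pol(R_BACKBONE + 6.2, psi + 8, zp + 1.2))
    add("O2G", "O", _pol(R_BACKBONE + 6.2, psi - 8, zp - 0.5))
    add("O3G", "O", _pol(R_BACKBONE + 7.5, psi, zp + 0.5))
    add("O5'", "O", _pol(R_BACKBONE, psi, z - 0.4))
    add("C5'", "C", _pol(8.3, alpha + 12, z + 0.6))
    add("C4'", "C", _pol(7.5, alpha + 6, z + 1.0))
    add("O4'", "O", _pol(6.5, alpha + 8, z + 0.8))
    add("C3'", "C", _pol(7.8, alpha - 4, z + 0.2))
    add("O3'", "O", _pol(7.8, alpha - 4, z - 1.2))
    add("C2'", "C", _pol(6.8, alpha - 6, z - 0.5))
    add("C1'", "C", _pol(R_C1, alpha, z))
    c1 = _pol(R_C1, alpha, z)
    target = _pol(0.8, phi, z)
    u = target - c1
    u = u / np.linalg.norm(u)
    v = np.cross(u, np.array([0.0, 0.0, 1.0]))
    v = v / np.linalg.norm(v)
    glyc = c1 + 1.5 * u
    for name, (bx, by) in _BASE_2D["A"].items():
        add(name, name[0], glyc + bx * u + by * v)
    return atoms, serial


def make_duplex_complex(primer_seq: str = "GACCACGGCCA",
                        template_seq: str = "AACTGTGGCCGTGGTC",
                        contact_plan: list[dict] | None = None,
                        with_ligand: bool = True
                        ) -> tuple[Structure, dict]:
    """Idealized primer/template duplex plus dNTP-like ligand.

    The primer anneals to the template 3' region leaving a single-stranded
    5' overhang; the templating residue (paired with the placed ligand) is
    t(0).  ``contact_plan`` entries place protein pseudo-residues:
    ``{"strand": "template", "position": -7, "atom": "OP1",
    "distance": 2.9, "role": "both", "water_legs": None | (l1, l2)}``.
    """
    primer_seq = primer_seq.replace(" ", "").upper()
    template_seq = template_seq.replace(" ", "").upper()
    n_primer, n_template = len(primer_seq), len(template_seq)
    if n_primer >= n_template:
        raise FixtureError("template must be longer than the primer")
    # primer pairs the template 3' end; check complementarity
    for k in range(n_primer):
        t_base = template_seq[n_template - 1 - k]
        p_base = primer_seq[k]
        if _COMPLEMENT[p_base] != t_base:
            raise FixtureError(
                f"primer base {p_base} at {k + 1} does not pair template "
                f"base {t_base}")

    s = Structure(id="duplex_complex")
    serial = 0
    # template: rung k holds template position n_template - k (1-based);
    # k runs 0 (3' terminus) .. n_template - 1 (5' terminus)
    template_by_rung: dict[int, Residue] = {}
    for k in range(n_template):
        pos = n_template - k
        base = template_seq[pos - 1]
        res = Residue("T", pos, f"D{base}")
        atoms, serial = _nucleotide_atoms(base, k, side=+1, direction=-1,
                                          serial_start=serial)
        res.atoms = atoms
        template_by_rung[k] = res
    # file order 5'->3'
    for k in sorted(template_by_rung, reverse=True):
        s.residues.append(template_by_rung[k])

    primer_by_rung: dict[int, Residue] = {}
    for k in range(n_primer):
        base = primer_seq[k]
        res = Residue("P", k + 1, f"D{base}")
        atoms, serial = _nucleotide_atoms(base, k, side=-1, direction=+1,
                                          serial_start=serial)
        res.atoms = atoms
        primer_by_rung[k] = res
        s.residues.append(res)

    t0_rung = n_primer  # one rung past the primer 3' terminus
    if with_ligand:
        lig = Residue("L", 1, "DTP")
        atoms, serial = _ligand_atoms(t0_rung, serial)
        lig.atoms = atoms
        s.residues.append(lig)

    # position bookkeeping for the contact plan and the ground truth:
    # template rung k -> index k - t0_rung; primer rung k -> k - (n_primer-1)
    def resolve(strand: str, position: int) -> Residue:
        if strand == "template":
            rung = position + t0_rung
            if rung not in template_by_rung:
                raise FixtureError(f"template position {position} absent")
            return template_by_rung[rung]
        if strand == "primer":
            rung = position + n_primer - 1
            if rung not in primer_by_rung:
                raise FixtureError(f"primer position {position} absent")
            return primer_by_rung[rung]
        raise FixtureError(f"unknown strand {strand!r}")

    planned = []
    wat_index = 0
    for i, plan in enumerate(contact_plan or []):
        res = resolve(plan["strand"], plan["position"])
        target = res.atom(plan["atom"]).coords
        axis_point = np.array([0.0, 0.0, target[2]])
        u = target - axis_point
        u = u / np.linalg.norm(u)
        d = float(plan["distance"])
        role = plan.get("role", "both")
        water_legs = plan.get("water_legs")
        resn, fname, felem = _ROLE_RESIDUES[role]
        prot = Residue("E", 100 + i, resn)
        if water_legs:
            l1, l2 = water_legs
            wat_index += 1
            water = Residue("W", 900 + wat_index, "HOH")
            serial += 1
            water.atoms.append(_atom(serial, "O", "O", target + u * l2))
            s.residues.append(water)
            anchor = target + u * (l1 + l2)
        else:
            anchor = target + u * d
        serial += 1
        prot.atoms.append(_atom(serial, fname, felem, anchor))
        serial += 1
        prot.atoms.append(_atom(serial, "CA", "C", anchor + u * 3.0))
        serial += 1
        prot.atoms.append(_atom(serial, "N", "N", anchor + u * 4.5))
        s.residues.append(prot)
        planned.append(dict(plan))

    truth = {
        "kind": "duplex_complex",
        "n_dna_residues": n_primer + n_template,
        "primer_chain": "P",
        "template_chain": "T",
        "templating_seq_id": n_template - t0_rung,
        "template_positions": sorted(k - t0_rung
                                     for k in range(n_template)),
        "primer_positions": sorted(k - (n_primer - 1)
                                   for k in range(n_primer)),
        "contacts": planned,
    }
    return classify_entities(s), truth


def make_duplex_fixture(**kwargs) -> tuple[Structure, dict]:
    """Alias for :func:`make_duplex_complex`."""
    return make_duplex_complex(**kwargs)


# ---------------------------------------------------------------------------
# hollow sphere / solid block (channel oracles)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def make_hollow_sphere(inner_radius: float = 8.0, n_atoms: int = 220,
                       pore_radius: float | None = None,
                       element: str = "C") -> tuple[Structure, dict]:
    """Shell of atoms around a sealed cavity of analytic volume.

    Atom centers sit at inner_radius + r_vdw, dense enough that neither a
    2.7 A nor a 7.0 A probe can slip between them; an optional pore removes
    shell atoms within ``pore_radius`` of the +z pole.
    """
    from .chemtables import vdw_radius

    if inner_radius < 4.0:
        raise FixtureError("inner_radius must be >= 4 A")
    r_shell = inner_radius + vdw_radius(element)
    pts = _fibonacci_sphere(n_atoms) * r_shell
    if pore_radius is not None:
        pole = np.array([0.0, 0.0, r_shell])
        pts = pts[np.linalg.norm(pts - pole, axis=1) >= pore_radius]
    s = Structure(id="hollow_sphere")
    for i, p in enumerate(pts):
        res = Residue("S", i + 1, "SPH")
        res.atoms.append(_atom(i + 1, element, element, p))
        s.residues.append(res)
    truth = {
        "kind": "hollow_sphere",
        "inner_radius": inner_radius,
        "analytic_volume": 4.0 / 3.0 * math.pi * inner_radius ** 3,
        "n_atoms": len(pts),
        "pore_radius": pore_radius,
    }
    return classify_entities(s), truth


def make_block(n: int = 6, spacing: float = 1.5) -> tuple[Structure, dict]:
    """Dense solid block of carbon atoms: no internal channels."""
    s = Structure(id="block")
    serial = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                serial += 1
                res = Residue("S", serial, "BLK")
                res.atoms.append(_atom(serial, "C", "C",
                                       (i * spacing, j * spacing,
                                        k * spacing)))
                s.residues.append(res)
    return classify_entities(s), {"kind": "block", "n_channels": 0}


# ---------------------------------------------------------------------------
# rotation pairs (domain-closure oracle)
# ---------------------------------------------------------------------------

_AA_CODES = ("ALA", "ARG", "ASN", "ASP", "GLN", "GLU", "GLY", "HIS", "ILE",
             "LEU", "LYS", "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL")


def _helix_protein(n_residues: int, seed: int) -> Structure:
    """Pseudo-protein: Calpha trace on an alpha-helical path, residue names
    drawn deterministically from the seed."""
    rng = np.random.default_rng(seed)
    s = Structure(id="helix")
    for i in range(n_residues):
        angle = math.radians(100.0 * i)
        pos = (2.3 * math.cos(angle), 2.3 * math.sin(angle), 1.5 * i)
        res = Residue("A", i + 1, str(rng.choice(_AA_CODES)))
        res.atoms.append(_atom(i + 1, "CA", "C", pos))
        s.residues.append(res)
    return classify_entities(s)


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def make_rotation_pair(angle_deg: float, axis=(1.0, 0.0, 0.0),
                       n_residues: int = 60, mobile_start: int = 31,
                       noise_sigma: float = 0.0, seed: int = 0,
                       base: Structure | None = None
                       ) -> tuple[Structure, Structure, dict]:
    """(open, closed) pair related by a rigid mobile-domain rotation.

    The closed copy rotates residues ``mobile_start``..end by ``angle_deg``
    about ``axis`` through the mobile centroid, then (optionally) perturbs
    every closed-copy atom with isotropic Gaussian noise.
    """
    open_s = base or _helix_protein(n_residues, seed)
    mobile_keys = {r.key for r in open_s.residues
                   if r.seq_id >= mobile_start}
    if not mobile_keys:
        raise FixtureError("empty mobile set")
    rng = np.random.default_rng(seed + 7919)
    rot = _rotation_matrix(np.asarray(axis, dtype=float), angle_deg)
    mobile_coords = np.array([a.coords for r in open_s.residues
                              if r.key in mobile_keys for a in r.atoms])
    pivot = mobile_coords.mean(axis=0)
    closed = Structure(id=f"{open_s.id}_closed")
    for res in open_s.residues:
        new = Residue(res.chain_id, res.seq_id, res.res_name, [],
                      res.insertion_code, res.entity)
        for atom in res.atoms:
            pos = atom.coords.copy()
            if res.key in mobile_keys:
                pos = rot @ (pos - pivot) + pivot
            if noise_sigma > 0:
                pos = pos + rng.normal(0.0, noise_sigma, 3)
            new.atoms.append(_atom(atom.serial, atom.name, atom.element,
                                   pos, b=atom.b_factor))
        closed.residues.append(new)
    axis_unit = np.asarray(axis, dtype=float)
    axis_unit = axis_unit / np.linalg.norm(axis_unit)
    truth = {
        "kind": "rotation_pair",
        "angle": angle_deg,
        "axis": axis_unit.tolist(),
        "mobile_start": mobile_start,
        "n_residues": len(open_s.residues),
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return open_s, closed, truth


# ---------------------------------------------------------------------------
# octahedral metal sites
# ---------------------------------------------------------------------------

_OCT_DIRECTIONS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                            [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)


def make_octahedron(element: str = "MG", bond_length: float = 2.1,
                    jitter_deg: float = 0.0, n_ligands: int = 6,
                    seed: int = 0) -> tuple[Structure, dict]:
    """Metal ion with water ligands on (jittered) octahedral directions."""
    if not 1 <= n_ligands <= 6:
        raise FixtureError("n_ligands must be 1..6")
    rng = np.random.default_rng(seed)
    s = Structure(id="octahedron")
    metal = Residue("M", 1, element.upper())
    metal.atoms.append(_atom(1, element.upper(), element.upper(),
                             (0, 0, 0)))
    s.residues.append(metal)
    for i, direction in enumerate(_OCT_DIRECTIONS[:n_ligands]):
        d = direction.copy()
        if jitter_deg > 0:
            perp = np.cross(d, rng.normal(size=3))
            perp = perp / np.linalg.norm(perp)
            d = _rotation_matrix(perp, jitter_deg) @ d
        water = Residue("W", i + 2, "HOH")
        water.atoms.append(_atom(i + 2, "O", "O", d * bond_length))
        s.residues.append(water)
    truth = {
        "kind": "octahedron",
        "coordination_number": n_ligands,
        "bond_length": bond_length,
        "jitter_deg": jitter_deg,
        "octahedricity_zero": jitter_deg == 0.0,
    }
    return classify_entities(s), truth


# ---------------------------------------------------------------------------
# three-metal active-site fixture (site-label oracle)
# ---------------------------------------------------------------------------

def make_metal_site_fixture(with_isolated_na: bool = False
                            ) -> tuple[Structure, dict]:
    """Simplified triphosphate with three metals in canonical positions.

    Metal B touches alpha-, beta- and gamma-phosphate oxygens, metal A the
    alpha-phosphate plus two waters and an aspartate, metal C only the
    gamma-phosphate plus three waters (each stabilised by a carboxylate,
    exercising the second shell).
    """
    s = Structure(id="metal_sites")
    serial = 0

    def add(res: Residue, name: str, element: str, pos) -> None:
        nonlocal serial
        serial += 1
        res.atoms.append(_atom(serial, name, element, pos))

    lig = Residue("L", 1, "DTP")
    add(lig, "PA", "P", (0.0, 0.0, 0.0))
    add(lig, "O1A", "O", (1.0, 1.4, 0.0))
    add(lig, "O2A", "O", (0.0, -1.0, 0.0))
    add(lig, "O3A", "O", (1.3, -0.6, 0.0))
    add(lig, "PB", "P", (2.6, 0.0, 0.0))
    add(lig, "O1B", "O", (2.6, 0.9, 0.0))
    add(lig, "O2B", "O", (2.6, -1.5, 1.0))
    add(lig, "O3B", "O", (3.9, -0.6, 0.0))
    add(lig, "PG", "P", (5.2, 0.0, 0.0))
    add(lig, "O1G", "O", (4.2, 1.4, 0.0))
    add(lig, "O2G", "O", (5.2, -1.5, 0.0))
    add(lig, "O3G", "O", (6.6, 0.6, 0.0))
    s.residues.append(lig)

    metal_b = Residue("M", 1, "MN")
    add(metal_b, "MN", "MN", (2.6, 3.0, 0.0))
    # pull the three phosphate oxygens into B's sphere
    # (O1A, O1B, O1G at ~2.1-2.3 A from B)
    s.residues.append(metal_b)

    metal_a = Residue("M", 2, "MG")
    add(metal_a, "MG", "MG", (0.0, -3.0, 0.0))
    s.residues.append(metal_a)

    metal_c = Residue("M", 3, "MN")
    add(metal_c, "MN", "MN", (5.2, -3.6, 0.0))
    s.residues.append(metal_c)

    asp = Residue("A", 404, "ASP")
    add(asp, "OD1", "O", (-1.5, -4.5, 0.0))
    add(asp, "CG", "C", (-2.6, -5.3, 0.0))
    s.residues.append(asp)

    waters_a = [(1.5, -4.5, 0.0), (0.0, -3.0, 2.1)]
    for i, pos in enumerate(waters_a):
        w = Residue("W", 800 + i, "HOH")
        add(w, "O", "O", pos)
        s.residues.append(w)

    waters_c = [(5.2, -3.6, 2.1), (5.2, -3.6, -2.1), (6.7, -5.1, 0.0)]
    stabilizers = [("GLU", 578, "OE1", (5.2, -3.6, 4.9)),
                   ("GLU", 580, "OE2", (5.2, -3.6, -4.9)),
                   ("LYS", 464, "NZ", (8.3, -6.9, 0.0))]
    for i, pos in enumerate(waters_c):
        w = Residue("W", 810 + i, "HOH")
        add(w, "O", "O", pos)
        s.residues.append(w)
    for resn, seq, aname, pos in stabilizers:
        r = Residue("A", seq, resn)
        add(r, aname, "O" if aname.startswith("O") else "N", pos)
        s.residues.append(r)

    if with_isolated_na:
        na = Residue("M", 9, "NA")
        add(na, "NA", "NA", (50.0, 0.0, 0.0))
        s.residues.append(na)

    truth = {
        "kind": "metal_sites",
        "labels": {"A": "MG", "B": "MN", "C": "MN"},
        "b_contacts": ["alpha", "beta", "gamma"],
        "c_contacts": ["gamma"],
        "n_second_shell_c": 3,
    }
    return classify_entities(s), truth
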