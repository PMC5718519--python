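"""Active-site metal coordination analysis.

Each metal's coordination sphere is every N/O atom within a cutoff
(default 2.6 A, covering Mg-O ~2.1 and Mn-O ~2.2 while excluding H-bond
range), annotated with a ligand kind.  Octahedricity is the mean absolute
deviation of inter-ligand angles from ideal octahedral values (cis 90 deg,
trans 180 deg); 0 for a perfect octahedron.  Canonical polymerase site
labels: B bridges the alpha-, beta- and gamma-phosphates, A contacts the
alpha-phosphate next to the primer 3' terminus, C contacts the
gamma-phosphate only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemtables as ct
from .structure_io import Atom, Residue, Structure, prune_altlocs


@dataclass
class Ligand:
    residue: Residue
    atom: Atom
    distance: float
    kind: str  # protein_sidechain | protein_backbone | dntp_alpha/beta/gamma
    #            | water | dna | other


@dataclass
class MetalSite:
    residue: Residue
    atom: Atom
    element: str
    ligands: list[Ligand]
    label: str = "unassigned"  # "A" | "B" | "C" | "unassigned"
    second_shell: list[tuple[Ligand, Residue, Atom, float]] = field(
        default_factory=list)

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)

    @property
    def octahedricity(self) -> float:
        return octahedricity(self.atom.coords,
                             [l.atom.coords for l in self.ligands])

    def phosphate_groups(self) -> set[str]:
        return {l.kind.removeprefix("dntp_") for l in self.ligands
                if l.kind.startswith("dntp_")}


def octahedricity(center: np.ndarray, ligand_coords: list[np.ndarray]
                  ) -> float:
    """Mean |angle deviation| (degrees) from octahedral cis/trans ideals.

    Pairs with angle > 135 deg are scored against 180 (trans), the rest
    against 90 (cis).
    """
    if len(ligand_coords) < 2:
        return 0.0
    vecs = [np.asarray(c) - center for c in ligand_coords]
    devs = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            cosa = np.dot(vecs[i], vecs[j]) / (
                np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j]))
            angle = float(np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0))))
            target = 180.0 if angle > 135.0 else 90.0
            devs.append(abs(angle - target))
    return float(np.mean(devs))


def _ligand_kind(res: Residue, atom: Atom) -> str:
    if res.entity == "water":
        return "water"
    if res.entity == "protein":
        # backbone carbonyl/amide vs side chain, from the atom name alone
        return ("protein_backbone" if atom.name in ("N", "O", "OXT")
                else "protein_sidechain")
    if res.entity == "dntp_ligand":
        if atom.name in ct.DNTP_ALPHA:
            return "dntp_alpha"
        if atom.name in ct.DNTP_BETA:
            return "dntp_beta"
        if atom.name in ct.DNTP_GAMMA:
            return "dntp_gamma"
        return "dntp_other"
    if res.entity == "dna":
        return "dna"
    return "other"


def find_metal_sites(s: Structure, cutoff: float = 2.6,
                     cutoff_by_element: dict[str, float] | None = None
                     ) -> list[MetalSite]:
    """Coordination spheres of all metal atoms, sorted by proximity to the
    dNTP alpha-phosphorus (when a ligand is present)."""
    s = prune_altlocs(s)
    overrides = cutoff_by_element or {}
    sites = []
    for res in s.residues_of("metal"):
        for metal in res.atoms:
            cut = overrides.get(metal.element.upper(), cutoff)
            ligands = []
            for ores, oatom in s.atoms():
                if ores is res or ores.entity == "metal":
                    continue
                if oatom.element not in ("N", "O"):
                    continue
                d = float(np.linalg.norm(oatom.coords - metal.coords))
                if d <= cut:
                    ligands.append(Ligand(ores, oatom, d,
                                          _ligand_kind(ores, oatom)))
            ligands.sort(key=lambda l: l.distance)
            sites.append(MetalSite(res, metal, metal.element.upper(),
                                   ligands))
    pa = _alpha_phosphorus(s)
    if pa is not None:
        sites.sort(key=lambda site: float(
            np.linalg.norm(site.atom.coords - pa)))
    return sites


def _alpha_phosphorus(s: Structure) -> np.ndarray | None:
    for res in s.residues_of("dntp_ligand"):
        for cand in ("PA", "P"):
            if res.has_atom(cand):
                return res.atom(cand).coords
    return None


def assign_site_labels(sites: list[MetalSite], s: Structure
                       ) -> list[MetalSite]:
    """Assign A/B/C by contacted phosphate groups.

    B contacts alpha, beta and gamma; A contacts alpha (and sits nearest
    the primer 3' terminus when several qualify); C contacts gamma only.
    """
    primer_o3 = _primer_three_prime(s)
    a_candidates = []
    for site in sites:
        groups = site.phosphate_groups()
        if {"alpha", "beta", "gamma"} <= groups:
            site.label = "B"
        elif groups == {"gamma"}:
            site.label = "C"
        elif "alpha" in groups:
            a_candidates.append(site)
        else:
            site.label = "unassigned"
    if a_candidates:
        if primer_o3 is not None and len(a_candidates) > 1:
            a_candidates.sort(key=lambda site: float(
                np.linalg.norm(site.atom.coords - primer_o3)))
            for extra in a_candidates[1:]:
                extra.label = "unassigned"
        a_candidates[0].label = "A"
    return sites


def _primer_three_prime(s: Structure) -> np.ndarray | None:
    """3'-terminal O3'/C3' of the DNA strand nearest the ligand PA."""
    from .fingerprint import index_positions

    try:
        index = index_positions(s)
    except Exception:
        return None
    for res in s.residues_of("dna", chain=index.primer_chain):
        if index.label_of(res) == ("primer", 0):
            for cand in ("O3'", "C3'"):
                if res.has_atom(cand):
                    return res.atom(cand).coords
    return None


def second_shell(site: MetalSite, s: Structure, cutoff: float = 3.5,
                 d_min: float = 2.2) -> list[tuple[Ligand, Residue, Atom,
                                                   float]]:
    """Polar protein atoms stabilising the site's water ligands.

    For every water ligand, protein N/O/S atoms within H-bond range
    (d_min..cutoff) of the water oxygen.
    """
    s = prune_altlocs(s)
    out = []
    for ligand in site.ligands:
        if ligand.kind != "water":
            continue
        for res in s.residues_of("protein"):
            for atom in res.atoms:
                if atom.element not in ("N", "O", "S"):
                    continue
                d = float(np.linalg.norm(atom.coords -
                                         ligand.atom.coords))
                if d_min <= d <= cutoff:
                    out.append((ligand, res, atom, d))
    site.second_shell = out
    return out


def site_report(sites: list[MetalSite]) -> list[dict]:
    """JSON-ready description of the sites."""
    out = []
    for site in sites:
        out.append({
            "element": site.element,
            "residue": f"{site.residue.chain_id}/"
                       f"{site.residue.res_name}{site.residue.seq_id}",
            "label": site.label,
            "coordination_number": site.coordination_number,
            "octahedricity_deg": round(site.octahedricity, 2),
            "b_factor": site.atom.b_factor,
            "ligands": [{
                "residue": f"{l.residue.chain_id}/"
                           f"{l.residue.res_name}{l.residue.seq_id}",
                "atom": l.atom.name,
                "distance": round(l.distance, 3),
                "kind": l.kind,
            } for l in site.ligands],
        })
    return out
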