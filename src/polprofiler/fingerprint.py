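"""Classed protein-DNA/dNTP hydrogen-bond fingerprints.

Hydrogen bonds are classed purely by heavy-atom distance: direct strong
bonds span 2.2-3.2 A (inclusive), direct weak bonds >3.2-4.0 A, and pairs
closer than 2.2 A are clashes, not bonds.  Water-mediated bonds run through
exactly one bridging water and inherit the class of their weaker (longer)
leg.  Donor/acceptor role compatibility is enforced to suppress
acceptor-acceptor artifacts; no angular term is used because deposited
structures carry no hydrogens.

Each bond is mapped to a DNA moiety (phosphate backbone, sugar, groove
edges, triphosphate groups) and a strand position index anchored at the
templating base t(0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import chemtables as ct
from .domain_model import DomainMap
from .structure_io import Atom, Residue, Structure, prune_altlocs, \
    strip_hydrogens

_EPS = 1e-6  # protects inclusive class boundaries from float rounding

D_MIN = 2.2
D_STRONG = 3.2
D_MAX = 4.0


class MoietyError(ValueError):
    pass


class IndexingError(ValueError):
    pass


@dataclass
class HBond:
    protein_res: Residue
    protein_atom: Atom
    partner_res: Residue
    partner_atom: Atom
    distance: float
    mediation: str            # "direct" | "water"
    strength: str             # "strong" | "weak"
    bridge_water: Residue | None = None
    leg_distances: tuple[float, float] | None = None

    @property
    def klass(self) -> str:
        return f"{self.mediation}-{self.strength}"


@dataclass
class Clash:
    protein_res: Residue
    protein_atom: Atom
    partner_res: Residue
    partner_atom: Atom
    distance: float


@dataclass
class MoietyLabel:
    strand: str     # "primer" | "template" | "dntp"
    position: int | None
    moiety: str

    @property
    def position_label(self) -> str:
        if self.strand == "dntp":
            return "dntp"
        prefix = "t" if self.strand == "template" else "p"
        if self.position is None:
            return f"{prefix}?"
        return f"{prefix}{self.position:+d}" if self.position else prefix


@dataclass
class StackingContact:
    protein_res: Residue
    partner_res: Residue
    distance: float  # ring centroid to deoxyribose centroid


@dataclass
class FingerprintRecord:
    bond: HBond
    label: MoietyLabel
    domain: str | None


@dataclass
class Fingerprint:
    structure_id: str
    records: list[FingerprintRecord]
    stacking: list[StackingContact]
    clashes: list[Clash]

    def count_matrix(self) -> dict[tuple[str, str, str, str], int]:
        """Counts keyed by (strand, position label, moiety, class)."""
        out: dict[tuple[str, str, str, str], int] = {}
        for rec in self.records:
            key = (rec.label.strand, rec.label.position_label,
                   rec.label.moiety, rec.bond.klass)
            out[key] = out.get(key, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.records)


def classify_distance(d: float) -> str:
    """Distance class: clash / strong / weak / none."""
    if d < D_MIN - _EPS:
        return "clash"
    if d <= D_STRONG + _EPS:
        return "strong"
    if d <= D_MAX + _EPS:
        return "weak"
    return "none"


# ---------------------------------------------------------------------------
# polar-atom harvesting
# ---------------------------------------------------------------------------

def _polar_atoms(s: Structure, entities: tuple[str, ...],
                 table: dict[str, dict[str, str]]
                 ) -> list[tuple[Residue, Atom, str]]:
    out = []
    for res in s.residues:
        if res.entity not in entities:
            continue
        roles = table.get(res.res_name.upper())
        for atom in res.atoms:
            if atom.element not in ("N", "O", "S"):
                continue
            if roles is not None:
                role = roles.get(atom.name)
                if role is None:
                    continue
            else:
                # unknown residue: fall back to element-only polarity
                role = "both"
            out.append((res, atom, role))
    return out


def find_direct_hbonds(s: Structure,
                       table: dict[str, dict[str, str]] | None = None,
                       d_min: float = D_MIN, d_strong: float = D_STRONG,
                       d_max: float = D_MAX
                       ) -> tuple[list[HBond], list[Clash]]:
    """All role-compatible protein(N/O/S) <-> DNA/dNTP(N/O) pairs in range.

    Returns (bonds, clashes); sub-2.2 A contacts are flagged as clashes,
    never as bonds.
    """
    s = prune_altlocs(strip_hydrogens(s))
    table = table or ct.default_donor_acceptor_table()
    prot = _polar_atoms(s, ("protein",), table)
    nuc = [(r, a, role) for r, a, role in
           _polar_atoms(s, ("dna", "dntp_ligand"), table)
           if a.element in ("N", "O")]
    bonds: list[HBond] = []
    clashes: list[Clash] = []
    if not prot or not nuc:
        return bonds, clashes
    tree = cKDTree(np.array([a.coords for _, a, _ in nuc]))
    for pres, patom, prole in prot:
        for j in tree.query_ball_point(patom.coords, d_max + _EPS):
            nres, natom, nrole = nuc[j]
            d = float(np.linalg.norm(patom.coords - natom.coords))
            klass = classify_distance(d)
            if klass == "none":
                continue
            if klass == "clash":
                clashes.append(Clash(pres, patom, nres, natom, d))
                continue
            if not ct.roles_compatible(prole, nrole):
                continue
            bonds.append(HBond(pres, patom, nres, natom, d,
                               mediation="direct", strength=klass))
    bonds.sort(key=_bond_key)
    return bonds, clashes


def find_water_bridges(s: Structure,
                       table: dict[str, dict[str, str]] | None = None,
                       d_min: float = D_MIN, d_strong: float = D_STRONG,
                       d_max: float = D_MAX) -> list[HBond]:
    """Single-water bridges protein...water...DNA/dNTP.

    One record per (protein atom, water, partner atom) triple; the class is
    that of the weaker (longer) leg.  Chains through two or more waters are
    not bridges.
    """
    s = prune_altlocs(strip_hydrogens(s))
    table = table or ct.default_donor_acceptor_table()
    waters = [(r, a) for r in s.residues if r.entity == "water"
              for a in r.atoms if a.element == "O"]
    if not waters:
        return []
    prot = _polar_atoms(s, ("protein",), table)
    nuc = [(r, a, role) for r, a, role in
           _polar_atoms(s, ("dna", "dntp_ligand"), table)
           if a.element in ("N", "O")]
    bonds: list[HBond] = []
    for wres, watom in waters:
        legs_p = []
        for pres, patom, _ in prot:
            d = float(np.linalg.norm(patom.coords - watom.coords))
            if classify_distance(d) in ("strong", "weak"):
                legs_p.append((pres, patom, d))
        if not legs_p:
            continue
        legs_n = []
        for nres, natom, _ in nuc:
            d = float(np.linalg.norm(natom.coords - watom.coords))
            if classify_distance(d) in ("strong", "weak"):
                legs_n.append((nres, natom, d))
        for pres, patom, dp in legs_p:
            for nres, natom, dn in legs_n:
                strength = ("strong"
                            if classify_distance(dp) == "strong"
                            and classify_distance(dn) == "strong"
                            else "weak")
                bonds.append(HBond(
                    pres, patom, nres, natom,
                    distance=float(
                        np.linalg.norm(patom.coords - natom.coords)),
                    mediation="water", strength=strength,
                    bridge_water=wres, leg_distances=(dp, dn)))
    bonds.sort(key=_bond_key)
    return bonds


def _bond_key(b: HBond):
    return (b.protein_res.key, b.protein_atom.name,
            b.partner_res.key, b.partner_atom.name,
            b.bridge_water.key if b.bridge_water else ("", 0, ""))


# ---------------------------------------------------------------------------
# moiety classification
# ---------------------------------------------------------------------------

def classify_moiety(res: Residue, atom: Atom) -> str:
    """Map one DNA/dNTP heavy atom to its moiety."""
    name = atom.name
    resn = res.res_name.upper()
    if res.entity == "dntp_ligand":
        if name in ct.DNTP_ALPHA:
            return "alpha_phosphate"
        if name in ct.DNTP_BETA:
            return "beta_phosphate"
        if name in ct.DNTP_GAMMA:
            return "gamma_phosphate"
        if name == "O3'":
            return "sugar_3oh"
        if name == "O4'":
            return "sugar_o4p"
        if name in ct.SUGAR_RING_ATOMS:
            return "sugar"
        return _base_moiety(resn in ct.PURINE_DNTP or resn not in
                            ct.PYRIMIDINE_RESIDUES, name, res)
    if res.entity == "dna":
        if name in ct.PHOSPHATE_BACKBONE_ATOMS:
            return "phosphate_backbone"
        if name == "O4'":
            return "sugar_o4p"
        if name in ct.SUGAR_RING_ATOMS:
            return "sugar"
        return _base_moiety(resn in ct.PURINE_RESIDUES, name, res)
    raise MoietyError(
        f"atom {res.chain_id}/{res.res_name}{res.seq_id}/{name} "
        f"is not a DNA or dNTP atom (entity={res.entity})")


def _base_moiety(purine: bool, name: str, res: Residue) -> str:
    if purine:
        if name in ct.PURINE_MINOR:
            return "base_minor_groove"
        if name in ct.PURINE_MAJOR:
            return "base_major_groove"
        if name in ct.PURINE_WC:
            return "base_wc_edge"
        if name in {"N9", "C4", "C5", "C8", "C2", "C6"}:
            return "base"
    else:
        if name in ct.PYRIMIDINE_MINOR:
            return "base_minor_groove"
        if name in ct.PYRIMIDINE_MAJOR:
            return "base_major_groove"
        if name in ct.PYRIMIDINE_WC:
            return "base_wc_edge"
        if name in {"N1", "C2", "C4", "C5", "C6"}:
            return "base"
    raise MoietyError(
        f"unknown base atom {name!r} in "
        f"{res.chain_id}/{res.res_name}{res.seq_id}")


# ---------------------------------------------------------------------------
# strand / position indexing
# ---------------------------------------------------------------------------

_BASE_ATOM_NAMES = {"N1", "C2", "N2", "N3", "C4", "N4", "C5", "C6", "N6",
                    "C7", "C5M", "N7", "C8", "N9", "O2", "O4", "O6"}


def _base_centroid(res: Residue) -> np.ndarray | None:
    pts = [a.coords for a in res.atoms if a.name in _BASE_ATOM_NAMES]
    if not pts:
        return None
    return np.mean(pts, axis=0)


def _order_strand(residues: list[Residue]) -> list[Residue]:
    """Order residues 5'->3' using O3'(i) - P(i+1) connectivity; fall back
    to seq_id order when the backbone is incomplete."""
    by_seq = sorted(residues, key=lambda r: r.seq_id)
    links: dict[int, int] = {}
    for i, ra in enumerate(by_seq):
        if not ra.has_atom("O3'"):
            continue
        o3 = ra.atom("O3'").coords
        for j, rb in enumerate(by_seq):
            if i == j or not rb.has_atom("P"):
                continue
            if np.linalg.norm(o3 - rb.atom("P").coords) < 2.0:
                links[i] = j
                break
    if not links:
        return by_seq
    succs = set(links.values())
    starts = [i for i in range(len(by_seq)) if i not in succs]
    ordered: list[Residue] = []
    for start in starts:
        i: int | None = start
        seen = set()
        while i is not None and i not in seen:
            ordered.append(by_seq[i])
            seen.add(i)
            i = links.get(i)
    for r in by_seq:
        if r not in ordered:
            ordered.append(r)
    return ordered


@dataclass
class PositionIndex:
    # (chain_id, seq_id, icode) -> (strand, index)
    labels: dict[tuple[str, int, str], tuple[str, int]]
    primer_chain: str
    template_chain: str
    templating_key: tuple[str, int, str]

    def label_of(self, res: Residue) -> tuple[str, int] | None:
        return self.labels.get(res.key)


def index_positions(s: Structure) -> PositionIndex:
    """Label DNA residues by strand and position.

    The templating residue (base-paired with the incoming dNTP) is t(0);
    template indices decrease toward the duplex 3' end (t-1 ... t-10) and
    increase toward the 5' overhang.  The primer 3' terminus is p(0),
    decreasing toward its 5' end.  The primer is recognised as the strand
    whose 3' terminus abuts the dNTP alpha-phosphate.
    """
    s = prune_altlocs(s)
    ligands = s.residues_of("dntp_ligand")
    if not ligands:
        raise IndexingError("no dNTP ligand: cannot anchor the t position")
    ligand = ligands[0]
    dna_chains = {}
    for res in s.residues_of("dna"):
        dna_chains.setdefault(res.chain_id, []).append(res)
    if len(dna_chains) < 2:
        raise IndexingError("need primer and template DNA chains")
    ordered = {c: _order_strand(res) for c, res in dna_chains.items()}

    # alpha-phosphorus (or any phosphorus) of the ligand
    p_atom = None
    for cand in ("PA", "P", "PB"):
        if ligand.has_atom(cand):
            p_atom = ligand.atom(cand)
            break
    if p_atom is None:
        raise IndexingError("ligand carries no phosphorus atom")

    def three_prime_anchor(chain: list[Residue]) -> np.ndarray:
        last = chain[-1]
        for cand in ("O3'", "C3'", "C1'"):
            if last.has_atom(cand):
                return last.atom(cand).coords
        return last.atoms[-1].coords

    primer_chain = min(
        ordered, key=lambda c: np.linalg.norm(
            three_prime_anchor(ordered[c]) - p_atom.coords))

    lig_centroid = _base_centroid(ligand)
    if lig_centroid is None:
        lig_centroid = p_atom.coords
    best: tuple[float, str, int] | None = None
    for chain, residues in ordered.items():
        if chain == primer_chain:
            continue
        for i, res in enumerate(residues):
            cen = _base_centroid(res)
            if cen is None:
                continue
            d = float(np.linalg.norm(cen - lig_centroid))
            if best is None or d < best[0]:
                best = (d, chain, i)
    if best is None:
        raise IndexingError("no template base found opposite the ligand")
    _, template_chain, t0_index = best

    labels: dict[tuple[str, int, str], tuple[str, int]] = {}
    template = ordered[template_chain]
    for i, res in enumerate(template):
        # 5'->3' order: larger i is closer to the 3' end, i.e. more negative
        labels[res.key] = ("template", t0_index - i)
    primer = ordered[primer_chain]
    n_primer = len(primer)
    for i, res in enumerate(primer):
        labels[res.key] = ("primer", i - (n_primer - 1))
    return PositionIndex(
        labels=labels, primer_chain=primer_chain,
        template_chain=template_chain,
        templating_key=template[t0_index].key)


# ---------------------------------------------------------------------------
# fingerprint assembly
# ---------------------------------------------------------------------------

def _stacking_contacts(s: Structure, cutoff: float = 4.5
                       ) -> list[StackingContact]:
    """Aromatic ring centroid within ``cutoff`` of a deoxyribose centroid."""
    out = []
    sugars = []
    for res in s.residues:
        if res.entity not in ("dna", "dntp_ligand"):
            continue
        pts = [a.coords for a in res.atoms
               if a.name in (ct.SUGAR_RING_ATOMS | {"O4'"})]
        if pts:
            sugars.append((res, np.mean(pts, axis=0)))
    for res in s.residues_of("protein"):
        ring = ct.AROMATIC_RING_ATOMS.get(res.res_name.upper())
        if not ring:
            continue
        pts = [a.coords for a in res.atoms if a.name in ring]
        if len(pts) < 3:
            continue
        centroid = np.mean(pts, axis=0)
        for sres, scen in sugars:
            d = float(np.linalg.norm(centroid - scen))
            if d <= cutoff:
                out.append(StackingContact(res, sres, d))
    return out


def build_fingerprint(s: Structure, dmap: DomainMap | None = None,
                      table: dict[str, dict[str, str]] | None = None,
                      structure_id: str | None = None,
                      require_positions: bool = True) -> Fingerprint:
    """Merge direct and water-mediated bonds with moiety/position labels,
    protein-domain attribution and ring-sugar stacking contacts."""
    sid = structure_id or s.id
    work = prune_altlocs(strip_hydrogens(s))
    direct, clashes = find_direct_hbonds(work, table)
    bridged = find_water_bridges(work, table)
    try:
        index = index_positions(work)
    except IndexingError:
        if require_positions:
            raise
        index = None
    records = []
    for bond in direct + bridged:
        res = bond.partner_res
        moiety = classify_moiety(res, bond.partner_atom)
        if res.entity == "dntp_ligand":
            label = MoietyLabel("dntp", None, moiety)
        else:
            lab = index.label_of(res) if index else None
            strand, position = lab if lab else ("?", None)
            label = MoietyLabel(strand, position, moiety)
        domain = (dmap.domain_of(sid, bond.protein_res.chain_id,
                                 bond.protein_res.seq_id)
                  if dmap else None)
        records.append(FingerprintRecord(bond, label, domain))
    return Fingerprint(structure_id=sid, records=records,
                       stacking=_stacking_contacts(work), clashes=clashes)


def count_contacts(fp: Fingerprint, strand: str | None = None,
                   positions: tuple[int, int] | None = None,
                   moieties: set[str] | str | None = None,
                   mediation: str | None = None,
                   strength: str | None = None,
                   distinct: str = "records") -> int:
    """Count fingerprint records matching a filter.

    ``positions`` is an inclusive (low, high) index range.  ``distinct``
    counts either every record ("records") or unique
    (protein residue, partner residue, moiety) combinations
    ("residue_moiety") -- both readings of a published contact total.
    """
    if isinstance(moieties, str):
        moieties = {moieties}
    hits = []
    for rec in fp.records:
        if strand and rec.label.strand != strand:
            continue
        if positions is not None:
            if rec.label.position is None:
                continue
            lo, hi = positions
            if not lo <= rec.label.position <= hi:
                continue
        if moieties and rec.label.moiety not in moieties:
            continue
        if mediation and rec.bond.mediation != mediation:
            continue
        if strength and rec.bond.strength != strength:
            continue
        hits.append(rec)
    if distinct == "records":
        return len(hits)
    if distinct == "residue_moiety":
        return len({(r.bond.protein_res.key, r.bond.partner_res.key,
                     r.label.moiety) for r in hits})
    raise ValueError(f"unknown distinct mode {distinct!r}")


# ---------------------------------------------------------------------------
# tabular / graphical output
# ---------------------------------------------------------------------------

def fingerprint_table(fp: Fingerprint):
    """One record per row, ready for TSV export."""
    import pandas as pd

    rows = []
    for rec in fp.records:
        b = rec.bond
        rows.append({
            "structure": fp.structure_id,
            "protein_chain": b.protein_res.chain_id,
            "protein_resi": b.protein_res.seq_id,
            "protein_resn": b.protein_res.res_name,
            "protein_atom": b.protein_atom.name,
            "domain": rec.domain or "",
            "strand": rec.label.strand,
            "position": rec.label.position_label,
            "moiety": rec.label.moiety,
            "partner_resn": b.partner_res.res_name,
            "partner_resi": b.partner_res.seq_id,
            "partner_atom": b.partner_atom.name,
            "distance": round(b.distance, 3),
            "mediation": b.mediation,
            "class": b.klass,
            "leg_distances": ";".join(f"{d:.3f}" for d in b.leg_distances)
            if b.leg_distances else "",
        })
    return pd.DataFrame(rows)


def plot_fingerprint(fp: Fingerprint, path=None):
    """Interaction-grid plot: positions on x, protein residues on y, marker
    style by bond class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    styles = {"direct-strong": ("o", "black"), "direct-weak": ("o", "grey"),
              "water-strong": ("s", "royalblue"),
              "water-weak": ("s", "lightsteelblue")}
    xs = sorted({r.label.position_label for r in fp.records})
    ys = sorted({f"{r.bond.protein_res.res_name}"
                 f"{r.bond.protein_res.seq_id}" for r in fp.records})
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(xs)),
                                    max(3, 0.25 * len(ys))))
    for rec in fp.records:
        marker, color = styles[rec.bond.klass]
        ax.scatter(xs.index(rec.label.position_label),
                   ys.index(f"{rec.bond.protein_res.res_name}"
                            f"{rec.bond.protein_res.seq_id}"),
                   marker=marker, color=color, s=40)
    ax.set_xticks(range(len(xs)), xs, rotation=90)
    ax.set_yticks(range(len(ys)), ys, fontsize=6)
    ax.set_xlabel("strand position")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
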