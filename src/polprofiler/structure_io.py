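"""Structure reading/writing, entity classification and atom selection.

The in-memory model is a deliberately small hierarchy (Structure -> Residue
-> Atom) built on top of gemmi's PDB/mmCIF parsers.  Author residue
numbering is canonical throughout, because the literature on these enzymes
cites author numbers (D404, E580, ...).  Each residue carries exactly one
entity class from {protein, dna, water, metal, dntp_ligand, other}.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

import gemmi
import numpy as np

from . import chemtables as ct


class ParseError(ValueError):
    pass


class FormatError(ValueError):
    pass


class LookupError_(KeyError):
    """Missing atom/residue lookup."""


class SelectionSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    entity: str = "other"
    incomplete_sugar: bool = False

    def atom(self, name: str, altloc: str | None = None) -> Atom:
        """Return the named atom.

        If several altlocs exist for the name, an explicit ``altloc`` is
        required: silent ambiguity would make B-factor and distance lookups
        ill-defined.
        """
        hits = [a for a in self.atoms if a.name == name]
        if altloc is not None:
            hits = [a for a in hits if a.altloc == altloc]
        if not hits:
            raise LookupError_(
                f"no atom {name!r} (altloc={altloc!r}) in "
                f"{self.chain_id}/{self.res_name}{self.seq_id}")
        if len(hits) > 1:
            raise LookupError_(
                f"atom {name!r} in {self.chain_id}/{self.res_name}"
                f"{self.seq_id} has {len(hits)} altlocs; pass altloc=")
        return hits[0]

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)

    def centroid(self, names: Iterable[str] | None = None) -> np.ndarray:
        sel = [a.coords for a in self.atoms
               if names is None or a.name in set(names)]
        if not sel:
            raise LookupError_(f"no atoms {names} in {self.key}")
        return np.mean(sel, axis=0)


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def residues_of(self, entity: str | None = None,
                    chain: str | None = None) -> list[Residue]:
        return [r for r in self.residues
                if (entity is None or r.entity == entity)
                and (chain is None or r.chain_id == chain)]

    def residue(self, chain: str, seq_id: int,
                insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain, seq_id, insertion_code):
                return r
        raise LookupError_(f"no residue {chain}/{seq_id}{insertion_code}")

    def entity_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.residues:
            out[r.entity] = out.get(r.entity, 0) + 1
        return out


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a classified Structure.

    All ATOM/HETATM records of the first model are kept, including alternate
    conformers.  Entity classes are assigned on the way out.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise FormatError(f"unknown format {format!r}")
    except FormatError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError with line info
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    out = Structure(id=st.name or path.stem)
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    model = st[0]
    for chain in model:
        for res in chain:
            residue = Residue(
                chain_id=chain.name,
                seq_id=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                res_name=res.name.strip(),
            )
            for at in res:
                element = at.element.name.upper().strip()
                residue.atoms.append(Atom(
                    serial=at.serial,
                    name=at.name.strip(),
                    element=element or _infer_element(at.name),
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    b_factor=at.b_iso,
                    altloc=(at.altloc or "").strip("\x00 "),
                ))
            out.residues.append(residue)
    return classify_entities(out)


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write the structure as a standard PDB file (used for fixtures)."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = 0
    for res in s.residues:
        if res.chain_id not in chains:
            chains[res.chain_id] = gemmi.Chain(res.chain_id)
        g_res = gemmi.Residue()
        g_res.name = res.res_name
        g_res.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
        g_res.het_flag = "A" if res.entity == "protein" else "H"
        for atom in res.atoms:
            serial += 1
            g_at = gemmi.Atom()
            g_at.name = atom.name
            g_at.serial = atom.serial or serial
            g_at.element = gemmi.Element(atom.element.capitalize())
            g_at.pos = gemmi.Position(*np.round(atom.coords, 3))
            g_at.occ = atom.occupancy
            g_at.b_iso = atom.b_factor
            g_at.altloc = atom.altloc or "\x00"
            g_res.add_atom(g_at)
        chains[res.chain_id].add_residue(g_res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def structure_summary(s: Structure) -> dict:
    """JSON-ready summary (entity counts, chains, atom count)."""
    return {
        "id": s.id,
        "n_residues": len(s.residues),
        "n_atoms": s.n_atoms,
        "chains": s.chains(),
        "entity_counts": s.entity_counts(),
    }


def write_summary(s: Structure, path: str | Path) -> None:
    Path(path).write_text(json.dumps(structure_summary(s), indent=2))


# ---------------------------------------------------------------------------
# entity classification
# ---------------------------------------------------------------------------

_SUGAR_SET = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'"}


def classify_entities(s: Structure) -> Structure:
    """Assign one entity class per residue.

    Name tables first, then atom-content heuristics: a residue carrying
    triphosphate atom names (PA/PB/PG or O1A..O3G) is a dNTP-like ligand; a
    single metallic atom is a metal; unmatched residues become "other".
    """
    for res in s.residues:
        names = {a.name for a in res.atoms}
        name = res.res_name.upper()
        if name in ct.WATER_RESIDUES:
            res.entity = "water"
        elif name in ct.METAL_RESIDUES and len(
                {a.element for a in res.atoms}) == 1 and len(res.atoms) <= 2:
            res.entity = "metal"
        elif names & ct.TRIPHOSPHATE_ATOMS or name in ct.DNTP_RESIDUES:
            res.entity = "dntp_ligand"
        elif name in ct.AMINO_ACIDS:
            res.entity = "protein"
        elif name in ct.DNA_RESIDUES:
            res.entity = "dna"
            res.incomplete_sugar = not _SUGAR_SET <= names
        elif _SUGAR_SET <= names and ("P" in names or "O3'" in names):
            res.entity = "dna"
        elif len(res.atoms) == 1 and res.atoms[0].element in ct.METAL_RESIDUES:
            res.entity = "metal"
        elif {"N", "CA", "C"} <= names:
            res.entity = "protein"
        else:
            res.entity = "other"
    return s


# ---------------------------------------------------------------------------
# altloc policy: geometry stages see a single conformer per atom name
# ---------------------------------------------------------------------------

def prune_altlocs(s: Structure) -> Structure:
    """Keep the highest-occupancy conformer per atom name (tie -> altloc A).

    Returns a new Structure; distance-based classification must be
    single-valued, so all geometry stages run on the pruned model.
    """
    out = Structure(id=s.id)
    for res in s.residues:
        new = Residue(res.chain_id, res.seq_id, res.res_name, [],
                      res.insertion_code, res.entity, res.incomplete_sugar)
        by_name: dict[str, list[Atom]] = {}
        for atom in res.atoms:
            by_name.setdefault(atom.name, []).append(atom)
        for name, group in by_name.items():
            best = sorted(group,
                          key=lambda a: (-a.occupancy, a.altloc or "A"))[0]
            new.atoms.append(best)
        out.residues.append(new)
    return out


def strip_hydrogens(s: Structure) -> Structure:
    out = Structure(id=s.id)
    for res in s.residues:
        new = Residue(res.chain_id, res.seq_id, res.res_name,
                      [a for a in res.atoms if a.element not in ("H", "D")],
                      res.insertion_code, res.entity, res.incomplete_sugar)
        out.residues.append(new)
    return out


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class Selection:
    structure: Structure
    expression: str
    pairs: list[tuple[Residue, Atom]]

    @property
    def atoms(self) -> list[Atom]:
        return [a for _, a in self.pairs]

    def coords(self) -> np.ndarray:
        if not self.pairs:
            return np.zeros((0, 3))
        return np.array([a.coords for _, a in self.pairs])

    def __len__(self) -> int:
        return len(self.pairs)


def select(s: Structure, expr: str) -> Selection:
    """Evaluate a small selection language over the structure.

    Grammar: or-separated groups of and-separated terms; a term is
    ``key=value`` with key in {name, element, entity, chain, resi, resn} or
    the bare word ``calpha``; ``resi`` accepts ``N`` or ``N-M`` ranges; any
    term may be prefixed with ``not``.  Matching is deterministic and
    preserves file order.
    """
    predicate = _parse_expression(expr)
    pairs = [(res, atom) for res, atom in s.atoms() if predicate(res, atom)]
    return Selection(structure=s, expression=expr, pairs=pairs)


def _parse_expression(expr: str) -> Callable[[Residue, Atom], bool]:
    if not expr.strip():
        raise SelectionSyntaxError("empty expression", 0)
    or_groups = []
    for group in expr.split(" or "):
        terms = []
        for raw in group.split(" and "):
            pos = expr.find(raw.strip())
            terms.append(_parse_term(raw.strip(), max(pos, 0)))
        or_groups.append(terms)

    def predicate(res: Residue, atom: Atom) -> bool:
        return any(all(t(res, atom) for t in terms) for terms in or_groups)

    return predicate


def _parse_term(term: str, pos: int) -> Callable[[Residue, Atom], bool]:
    negate = False
    while term.startswith("not "):
        negate = not negate
        term = term[4:].strip()
    if term == "calpha":
        base = lambda r, a: r.entity == "protein" and a.name == "CA"
    elif "=" in term:
        key, _, value = term.partition("=")
        key, value = key.strip(), value.strip()
        if not value:
            raise SelectionSyntaxError(f"missing value in {term!r}", pos)
        if key == "name":
            base = lambda r, a, v=value: a.name == v
        elif key == "element":
            base = lambda r, a, v=value.upper(): a.element == v
        elif key == "entity":
            base = lambda r, a, v=value: r.entity == v
        elif key == "chain":
            base = lambda r, a, v=value: r.chain_id == v
        elif key == "resn":
            base = lambda r, a, v=value.upper(): r.res_name.upper() == v
        elif key == "resi":
            lo, hi = _parse_range(value, pos)
            base = lambda r, a, lo=lo, hi=hi: lo <= r.seq_id <= hi
        else:
            raise SelectionSyntaxError(f"unknown key {key!r}", pos)
    else:
        raise SelectionSyntaxError(f"cannot parse term {term!r}", pos)
    if negate:
        return lambda r, a, b=base: not b(r, a)
    return base


def _parse_range(value: str, pos: int) -> tuple[int, int]:
    try:
        if "-" in value and not value.startswith("-"):
            lo_s, _, hi_s = value.partition("-")
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(value)
    except ValueError:
        raise SelectionSyntaxError(f"bad residue range {value!r}", pos)
    if hi < lo:
        raise SelectionSyntaxError(f"inverted range {value!r}", pos)
    return lo, hi


# ---------------------------------------------------------------------------
# B-factor lookup
# ---------------------------------------------------------------------------

def atom_bfactor(s: Structure, chain: str, resi: int, name: str,
                 altloc: str | None = None) -> float:
    """Stored isotropic B-factor of one atom (ambiguous altloc -> error)."""
    res = s.residue(chain, resi)
    return res.atom(name, altloc=altloc).b_factor
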