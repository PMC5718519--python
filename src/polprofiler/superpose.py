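"""Calpha pairing and least-squares superposition with outlier rejection.

Pairing is sequence-based: a global alignment of the one-letter sequences
(BLOSUM62, gap open -10, gap extend -0.5 by default) yields Calpha pairs at
aligned non-gap columns.  The rigid fit is the closed-form Kabsch solution;
``refine_superposition`` then iterates fit / reject (deviation greater than
``cutoff_rms`` times the current RMSD) / refit, the convention used to
report "RMSD over N Calpha atoms" for polymerase comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import chemtables as ct
from .domain_model import DomainMap
from .structure_io import Atom, Residue, Structure


class PairingError(ValueError):
    pass


class FitError(ValueError):
    pass


@dataclass
class PairedAtoms:
    pairs: list[tuple[Atom, Atom]]
    residues: list[tuple[Residue, Residue]]
    provenance: str  # "seq-align" | "index" | "user-map"
    identity: float  # identical residue pairs / aligned non-gap columns

    def __len__(self) -> int:
        return len(self.pairs)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        xa = np.array([a.coords for a, _ in self.pairs]).reshape(-1, 3)
        xb = np.array([b.coords for _, b in self.pairs]).reshape(-1, 3)
        return xa, xb

    def subset(self, keep: np.ndarray) -> "PairedAtoms":
        idx = np.flatnonzero(keep)
        return PairedAtoms(
            pairs=[self.pairs[i] for i in idx],
            residues=[self.residues[i] for i in idx],
            provenance=self.provenance,
            identity=self.identity,
        )


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # (3,3), det +1
    translation: np.ndarray    # (3,)
    rmsd: float
    n_pairs_initial: int
    n_pairs_final: int
    rejected: list[tuple[Residue, Residue]] = field(default_factory=list)
    cycles_run: int = 0
    identity: float | None = None

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def _calpha_residues(s: Structure, chain: str | None = None
                     ) -> list[Residue]:
    return [r for r in s.residues
            if r.entity == "protein" and r.has_atom("CA")
            and (chain is None or r.chain_id == chain)]


def _sequence(residues: list[Residue]) -> str:
    return "".join(ct.AA_THREE_TO_ONE.get(r.res_name.upper(), "X")
                   for r in residues)


def _aligner(matrix: str, gap_open: float, gap_extend: float
             ) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pair_calpha(a: Structure, b: Structure, mode: str = "seq-align",
                matrix: str = "BLOSUM62", gap_open: float = -10.0,
                gap_extend: float = -0.5) -> PairedAtoms:
    """Pair Calpha atoms between two structures.

    ``seq-align`` aligns the one-letter sequences globally and pairs
    Calphas at aligned non-gap columns; ``index`` pairs residues in file
    order (the fixture path).  Multi-chain proteins are paired greedily by
    best alignment score.
    """
    chains_a = [c for c in a.chains() if _calpha_residues(a, c)]
    chains_b = [c for c in b.chains() if _calpha_residues(b, c)]
    if not chains_a or not chains_b:
        raise PairingError("both structures need at least one protein chain")

    if mode == "index":
        ra, rb = _calpha_residues(a), _calpha_residues(b)
        n = min(len(ra), len(rb))
        residues = list(zip(ra[:n], rb[:n]))
        ident = sum(x.res_name == y.res_name for x, y in residues) / n
        return PairedAtoms(
            pairs=[(x.atom("CA"), y.atom("CA")) for x, y in residues],
            residues=residues, provenance="index", identity=ident)
    if mode != "seq-align":
        raise PairingError(f"unknown pairing mode {mode!r}")

    aligner = _aligner(matrix, gap_open, gap_extend)
    # greedy chain pairing by best alignment score
    scored = []
    for ca in chains_a:
        for cb in chains_b:
            sa = _sequence(_calpha_residues(a, ca))
            sb = _sequence(_calpha_residues(b, cb))
            scored.append((aligner.score(sa, sb), ca, cb))
    scored.sort(key=lambda t: -t[0])
    used_a: set[str] = set()
    used_b: set[str] = set()
    chain_pairs = []
    for _, ca, cb in scored:
        if ca in used_a or cb in used_b:
            continue
        chain_pairs.append((ca, cb))
        used_a.add(ca)
        used_b.add(cb)

    residues: list[tuple[Residue, Residue]] = []
    n_cols = 0
    n_ident = 0
    for ca, cb in chain_pairs:
        res_a = _calpha_residues(a, ca)
        res_b = _calpha_residues(b, cb)
        alignment = aligner.align(_sequence(res_a), _sequence(res_b))[0]
        for (sa, ea), (sb, eb) in zip(*alignment.aligned):
            for i, j in zip(range(sa, ea), range(sb, eb)):
                n_cols += 1
                if res_a[i].res_name == res_b[j].res_name:
                    n_ident += 1
                residues.append((res_a[i], res_b[j]))
    if not residues:
        raise PairingError("empty alignment: no Calpha pairs")
    return PairedAtoms(
        pairs=[(x.atom("CA"), y.atom("CA")) for x, y in residues],
        residues=residues,
        provenance="seq-align",
        identity=n_ident / n_cols,
    )


# ---------------------------------------------------------------------------
# Kabsch fit
# ---------------------------------------------------------------------------

def kabsch_fit(pairs: PairedAtoms) -> SuperpositionResult:
    """Closed-form least-squares rigid fit of the first member onto the
    second; RMSD is computed on all supplied pairs."""
    if len(pairs) < 3:
        raise FitError(f"need >= 3 pairs, got {len(pairs)}")
    xa, xb = pairs.coords()
    rotation, translation, rmsd = _kabsch(xa, xb)
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd,
        n_pairs_initial=len(pairs), n_pairs_final=len(pairs),
        cycles_run=0, identity=pairs.identity)


def _kabsch(xa: np.ndarray, xb: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    pa, pb = xa - ca, xb - cb
    # degenerate geometry: a (near-)collinear point set leaves the rotation
    # about that axis undetermined
    for pts in (pa, pb):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-8 * max(sv[0], 1.0):
            raise FitError("degenerate (collinear) point set")
    h = pa.T @ pb
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cb - rotation @ ca
    diff = xa @ rotation.T + translation - xb
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return rotation, translation, rmsd


# ---------------------------------------------------------------------------
# iterative outlier rejection
# ---------------------------------------------------------------------------

def refine_superposition(pairs: PairedAtoms, cutoff_rms: float = 2.0,
                         cycles: int = 5) -> SuperpositionResult:
    """Fit / reject / refit.

    Per cycle: fit on the surviving pairs, compute per-pair deviations,
    drop pairs deviating more than ``cutoff_rms`` times the current RMSD,
    refit.  Stops after ``cycles`` cycles or when nothing is rejected.  The
    reported RMSD covers surviving pairs only.
    """
    current = pairs
    rejected: list = []
    result = kabsch_fit(current)
    cycle = 0
    for cycle in range(1, cycles + 1):
        xa, xb = current.coords()
        dev = np.linalg.norm(
            xa @ result.rotation.T + result.translation - xb, axis=1)
        keep = dev <= cutoff_rms * max(result.rmsd, 1e-12)
        if keep.all():
            break
        if keep.sum() < 3:
            raise FitError("outlier rejection removed (nearly) all pairs")
        rejected.extend(r for r, k in zip(current.residues, keep) if not k)
        current = current.subset(keep)
        result = kabsch_fit(current)
    return SuperpositionResult(
        rotation=result.rotation, translation=result.translation,
        rmsd=result.rmsd, n_pairs_initial=len(pairs),
        n_pairs_final=len(current), rejected=rejected,
        cycles_run=cycle, identity=pairs.identity)


# ---------------------------------------------------------------------------
# domain-restricted comparison
# ---------------------------------------------------------------------------

def _restrict(s: Structure, dmap: DomainMap, domain: str,
              structure_id: str | None = None) -> Structure:
    sid = structure_id or s.id
    ranges = dmap.domain_ranges(sid, domain)
    out = Structure(id=s.id)
    for res in s.residues:
        if any(res.chain_id == c and lo <= res.seq_id <= hi
               for c, lo, hi in ranges):
            out.residues.append(res)
    return out


def domain_rmsd(a: Structure, b: Structure, dmap: DomainMap, domain: str,
                mode: str = "seq-align", cutoff_rms: float = 2.0,
                cycles: int = 5, id_a: str | None = None,
                id_b: str | None = None) -> SuperpositionResult:
    """Pairing and refined superposition restricted to one domain."""
    sub_a = _restrict(a, dmap, domain, id_a)
    sub_b = _restrict(b, dmap, domain, id_b)
    if not sub_a.residues or not sub_b.residues:
        raise PairingError(f"domain {domain!r} resolves to no residues")
    pairs = pair_calpha(sub_a, sub_b, mode=mode)
    return refine_superposition(pairs, cutoff_rms=cutoff_rms, cycles=cycles)
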