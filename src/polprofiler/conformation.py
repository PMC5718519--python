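"""Open/closed domain-motion analysis.

The mobile (finger) domain's closure is measured by superposing the two
structures on a core (every protein residue outside the mobile domain, with
outlier rejection), then rigid-fitting the mobile-domain Calphas of the
core-superposed structures.  The residual rotation's angle,
arccos((trace(R) - 1) / 2), is the closure angle; its axis is the screw
axis.  Per-residue Calpha displacements after core superposition quantify
how far individual residues travel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain_model import DomainMap
from .structure_io import Structure
from .superpose import (FitError, SuperpositionResult, pair_calpha,
                        refine_superposition, _restrict)


@dataclass
class RotationReport:
    angle: float                 # degrees, in [0, 180]
    axis: np.ndarray             # unit 3-vector
    core_rmsd: float
    mobile_rmsd: float
    core_result: SuperpositionResult
    displacements: dict[tuple[str, int, str], float] = field(
        default_factory=dict)


def rotation_angle_axis(rotation: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (deg) and unit axis of a proper rotation matrix."""
    cos_theta = np.clip((np.trace(rotation) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_theta)))
    # axis from the skew-symmetric part; falls back to the +1 eigenvector
    w = np.array([rotation[2, 1] - rotation[1, 2],
                  rotation[0, 2] - rotation[2, 0],
                  rotation[1, 0] - rotation[0, 1]])
    norm = np.linalg.norm(w)
    if norm > 1e-9:
        return angle, w / norm
    eigvals, eigvecs = np.linalg.eig(rotation)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    axis = np.real(eigvecs[:, idx])
    return angle, axis / np.linalg.norm(axis)


def _complement_domain(s: Structure, dmap: DomainMap, mobile: str,
                       structure_id: str | None = None) -> Structure:
    """All protein residues outside the mobile domain."""
    sid = structure_id or s.id
    ranges = dmap.domain_ranges(sid, mobile)
    out = Structure(id=s.id)
    for res in s.residues:
        if res.entity != "protein":
            continue
        if any(res.chain_id == c and lo <= res.seq_id <= hi
               for c, lo, hi in ranges):
            continue
        out.residues.append(res)
    return out


def domain_rotation(open_s: Structure, closed_s: Structure, dmap: DomainMap,
                    mobile: str, core: str | None = None,
                    mode: str = "seq-align", cutoff_rms: float = 2.0,
                    cycles: int = 5, id_open: str | None = None,
                    id_closed: str | None = None) -> RotationReport:
    """Closure rotation of ``mobile`` after superposition on ``core``.

    ``core=None`` uses every protein residue outside the mobile domain.
    """
    ido = id_open or open_s.id
    idc = id_closed or closed_s.id
    if core is None:
        core_open = _complement_domain(open_s, dmap, mobile, ido)
        core_closed = _complement_domain(closed_s, dmap, mobile, idc)
    else:
        core_open = _restrict(open_s, dmap, core, ido)
        core_closed = _restrict(closed_s, dmap, core, idc)
    core_pairs = pair_calpha(core_open, core_closed, mode=mode)
    core_fit = refine_superposition(core_pairs, cutoff_rms=cutoff_rms,
                                    cycles=cycles)

    mobile_open = _restrict(open_s, dmap, mobile, ido)
    mobile_closed = _restrict(closed_s, dmap, mobile, idc)
    mobile_pairs = pair_calpha(mobile_open, mobile_closed, mode=mode)
    if len(mobile_pairs) < 3:
        raise FitError("mobile domain has fewer than 3 Calpha pairs")
    xa, xb = mobile_pairs.coords()
    xa_core = core_fit.transform(xa)  # open coords in the closed frame
    residual = _fit_arrays(xa_core, xb)
    angle, axis = rotation_angle_axis(residual.rotation)

    displacements = {
        res_a.key: float(np.linalg.norm(xa_core[i] - xb[i]))
        for i, (res_a, _) in enumerate(mobile_pairs.residues)
    }
    return RotationReport(angle=angle, axis=axis,
                          core_rmsd=core_fit.rmsd,
                          mobile_rmsd=residual.rmsd,
                          core_result=core_fit,
                          displacements=displacements)


def _fit_arrays(xa: np.ndarray, xb: np.ndarray) -> SuperpositionResult:
    from .superpose import _kabsch

    rotation, translation, rmsd = _kabsch(xa, xb)
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_pairs_initial=len(xa),
                               n_pairs_final=len(xa))


def residue_displacements(open_s: Structure, closed_s: Structure,
                          dmap: DomainMap | None = None,
                          core_mobile: str | None = None,
                          residues: list[int] | None = None,
                          chain: str | None = None,
                          mode: str = "seq-align",
                          id_open: str | None = None,
                          id_closed: str | None = None
                          ) -> dict[tuple[str, int, str], float | None]:
    """Per-residue Calpha displacement after core superposition.

    ``core_mobile`` names the mobile domain excluded from the core fit
    (requires ``dmap``); with neither, the whole protein is the core.
    Residues missing from either structure are reported as None, not zero.
    """
    ido = id_open or open_s.id
    idc = id_closed or closed_s.id
    if core_mobile is not None:
        if dmap is None:
            raise ValueError("core_mobile requires a domain map")
        core_open = _complement_domain(open_s, dmap, core_mobile, ido)
        core_closed = _complement_domain(closed_s, dmap, core_mobile, idc)
    else:
        core_open, core_closed = open_s, closed_s
    core_fit = refine_superposition(pair_calpha(core_open, core_closed,
                                                mode=mode))

    all_pairs = pair_calpha(open_s, closed_s, mode=mode)
    out: dict[tuple[str, int, str], float | None] = {}
    xa, xb = all_pairs.coords()
    xa = core_fit.transform(xa)
    paired_keys = set()
    for i, (res_a, _) in enumerate(all_pairs.residues):
        paired_keys.add(res_a.key)
        out[res_a.key] = float(np.linalg.norm(xa[i] - xb[i]))
    if residues is not None:
        filtered: dict[tuple[str, int, str], float | None] = {}
        for r in open_s.residues_of("protein"):
            if residues and r.seq_id in residues and \
                    (chain is None or r.chain_id == chain):
                filtered[r.key] = out.get(r.key)
        for seq in residues:
            if not any(k[1] == seq for k in filtered):
                filtered[(chain or "?", seq, "")] = None
        return filtered
    return out
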