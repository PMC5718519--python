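"""Named domain definitions (residue ranges) per structure.

DNA-polymerase structures are conventionally split into N-terminal,
exonuclease, finger, palm and thumb domains (plus the exonuclease
beta-hairpin).  Boundaries are configuration, not computation: they ship as
a default map derived from the deposited archaeal B-family entries and are
always user-overridable.  Every domain-dependent result should echo the
ranges used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .structure_io import Selection, Structure


class DomainConfigError(ValueError):
    pass


class DomainLookupError(KeyError):
    pass


Range = tuple[str, int, int]  # (chain, start, end) inclusive


@dataclass
class DomainMap:
    # structure id -> domain name -> list of (chain, start, end)
    ranges: dict[str, dict[str, list[Range]]] = field(default_factory=dict)

    def domains(self, structure_id: str) -> dict[str, list[Range]]:
        if structure_id not in self.ranges:
            raise DomainLookupError(f"no domain map for {structure_id!r}")
        return self.ranges[structure_id]

    def domain_ranges(self, structure_id: str, domain: str) -> list[Range]:
        domains = self.domains(structure_id)
        if domain not in domains:
            raise DomainLookupError(
                f"domain {domain!r} undefined for {structure_id!r}")
        return domains[domain]

    def domain_of(self, structure_id: str, chain: str,
                  seq_id: int) -> str | None:
        """Name of the domain containing (chain, seq_id), or None."""
        try:
            domains = self.domains(structure_id)
        except DomainLookupError:
            return None
        for name, ranges in domains.items():
            for c, lo, hi in ranges:
                if c == chain and lo <= seq_id <= hi:
                    return name
        return None


def load_domain_map(source: str | Path | dict) -> DomainMap:
    """Load and validate a YAML/JSON-style domain map.

    Layout: ``domains: {<structure id>: {<domain>: [[chain, start, end], ...]}}``.
    Overlapping ranges within one domain are a configuration error; unknown
    structure ids are allowed (they are resolved lazily).
    """
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = source
    if not isinstance(data, dict):
        raise DomainConfigError("domain config must be a mapping")
    body = data.get("domains", data)
    out = DomainMap()
    for sid, domains in body.items():
        if not isinstance(domains, dict):
            raise DomainConfigError(f"{sid}: expected domain mapping")
        parsed: dict[str, list[Range]] = {}
        for name, ranges in domains.items():
            norm: list[Range] = []
            for rng in ranges:
                if len(rng) != 3:
                    raise DomainConfigError(
                        f"{sid}/{name}: range must be [chain, start, end]")
                chain, lo, hi = str(rng[0]), int(rng[1]), int(rng[2])
                if hi < lo:
                    raise DomainConfigError(
                        f"{sid}/{name}: range end {hi} < start {lo}")
                norm.append((chain, lo, hi))
            for i, (c1, lo1, hi1) in enumerate(norm):
                for c2, lo2, hi2 in norm[i + 1:]:
                    if c1 == c2 and lo1 <= hi2 and lo2 <= hi1:
                        raise DomainConfigError(
                            f"{sid}/{name}: overlapping ranges "
                            f"{(c1, lo1, hi1)} / {(c2, lo2, hi2)}")
            parsed[name] = norm
        out.ranges[sid] = parsed
    return out


def default_domain_map() -> DomainMap:
    """Domain map shipped with the package (archaeal B-family numbering)."""
    with resources.files("polprofiler.data").joinpath(
            "domains_default.yaml").open() as fh:
        return load_domain_map(yaml.safe_load(fh))


def residues_in(dmap: DomainMap, structure: Structure, domain: str,
                structure_id: str | None = None) -> Selection:
    """Deterministic selection of all atoms in a named domain."""
    sid = structure_id or structure.id
    ranges = dmap.domain_ranges(sid, domain)
    pairs = []
    for res in structure.residues:
        for chain, lo, hi in ranges:
            if res.chain_id == chain and lo <= res.seq_id <= hi:
                pairs.extend((res, a) for a in res.atoms)
                break
    return Selection(structure=structure, expression=f"domain={domain}",
                     pairs=pairs)
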