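#!/usr/bin/env python
"""Optional helper: download the deposited comparison entries.

The library itself never fetches anything; this thin script populates
data/pdb/ so the deposited-structure acceptance tests can run.  The binary
(open-conformation) KOD entry used for the closure comparison is not part
of the ternary-complex depositions; supply its accession with
--binary-kod and the file is stored as kod_binary.cif.
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

ENTRIES = ["5OMF", "5OMQ", "5OMV", "3IAY", "3NCI", "3RTV"]
URL = "https://files.rcsb.org/download/{}.cif"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--outdir", type=Path,
                        default=Path(__file__).resolve().parent.parent
                        / "data" / "pdb")
    parser.add_argument("--binary-kod", default=None,
                        help="accession of the open/binary KOD entry")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    targets = [(e, f"{e.lower()}.cif") for e in ENTRIES]
    if args.binary_kod:
        targets.append((args.binary_kod.upper(), "kod_binary.cif"))
    for entry, filename in targets:
        dest = args.outdir / filename
        if dest.exists():
            print(f"{dest} exists, skipping")
            continue
        print(f"fetching {entry} -> {dest}")
        urllib.request.urlretrieve(URL.format(entry), dest)


if __name__ == "__main__":
    main()
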