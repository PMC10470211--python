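#!/usr/bin/env python
"""Fetch the reference depositions used by the accession-based analyses.

Downloads the carotenoprotein heterodimer (8I34), beta-crustacyanin (1GKA)
and the ependymin-related protein dimer (6E8N) from the PDB into
``data/reference/``.  Requires network access; the coordinate files are not
distributed with this package.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

PDB_IDS = ["8I34", "1GKA", "6E8N"]
URL = "https://files.rcsb.org/download/{pdb_id}.cif"


def main() -> int:
    out_dir = Path("data") / "reference"
    out_dir.mkdir(parents=True, exist_ok=True)
    for pdb_id in PDB_IDS:
        dest = out_dir / f"{pdb_id}.cif"
        if dest.exists():
            print(f"{dest} already present")
            continue
        url = URL.format(pdb_id=pdb_id)
        print(f"fetching {url} -> {dest}")
        try:
            urllib.request.urlretrieve(url, dest)
        except OSError as exc:
            print(f"failed to fetch {pdb_id}: {exc}", file=sys.stderr)
            return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
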