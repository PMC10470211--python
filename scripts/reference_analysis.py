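#!/usr/bin/env python
"""Run the accession-based structural analyses on locally fetched depositions.

Usage::

    python scripts/fetch_reference_data.py        # once, needs network
    python scripts/reference_analysis.py [--out results/reference.json]

Prints the descriptors of the carotenoprotein heterodimer (8I34), the
beta-crustacyanin comparison (1GKA) and the dimer superposition against the
ependymin-related protein (6E8N).
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from carotenostruct import reference
from carotenostruct.structure_io import _round_floats


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=None)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    bcp = reference.load_reference_structure("8I34", args.data_dir)
    cru = reference.load_reference_structure("1GKA", args.data_dir)
    epdr1 = reference.load_reference_structure("6E8N", args.data_dir)
    report = {
        "carotenoprotein_8I34": reference.analyze_carotenoprotein(bcp),
        "crustacyanin_1GKA": reference.analyze_crustacyanin(cru),
        "dimer_vs_EPDR1_6E8N": reference.compare_dimers(bcp, epdr1),
    }
    text = json.dumps(_round_floats(report), indent=2)
    if args.out:
        args.out.parent.mkdir(parents=True, exist_ok=True)
        args.out.write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
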