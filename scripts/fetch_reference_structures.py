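#!/usr/bin/env python
"""Download the two published reference structures used by the optional
end-to-end-distance acceptance test.

Usage:
    python scripts/fetch_reference_structures.py

Requires network access. Fetches PDB entries 6NTS (compact conformer) and
1B3U (extended conformer) from the RCSB file server into data/reference/,
where tests/test_acceptance.py::test_criterion_2_reference_end_to_end_distances
expects them. The files are not redistributed with the package.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

REFERENCE_DIR = Path(__file__).resolve().parents[1] / "data" / "reference"
ENTRIES = ("6nts", "1b3u")
URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def main() -> int:
    REFERENCE_DIR.mkdir(parents=True, exist_ok=True)
    failures = 0
    for pdb_id in ENTRIES:
        dest = REFERENCE_DIR / f"{pdb_id}.pdb"
        if dest.exists():
            print(f"{dest} already present, skipping")
            continue
        url = URL.format(pdb_id=pdb_id.upper())
        print(f"fetching {url} -> {dest}")
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                dest.write_bytes(resp.read())
        except OSError as exc:
            print(f"error: could not fetch {pdb_id}: {exc}",
                  file=sys.stderr)
            failures += 1
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
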