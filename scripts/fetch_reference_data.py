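"""Download the deposited reference structures and SAXS profile.

Optional helper: the library itself never touches the network, and no
test depends on these files.  Run it once to populate ``reference_data/``
for the full complex analysis (see examples/kif2a_tubulin.yaml):

    python scripts/fetch_reference_data.py --dest reference_data

Entries fetched:
  6BBN  kinesin-13 Kif2A-NM bound to two tubulin dimers + DARPin cap
  2GRY  isolated ADP-bound Kif2A motor domain (apo comparator)
  5MIO  Kif2C (MCAK) - tubulin - DARPin complex
  4EB6  stathmin - tubulin - vinblastine complex
  1JFF  straight-protofilament tubulin (zinc-sheet)
  4HNA  kinesin-1 - tubulin complex
  SASDCR9  SEC-SAXS profile of the 1:2:1 complex (SASBDB)
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

PDB_IDS = ["6BBN", "2GRY", "5MIO", "4EB6", "1JFF", "4HNA"]
PDB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"
SASBDB_URL = "https://www.sasbdb.org/media/intensities_files/SASDCR9.dat"


def fetch(url: str, dest: Path) -> None:
    if dest.exists():
        print(f"  {dest} exists, skipping")
        return
    print(f"  {url} -> {dest}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path, default=Path("reference_data"))
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for pdb_id in PDB_IDS:
        fetch(PDB_URL.format(pdb_id=pdb_id), args.dest / f"{pdb_id.lower()}.cif")
    fetch(SASBDB_URL, args.dest / "sasdcr9.dat")
    print("done")


if __name__ == "__main__":
    main()
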