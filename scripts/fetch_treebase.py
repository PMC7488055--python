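#!/usr/bin/env python
"""One-time download of the study's deposited alignment matrices.

Fetches the four per-locus matrices of TreeBase study TB2:S26825 and
writes them as FASTA under data/treebase/, where the deposited-matrix
acceptance test expects them.  Needs network access; everything else in
the test suite runs offline.

Usage:
    python scripts/fetch_treebase.py [--out data/treebase]
"""

from __future__ import annotations

import argparse
import io
import os
import re
import urllib.request

STUDY_URL = "http://purl.org/phylo/treebase/phylows/study/TB2:S26825"
MATRIX_URL = "http://purl.org/phylo/treebase/phylows/matrix/{mid}?format=nexus"


def fetch(url: str) -> bytes:
    req = urllib.request.Request(url, headers={"User-Agent": "coaldelim"})
    with urllib.request.urlopen(req, timeout=120) as resp:
        return resp.read()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="data/treebase")
    args = parser.parse_args()
    os.makedirs(args.out, exist_ok=True)

    page = fetch(STUDY_URL + "?format=html").decode("utf-8", "replace")
    matrix_ids = sorted(set(re.findall(r"matrix/(TB2:M\d+)", page)))
    if not matrix_ids:
        raise SystemExit(
            "no matrix identifiers found on the study page; TreeBase may "
            "have changed its layout -- download the matrices manually and "
            f"place them under {args.out}/"
        )
    from Bio import AlignIO

    for mid in matrix_ids:
        raw = fetch(MATRIX_URL.format(mid=mid)).decode("utf-8", "replace")
        msa = AlignIO.read(io.StringIO(raw), "nexus")
        name = mid.replace(":", "_")
        out_path = os.path.join(args.out, f"{name}.fasta")
        with open(out_path, "w") as fh:
            for rec in msa:
                fh.write(f">{rec.id}\n{rec.seq}\n")
        print(f"wrote {out_path} ({len(msa)} taxa x {msa.get_alignment_length()} columns)")


if __name__ == "__main__":
    main()
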