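#!/usr/bin/env python
"""Fetch the three public microarray CSVs (colon, leukemia, prostate)
from the PMC supplementary archive into data/.

These are third-party data and are not redistributed with the package;
run this once (network required) before the real-data reproduction tests.

Usage:  python scripts/fetch_datasets.py [--dest data]
"""

import argparse
import urllib.request
from pathlib import Path

BASE = "https://www.ncbi.nlm.nih.gov/pmc/articles/PMC7842997/bin"
FILES = {
    "leukemia.csv": f"{BASE}/pone.0246039.s001.csv",  # 72 x 3572
    "colon.csv": f"{BASE}/pone.0246039.s002.csv",     # 62 x 2000
    "prostate.csv": f"{BASE}/pone.0246039.s003.csv",  # 102 x 6033
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path, default=Path("data"))
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for name, url in FILES.items():
        target = args.dest / name
        if target.exists():
            print(f"{target} already present, skipping")
            continue
        print(f"fetching {url} -> {target}")
        urllib.request.urlretrieve(url, target)
    print("done")


if __name__ == "__main__":
    main()
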