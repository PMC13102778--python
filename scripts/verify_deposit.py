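"""Check a locally downloaded copy of the public spheroid dataset manifest.

The full dataset (bright-field images + manifest CSV) is deposited at
doi:10.5281/zenodo.15120118.  This script takes the path to the downloaded
manifest and verifies the published dataset counts: 2,359 labeled images
overall, the per-domain totals (A: 1,022, B: 712, C: 245, D: 380), and —
when a study-date mapping is supplied — the domain-A chronological
train+validation/test split of 777/245 images at the 2022-07-28 cutoff.

This is an optional, network-dependent check; nothing in the package or its
test suite requires the download.

Usage:
    python scripts/verify_deposit.py /path/to/manifest.csv \
        [--study-dates study_dates.csv]
"""

from __future__ import annotations

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

EXPECTED_LABELED = 2359
EXPECTED_PER_DOMAIN = {"A": 1022, "B": 712, "C": 245, "D": 380}
EXPECTED_DOMAIN_A_SPLIT = (777, 245)
CUTOFF = "2022-07-28"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("manifest", help="Path to the deposited manifest CSV.")
    parser.add_argument("--study-dates", default=None,
                        help="Optional CSV with columns study,date mapping "
                             "each study id to its start date.")
    args = parser.parse_args()

    import pandas as pd

    from spherovia.manifest import read_manifest
    from spherovia.model import chronological_split

    records = read_manifest(args.manifest)
    labeled = [r for r in records if r.labeled]
    ok = True

    def check(name, got, want):
        nonlocal ok
        status = "OK " if got == want else "FAIL"
        if got != want:
            ok = False
        print(f"[{status}] {name}: got {got}, expected {want}")

    check("labeled images", len(labeled), EXPECTED_LABELED)
    for domain, want in EXPECTED_PER_DOMAIN.items():
        got = sum(1 for r in labeled if r.domain == domain)
        check(f"domain {domain} labeled images", got, want)

    if args.study_dates:
        dates = pd.read_csv(args.study_dates)
        order = dict(zip(dates["study"].astype(str), dates["date"].astype(str)))
        df = pd.DataFrame({
            "Study": [r.study for r in labeled if r.domain == "A"],
        })
        train_df, test_df = chronological_split(df, cutoff=CUTOFF,
                                                study_order=order)
        check("domain A train+val images", len(train_df),
              EXPECTED_DOMAIN_A_SPLIT[0])
        check("domain A test images", len(test_df), EXPECTED_DOMAIN_A_SPLIT[1])
    else:
        print("[SKIP] domain A chronological split "
              "(provide --study-dates to check 777/245)")

    return 0 if ok else 1


if __name__ == "__main__":
    raise SystemExit(main())
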