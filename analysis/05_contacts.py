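#!/usr/bin/env python
"""Hydrogen-bond and salt-bridge detection on planted contact geometries.

Builds minimal donor/acceptor and charged-pair fixtures at controlled
distances and angles, sweeps them through the geometric contact criteria
(3.5 Å / 120° for hydrogen bonds, 4.0 Å for salt bridges), and records the
detected occupancies — including a fractional-occupancy trajectory alternating
between bonded and broken geometries.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from helixnet import (
    Trajectory,
    detect_hbonds,
    detect_salt_bridges,
    make_contact_fixture,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for distance, angle in [(2.7, 170.0), (2.9, 165.0), (3.4, 130.0),
                            (2.9, 100.0), (4.5, 165.0)]:
        fixture = make_contact_fixture("hbond", distance, angle)
        found = [r for r in detect_hbonds(fixture) if r.donor[2] == "OG"]
        rows.append({"kind": "hbond", "distance_A": distance,
                     "angle_deg": angle, "detected": bool(found),
                     "occupancy": found[0].occupancy if found else 0.0})
    for distance in (3.0, 3.5, 3.9, 4.5, 6.0):
        fixture = make_contact_fixture("saltbridge", distance)
        found = detect_salt_bridges(fixture)
        rows.append({"kind": "saltbridge", "distance_A": distance,
                     "angle_deg": np.nan, "detected": bool(found),
                     "occupancy": found[0].occupancy if found else 0.0})

    # alternating bonded/broken frames: occupancy equals the bonded fraction
    near = make_contact_fixture("hbond", 2.9, 165.0)
    far = make_contact_fixture("hbond", 4.5, 165.0)
    frames = np.array([near.coordinates] * 3 + [far.coordinates] * 1)
    rec = [r for r in detect_hbonds(Trajectory(near, frames))
           if r.donor[2] == "OG"][0]
    rows.append({"kind": "hbond-trajectory", "distance_A": 2.9,
                 "angle_deg": 165.0, "detected": True,
                 "occupancy": rec.occupancy})

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "05_contacts.csv", index=False, float_format="%.4g")
    n_hb = int(table[table.kind == "hbond"]["detected"].sum())
    n_sb = int(table[table.kind == "saltbridge"]["detected"].sum())
    print(f"hydrogen bonds detected in {n_hb}/5 planted geometries "
          "(long distance and closed D-H...A angle correctly rejected)")
    print(f"salt bridges detected in {n_sb}/5 planted distances "
          "(cutoff 4.0 Å)")
    print(f"3:1 bonded/broken trajectory occupancy: {rec.occupancy:.2f}")
    print(f"table: {RESULTS/'05_contacts.csv'}")


if __name__ == "__main__":
    main()
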