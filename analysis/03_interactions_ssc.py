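#!/usr/bin/env python
"""Interface interactions and helical content over the stable windows.

For each run: hydrogen-bond and hydrophobic-contact occupancy tables
(3.2 A / 120 deg and 3.5-5.5 A criteria), the central-helix contact census
at the 10% occupancy threshold with the A1-balance verdict, and per-segment
plus accumulated secondary-structure content.  Results land under
results/03_interactions/.
"""

import json
from pathlib import Path

import dimerdyn as dd
from dimerdyn import interactions as ia
from dimerdyn import secondary_structure as ssm
from dimerdyn import stability, structures as st, tables

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "03_interactions"
INTERVAL_PS = 100.0


def main():
    topo, _ = st.read_structure(ROOT / "01_runs" / "topology.pdb")
    helix_set = st.HelixSet.from_dict(
        json.loads((ROOT / "01_runs" / "helix_set.json").read_text()))
    OUT.mkdir(parents=True, exist_ok=True)
    for dcd in sorted((ROOT / "01_runs").glob("*.dcd")):
        name = dcd.stem
        traj = st.read_trajectory(dcd, topo, INTERVAL_PS)
        win = json.loads(
            (ROOT / "02_stability" / f"{name}_window.json").read_text())
        window = stability.StableWindow(win["start_frame"], win["end_frame"],
                                        win["span_ns"])
        hb = ia.hbond_occupancy(traj, window)
        hi = ia.hydrophobic_occupancy(traj, window)
        census = ia.contact_census(hb, hi, helix_set,
                                   occupancy_threshold_percent=10.0)
        labels = ssm.assign(traj, window)
        ssc = ssm.ssc(labels, topo, helix_set)
        tables.save_occupancy_table(hb, OUT / f"{name}_hbonds.csv")
        tables.save_occupancy_table(hi, OUT / f"{name}_contacts.csv")
        (OUT / f"{name}_census.json").write_text(
            json.dumps(census.to_dict(), indent=2))
        (OUT / f"{name}_ssc.json").write_text(json.dumps(ssc, indent=2))
        inter_hb = hb[(hb.res1 <= 913) != (hb.res2 <= 913)]
        strongest = inter_hb.iloc[0] if len(inter_hb) else None
        print(f"{name}: census total {census.total} "
              f"(intersubunit {census.intersubunit}, A1 balance "
              f"{census.a1_balance}); accumulated SSC "
              f"{ssc['accumulated']:.1f}%"
              + (f"; strongest interchain H-bond {int(strongest.res1)}-"
                 f"{int(strongest.res2)} at {strongest.occupancy:.1f}%"
                 if strongest is not None else ""))


if __name__ == "__main__":
    main()
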