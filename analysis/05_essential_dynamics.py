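#!/usr/bin/env python
"""Essential dynamics of the runs: PCA-1, PCA-2 and the combined PCA-3.

PCA-1 decomposes the global C-alpha fluctuations, PCA-2 the central-helix
fluctuations (both on up to 2,500 uniformly sampled window frames); their
eigenvalue spectra and the r^2 between the runs' PC1 time series quantify
how similar the concerted motions are.  PCA-3 pools the 6 inter-helix
centroid distances of all runs into one plane so the runs' projection
clouds (centroid separation, dispersion) can be compared directly.
Outputs under results/05_ed/.
"""

import json
from pathlib import Path

import numpy as np

import dimerdyn as dd
from dimerdyn import essential_dynamics as ed
from dimerdyn import stability, structures as st, tables

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "05_ed"
INTERVAL_PS = 100.0


def main():
    topo, _ = st.read_structure(ROOT / "01_runs" / "topology.pdb")
    helix_set = st.HelixSet.from_dict(
        json.loads((ROOT / "01_runs" / "helix_set.json").read_text()))
    ca = topo.ca_indices
    helix_resids = {r for seg in st.HelixSet.SEGMENTS
                    for r in helix_set.residues(seg)}
    central = np.array([i for i in ca
                        if int(topo.dimer_resid[i]) in helix_resids])
    OUT.mkdir(parents=True, exist_ok=True)
    pc1_series, features = {}, {}
    for dcd in sorted((ROOT / "01_runs").glob("*.dcd")):
        name = dcd.stem
        traj = st.read_trajectory(dcd, topo, INTERVAL_PS)
        win = json.loads(
            (ROOT / "02_stability" / f"{name}_window.json").read_text())
        window = stability.StableWindow(win["start_frame"], win["end_frame"],
                                        win["span_ns"])
        pca1 = ed.pca_cartesian(traj, window, ca)
        pca2 = ed.pca_cartesian(traj, window, central)
        tables.save_modeset_summary(pca1, OUT / f"{name}_pca1_spectrum.csv")
        tables.save_modeset_summary(pca2, OUT / f"{name}_pca2_spectrum.csv")
        ed.export_mode_animation(pca2, topo, traj.coords[window.start_frame],
                                 0, 3.0, 7, OUT / f"{name}_pca2_mode1.pdb",
                                 OUT / f"{name}_pca2_mode1_arrows.csv")
        pc1_series[name] = pca1.projections[:, 0]
        features[name] = ed.helix_distance_features(traj, helix_set,
                                                    stride=1, window=window)
        print(f"{name}: PC1 explains {100 * pca1.explained_fraction[0]:.1f}% "
              f"(global) / {100 * pca2.explained_fraction[0]:.1f}% "
              f"(central helices); top eigenvalue "
              f"{pca2.eigenvalues[0]:.2f} A^2")
    names = sorted(pc1_series)
    if len(names) == 2:
        r2 = ed.pc_correlation(pc1_series[names[0]], pc1_series[names[1]])
        print(f"r^2 of PC1 projections {names[0]} vs {names[1]}: {r2:.3f}")
        (OUT / "pc1_r2.json").write_text(json.dumps(
            {"pair": names, "r2": r2}))
    joint = ed.pca_features(features)
    for name in names:
        np.savetxt(OUT / f"{name}_pca3_projections.csv",
                   joint.projections[name], delimiter=",",
                   header="pc1,pc2", comments="")
    summary = {"explained_variance_ratio":
               joint.explained_variance_ratio.tolist(),
               "dispersion": joint.dispersion,
               "centroid_separation":
               joint.centroid_separation(*names) if len(names) == 2 else None}
    (OUT / "pca3_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"PCA-3: 2 components explain "
          f"{100 * joint.explained_variance_ratio.sum():.1f}% of the "
          f"inter-helix distance variance; dispersions "
          + ", ".join(f"{n}={joint.dispersion[n]:.2f}" for n in names))


if __name__ == "__main__":
    main()
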