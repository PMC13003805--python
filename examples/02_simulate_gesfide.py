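"""Simulate pre/post-contrast GESFIDE signals from a vascular network.

The susceptibility difference created by an intravascular iron-oxide agent
(Δχ = 1e-6 at 3 T) perturbs the field around the vessels; diffusing spins
(D = 1e-3 mm²/s) dephase in that field.  The 18-echo ratio curve samples the
free induction decay up to 60 ms and the refocused decay thereafter, with
the pure spin echo at 120 ms.  From the curve the contrast-induced rate
changes ΔR2*, ΔR2 and the analytical vessel size index follow.
"""

from vsdprint import (
    SimulationConfig,
    VoxelGrid,
    VsiParams,
    delta_r2,
    delta_r2_star,
    generate_network,
    simulate_gesfide,
    vsi_histo,
    vsi_mri,
)

grid = VoxelGrid((32, 32, 32), voxel_size=221.4 / 32)  # coarse partial-volume grid
cfg = SimulationConfig(dt=2.5e-3)

for target_cbv in (0.03, 0.10, 0.20):
    volume, truth = generate_network(
        grid, target_cbv, {"kind": "uniform", "low": 4.0, "high": 10.0}, seed=1
    )
    curve = simulate_gesfide(volume, cfg)
    dr2s, dr2 = delta_r2_star(curve), delta_r2(curve)
    vsi = vsi_mri(dr2s, dr2, VsiParams())
    print(
        f"CBV {100 * volume.cbv:5.2f}%: ratio@60ms={curve.at(0.060):.3f} "
        f"ratio@120ms={curve.at(0.120):.3f}  ΔR2*={dr2s:6.1f} s⁻¹  "
        f"ΔR2={dr2:5.1f} s⁻¹  VSI_MRI={vsi:5.2f} µm  "
        f"VSI_Histo={vsi_histo(truth.true_vsd):5.2f} µm"
    )
# denser vasculature dephases more spins: the ratio at every echo drops and
# both rate changes grow with CBV; the two VSI estimates need not agree at
# this sub-voxel scale (the analytic formula assumes many sparse cylinders)
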