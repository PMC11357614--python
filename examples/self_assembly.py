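"""Run one small self-assembly simulation and characterize the micelles.

A 100-chain BAB solution at reduced temperature 0.5 (below the transition)
assembles into spherical micelles within a couple hundred tau; the morphology
summary reports how much hydrophobe mass sits in spheres vs worms and the
mean core diameters in units of the bead size sigma.
"""

from triblock import RunConfig, run, summarize_trajectory
from triblock.phase_diagram import topology_for_ratio

config = RunConfig(
    topology=topology_for_ratio(0.75),  # 2 N_B / N_A = 0.75, as in the phase diagram
    n_chains=100,
    temperature=0.5,
    n_warmup=1_000,
    n_equil=40_000,
    n_prod=4_000,
    stride=2_000,
    seed=7,
)
traj = run(config, xyz_path="self_assembly.xyz")
summary = summarize_trajectory(traj)
print(f"frames: {len(traj.frames)}, box edge: {traj.frames[0].box_edge:.2f} sigma")
print(f"worm mass fraction: {summary.worm_mass_fraction:.2f} "
      f"(0 = all spheres, 1 = all worms)")
print(f"mean sphere core diameter: {summary.mean_sphere_diameter} sigma")
print(f"mean worm core diameter:   {summary.mean_worm_diameter} sigma")
print("trajectory written to self_assembly.xyz (extended XYZ)")
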