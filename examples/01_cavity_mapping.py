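"""Map a docking volume with both cavity-mapping algorithms.

Builds a toy pocket (a spherical carbon shell with an opening), then maps
its interior with the two-probe-sphere method and, separately, with the
reference-ligand method around a small molecule placed at the centre.
"""

from gadock.cavity import map_reference_ligand, map_two_sphere
from gadock.fixtures import make_toy_cage, make_toy_ligand

receptor = make_toy_cage(seed=7, pocket_radius=6.0, n_shell_atoms=150,
                         polar_sites=4, jitter=0.05)
print(f"toy receptor: {receptor.molecule.n_atoms} atoms")

grid = map_two_sphere(receptor, center=(0, 0, 0), search_radius=8.0,
                      r_large=4.0, r_small=1.5, spacing=0.5)
print(f"two-probe cavity: {grid.n_inside} grid points, "
      f"volume {grid.volume:.0f} A^3")
# the volume is the sheltered interior of the shell that a 1.5 A probe can
# reach but a 4 A probe rolled in from outside cannot

ligand = make_toy_ligand(seed=3, n_heavy=5, n_rotatable=1,
                         features=("neutral HBD",))
grid_ref = map_reference_ligand(receptor, ligand, radius=6.0, spacing=0.5)
print(f"reference-ligand cavity (6 A): {grid_ref.n_inside} grid points, "
      f"volume {grid_ref.volume:.0f} A^3")
# accessible volume within 6 A of the reference ligand's heavy atoms;
# this is the default way a known binding site is turned into a docking
# volume when a bound ligand is available
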