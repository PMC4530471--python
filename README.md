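# structloc

Integrative structural localization: where does a protein domain sit inside
a large assembly, and does an independent fluorescence measurement agree?

`structloc` is for structural biologists who have (a) an atomic structure of
a domain, (b) a 3D density map of the full assembly at intermediate
resolution, and (c) optionally, FRET measurements from labelled accessory
proteins — and who want to place the domain, cross-validate the placement,
and quantify the supporting biochemistry. It was built around the kind of
study where a receptor domain (e.g. a ryanodine-receptor SPRY domain) is
docked into cryo-EM maps, its position validated by FRET trilateration from
FKBP labelling sites, and characterized by thermal-shift and binding assays.

## What it computes

**Rigid-body docking.** An unbiased six-dimensional search: a deterministic
near-uniform orientation grid (super-Fibonacci quaternions at a chosen
angular step), FFT translation scan per orientation, Pearson correlation
scoring, clustering, and ranking by normalized correlation
(cc / cc of hit 1). Optional Laplacian filtering of both maps adds penalties
for mismatched surface features. Local Nelder-Mead refinement polishes any
pose and never returns a score below its start.

**FRET distances and trilateration.** Acceptor-photobleach efficiency
E = 1 − F_pre/F_post and the Förster relation

    R = R0 · (1/E − 1)^(1/6),        E = 1 / (1 + (R/R0)^6)

with R0 = 59 Å for the AF488/Cy3NTA pair by default, plus first-order
uncertainty propagation. The acceptor locus is the intersection of
spherical shells around the donors (exported as an MRC volume), and a
weighted least-squares point estimate with mirror-ambiguity detection for
the 3-donor case. A uniform accessible-volume sampler models dye positions
around an attachment atom.

**Model comparison.** Kabsch superposition, per-residue RMSD profiles
(Cα / backbone / all-heavy), Shrake-Rupley solvent-accessible surface area,
interface burial (half the SASA lost on complexation) with VDW contact
lists, and per-secondary-structure-element map correlation.

**Assay fits.** Melting temperatures from the normalized first derivative
of thermal-shift curves, with multi-transition detection by peak prominence;
one-site saturation binding (K_d, B_max); single-exponential dissociation
(k_off = 1/τ).

**Synthetic data.** Generators for toy multi-helix structures, blurred noisy
maps, FRET panels from a known acceptor, melt curves, and binding series —
each carrying its ground truth, each bit-reproducible from its seed.

## Worked example

Dock a toy 3-helix domain into a noisy synthetic map (SNR 2, 6 Å), then
localize a synthetic acceptor from five FRET donors:

```python
import numpy as np
from structloc import exhaustive_search, refine_pose, measurements_to_constraints
from structloc.docking import rotation_angle_deg
from structloc.synthetic import (make_toy_structure, simulate_noisy_map,
                                 simulate_fret_dataset, DEFAULT_DONOR_SITES,
                                 DEFAULT_ACCEPTOR)
from structloc.trilateration import shell_locus, point_estimate

domain = make_toy_structure(n_helices=3, helix_length=20, seed=2)
density, truth = simulate_noisy_map(domain, resolution=6.0, voxel=1.5,
                                    snr=2.0, seed=5)
result = exhaustive_search(density, domain, resolution=6.0, angular_step=20.0)
pose, cc = refine_pose(density, domain, result.hits[0].pose, resolution=6.0)

donors = [DEFAULT_DONOR_SITES[k] for k in DEFAULT_DONOR_SITES]
measurements, _ = simulate_fret_dataset(donors, DEFAULT_ACCEPTOR,
                                        noise_sd_efficiency=0.05, n_cells=30,
                                        seed=1,
                                        site_names=list(DEFAULT_DONOR_SITES))
constraints = measurements_to_constraints(measurements, DEFAULT_DONOR_SITES,
                                          forster_radius=59.0)
locus = shell_locus(constraints, grid_step=2.0, tolerance_scale=2.0)
est = point_estimate(constraints)
```

Output:

```
top hit cc = 0.734 (normalized 1.0)
refined pose: 0.34 deg, 0.04 A from the generative pose; cc = 0.752
  D32: R = 48.7 +/- 0.3 A
  D44: R = 68.3 +/- 0.5 A
  D49: R = 47.0 +/- 0.4 A
  D85: R = 56.6 +/- 0.3 A
  D97: R = 54.2 +/- 0.4 A
locus volume = 128 A^3; contains true acceptor: True
point estimate error = 0.39 A (rms residual 0.08 A)
```

Reading this: the exhaustive search's best cluster scores cc 0.734 against
the noisy map (normalized 1.0 by definition), and refinement lands 0.34° /
0.04 Å from the pose the map was generated at. The five donor-site mean
efficiencies convert to distances of 47-68 Å; the shells intersect in a
128 Å³ locus that contains the true acceptor position, and the
least-squares point estimate is 0.39 Å from it.

The same stages are available from the shell:

```bash
structloc --seed 1 simulate-data --kind map --out demo/
structloc dock --map demo/map.mrc --model demo/structure.pdb \
          --resolution 6 --step 20 --top 10 --out demo/hits.csv
structloc fret-distances --in fret_means.csv --r0 59 --out constraints.csv
structloc trilaterate --constraints constraints.csv --donors donors.csv \
          --grid 2 --out locus.mrc
structloc melt-tm --in melt.csv --out tm.json
structloc binding-fit --mode saturation --in saturation.csv --out fit.json
```

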