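# mpioct

Simulation, marker tracking and motion-compensated volume reconstruction
for rotational-pullback intravascular imaging guided by a volumetric
tracking modality.

A catheter with a trackable tip marker is rotated and pulled back through a
straight stenosis phantom while two synchronized devices acquire data: a
volumetric scanner imaging the marker as a compact bright blob at ~46 Hz,
and a rotational probe acquiring 91 kHz depth profiles (A-scans) of the
vessel wall. The package simulates both data streams for configurable
catheter motion profiles (constant pullback, bending-artifact and
heart-beat-artifact profiles), localizes the marker per frame with
sub-voxel accuracy, and compares two ways of arranging the A-scan wall
distances into a 3D/4D boundary point cloud:

* **IP** (input parameters): ideal helix assuming constant pullback and
  rotation speeds.
* **MT** (marker tracking): A-scans distributed along the tracked axial
  catheter trajectory using trigger-based time synchronization.

Reconstructions are quantified against the known phantom geometry with a
projected-silhouette Dice coefficient (mean over 180 projection angles),
a full-width-at-half-maximum stenosis length, and trajectory MAE /
per-segment velocity-regression errors.

## Modules

| module                 | responsibility |
| ---------------------- | -------------- |
| `mpioct.phantom_sim`   | phantom geometry, motion profiles, synthetic image series and A-scan streams, first-peak boundary segmentation |
| `mpioct.mpi_recon`     | synthetic system matrix, Tikhonov-regularized Kaczmarz solver, temporal block averaging |
| `mpioct.tracking`      | threshold segmentation, connected-region selection, centre-of-mass localization, trajectory cleaning (running median + windowed RANSAC + smoothing) |
| `mpioct.reconstruction`| time synchronization, IP and MT point-cloud reconstruction |
| `mpioct.quantify`      | envelopes, projected shapes, Dice, stenosis length, trajectory errors |
| `mpioct.cli`           | `mpioct` command-line interface |
| `mpioct.pipeline`      | end-to-end experiment runner and replicate aggregation |
| `mpioct.io`            | HDF5 image series, CSV trajectories/clouds/A-scans, YAML configs |

## CLI

```sh
mpioct simulate --profile SP --seed 1 --out-dir scratch/run   # series + A-scans
mpioct track scratch/run/series_SP_seed1.h5 --out scratch/run/traj.csv
mpioct reconstruct scratch/run/ascans_SP_seed1.csv --method mt \
    --trajectory scratch/run/traj.csv --out scratch/run/cloud.csv
mpioct quantify scratch/run/cloud.csv
mpioct pipeline --out-dir scratch/study          # full replicate study
mpioct recon measurement.h5 --iterations 3 --lambda-rel 1e-3
```

`mpioct pipeline --config run.yaml` accepts a YAML file with the
`RunConfig` fields (profiles, seeds, phantom overrides, noise levels,
crop window, output directory).

## File formats

* Image series: HDF5 with a `/frames` dataset `(T, X, Y, Z)`, attributes
  `voxel_size`, `origin`, `frame_rate`, and a `/timestamps` dataset.
  Voxel index `i` maps to world coordinate `origin + (i + 0.5) * voxel_size`.
* Trajectories: CSV `time_s, x_mm, y_mm, z_mm, valid`.
* Point clouds: CSV `x_mm, y_mm, z_mm, t_s`.
* A-scan streams: CSV `time_s, r_mm, valid`.
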