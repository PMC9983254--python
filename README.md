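# jointcal

Calibration toolkit for robotic joint-testing rigs that pair a six-axis robot
with an optical 3D tracker. It implements the full calibration chain needed to
let a robot reproduce manually recorded joint motion:

* **geometry** — coordinate-frame data model; estimation of the
  optical→robot transformation by zero-point shifting both pose recordings and
  solving the unconstrained least-squares map `T = R·Aᵀ·(A·Aᵀ)⁻¹`.
* **spherefit** — algebraic sphere fitting of joint trajectories: one-shot
  linear least squares, exact four-point solves over all `C(n,4)`
  combinations, and an iterative SD-threshold rejection scheme that averages
  the surviving combination fits (robust to gross outliers) and grades how
  sphere-like the trajectory is.
* **calibration** — the three-stage pipeline: plane fitting of the robot's
  calibration pose groups and robot-world origin reconstruction, tool center
  point (TCP = joint rotation center) and length-of-tool (LOT) computation,
  and point-by-point trajectory transformation for non-spherical joints.
* **metrics** — the report statistics (population SD, even-n median of
  deviations, signed extreme deviations, mounting-grid normalization) and
  trajectory reproduction accuracy (per-axis + Euclidean deviations).
* **synthetic** — seeded, ground-truthed generator emulating the rig:
  paired calibration poses under a hidden rigid motion, spheroidal manual
  trajectories with configurable noise and outliers.
* **io / cli** — CSV/JSON readers and writers and the `jointcal` command.

All lengths are millimetres; standard deviations use divisor `n` throughout.

## Command line

```sh
# generate a ground-truthed synthetic dataset
jointcal simulate --seed 7 --noise-sd 0.1 --out data/

# run the calibration pipeline (ball-joint route)
jointcal calibrate --robot-poses data/robot_poses.csv \
    --optical-poses data/optical_poses.csv \
    --manual data/manual_trajectory.csv \
    --method tcp_lot --k-sd 1.0 --iterations 4 --out result.json

# robust sphere fit of a single trajectory
jointcal spherefit data/manual_trajectory.csv

# compare a reference vs a reproduced trajectory
jointcal compare manual.csv reproduced.csv --pairing arclength
```

Marker CSV schema: `frame,pose_index,x_mm,y_mm,z_mm[,alpha_deg,beta_deg,gamma_deg]`,
header required, dot decimals. Orientation angles are carried as metadata but
do not enter any computation.

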