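# crowdvis

Vision-based modelling of human collective motion ("flocking") in crowds.

A walking agent is steered not by its neighbours' physical positions and
velocities, but by what it can *see*: the angular velocity, optical
expansion/contraction, eccentricity and visibility of each neighbour's
body. `crowdvis` implements

- **optics** — first-person optical variables of a neighbour: distance,
  bearing, eccentricity β (right-positive), visual angle θ = 2·atan(w/2d),
  angular velocity ψ̇ and expansion rate θ̇;
- **visibility** — 2-D occlusion geometry: each neighbour's visibility
  fraction v ∈ [0, 1] under occlusion by nearer bodies and a field-of-view
  filter, thresholded at v_t = 0.15, plus an independent ray-casting oracle
  and a crowd-opacity range measure;
- **control** — the visual control laws
  (`φ̈ = −c1·cosβ·ψ̇ + c2·sinβ·θ̇`, `r̈ = −c3·sinβ·ψ̇ − c4·cosβ·θ̇`
  with c1=14.38, c2=59.71, c3=0.18, c4=0.72), combined across neighbours by
  visibility-weighted averaging, and an omniscient baseline that relaxes
  toward the distance-weighted mean heading/speed of neighbours within a
  4 m cutoff;
- **simulator** — fixed-step integration (semi-implicit Euler at 60 Hz,
  RK4 for convergence checks) for scripted-crowd trials, swarm replay with
  a simulated focal walker, and fully coupled multi-agent simulation;
- **scenarios** — virtual-crowd perturbation layouts (single row at
  1.8–8 m, three rows of four with selective row perturbation, the
  5-near/7-far two-row layout with heading ±10° or speed ±0.3 m/s
  perturbations), plus seeded synthetic-swarm and dense-crowd generators;
- **metrics** — final heading (circular mean over the last 2 s),
  left/right collapsing, zero-phase low-pass filtering, heading/speed RMSE,
  mean position error, linear-fit range extrapolation, polarization;
- **io / cli** — a plain-text trajectory table format
  (`time_s, agent_id, x_m, y_m, heading_deg, speed_mps`) and a command-line
  interface.

## CLI

```sh
# one trial: a row of 4 neighbours at 1.8 m turns 10 deg right after 5 s
crowdvis simulate --scenario exp1 --crowd-size 4 --distance 1.8 --out out/

# full factor grid of the three-row layout, both models
crowdvis experiment exp2 --model visual --model omniscient --out out/

# emit a seeded synthetic swarm, then replay its hindmost walker
crowdvis fixtures --n-agents 10 --duration 10 --seed 3 --out out/
crowdvis replay out/swarm.csv --model visual --out out/

# compare two trajectory files
crowdvis metrics out/swarm.csv out/swarm.csv
```

Headings in files and reports are degrees, measured from the forward
walking direction with positive values to the right; internally all
angles are radians.

## Conventions

- World frame: metres; internal headings are CCW radians from +x; trial
  scenarios walk along +y.
- Optical frame: eccentricity and angular velocity are positive to the
  observer's right.
- Bodies are discs of diameter 0.4 m; equidistant bodies do not occlude
  each other; occluders outside the field of view still occlude bodies
  inside it.
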