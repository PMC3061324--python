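# symbem

A symmetric boundary element (BEM) forward solver for bioelectromagnetism:
given a nested triangulated head model with piecewise-constant
conductivities, it computes EEG, MEG, EIT and intracranial-potential lead
fields, and validates them against analytic multilayer-sphere solutions
with the RDM/MAG accuracy metrics.

Both the potential (piecewise linear, P1) and the normal current
(piecewise constant, P0) are discretized on every interface, producing a
symmetric block system. Singular Galerkin integrals use closed-form
triangle potentials with adaptive outer quadrature.

## Layout

| module | contents |
|---|---|
| `symbem.mesh` | triangle meshes, icosphere / random sphere generators, validation, nesting checks, sources and sensors |
| `symbem.operators` | single/double-layer and hypersingular Galerkin operators, analytic triangle integrals, adaptive quadrature, mass matrices |
| `symbem.assembly` | head matrix (+ conductivity decomposition), dipole/surface/EIT source matrices, sensor transfer matrices |
| `symbem.gain` | head-matrix inversion and the four lead fields |
| `symbem.sphere` | analytic multilayer-sphere references (EEG series, dipole-in-sphere magnetic field, EIT Neumann series, interior potentials) |
| `symbem.metrics`, `symbem.benchmark` | RDM/MAG and the sphere benchmark harness (regular + random meshes) |
| `symbem.io`, `symbem.cli` | `.tri`/`.geom`/`.cond`/ASCII-matrix/sensor text formats and the command line |

## Command line

The workflow mirrors an assemble → invert → combine pipeline; matrices are
exchanged as ASCII files:

```sh
symbem make-sphere scalp.tri --radius 0.1 --level 2
symbem assemble -HeadMat model.geom model.cond hm.mat
symbem minverser hm.mat hminv.mat
symbem assemble -DipSourceMat model.geom model.cond dipoles.txt dsm.mat
symbem assemble -Head2EEGMat model.geom model.cond electrodes.txt h2e.mat
symbem gain -EEG hminv.mat dsm.mat h2e.mat lead_field.mat
```

Assemble options: `-HeadMat`, `-DipSourceMat`, `-SurfSourceMat`,
`-Head2EEGMat`, `-Head2MEGMat`, `-DipSource2MEGMat`, `-SurfSource2MEGMat`,
`-EITSourceMat`, `-Head2InternalPotMat`, `-DipSource2InternalPotMat`;
gain modalities: `-EEG` (also used for EIT), `-MEG`, `-InternalPotential`.
`--no-adaptive` switches off adaptive integration; `--tol` sets its
tolerance.

File formats (documented in `symbem/io.py`): BrainVisa-style `.tri`
meshes; a versioned `.geom`/`.cond` dialect for the nested model; plain
text dipole (`x y z qx qy qz`), electrode (`[name] x y z`, plus a current
column for EIT) and MEG (`x y z dx dy dz [weight] [channel]`) files;
ASCII matrices with a `rows cols [symmetric]` header.

## Benchmark

```sh
symbem benchmark out.csv --level 3                      # regular meshes
symbem benchmark out.csv --mesh-type random --random-n 600 --n-models 20
```

runs the three-sphere benchmark (radii 0.088/0.092/0.100 m, conductivities
1, 1/80, 1 S/m, five z-axis dipoles with orientation (1,0,1)) and scores
every lead-field column against the analytic solution.

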