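# tubekin

Quantitative analysis of folding tube-shaped epithelia — covariant tissue
kinematics on evolving surfaces, material-frame shear, cell-shape and
rearrangement statistics, calcium-transient quantification, and the
comparison statistics used in mutant analyses.  A synthetic-data generator
with analytic ground truth stands in for light-sheet recordings, so every
stage of the pipeline is testable against closed forms.

The motivating system is the embryonic *Drosophila* midgut: a bilayer tube
(circumferential visceral muscle wrapping an endodermal epithelium) that
subdivides into chambers through localized constrictions.  The package is
written for anyone analyzing Lagrangian surface meshes of a deforming
tubular organ together with cell segmentations, nuclei tracks, and
fluorescence movies.

## The quantities it computes

**Incompressible surface kinematics.**  On a deforming surface with inward
normal velocity $v_n$ and tangential velocity $\mathbf{v}_\parallel$, local
area conservation couples out-of-plane to in-plane motion through the mean
curvature $H$:

$$2 H v_n = \nabla \cdot \mathbf{v}_\parallel .$$

The residual $\nabla\cdot\mathbf{v}_\parallel - 2Hv_n$ equals the local
relative area growth rate $\mathrm{d}\ln A/\mathrm{d}t$.  `tubekin.kinematics`
computes both sides discretely (cotangent Laplace–Beltrami curvature,
P1 finite-element covariant divergence), averages them in non-overlapping
chart patches, and reports their pooled correlation and slope.

**Material-frame shear.**  Anisotropic deformation is measured against a
conformal (isotropy-normalized) chart fixed at the onset of the first
constriction.  All anisotropy of the induced metric $g'$ is encoded in the
Beltrami coefficient

$$\mu = \frac{g'_{11} - g'_{22} + 2 i\, g'_{12}}
            {g'_{11} + g'_{22} + 2\sqrt{\det g'}},\qquad
  K = \frac{1+|\mu|}{1-|\mu|},$$

where $K$ is the axis ratio of the image ellipse of an infinitesimal
circle and $\arg\mu/2$ its orientation.  `tubekin.shear` builds the
material chart, evaluates per-face $\mu(t)$, and produces circumferentially
averaged kymographs.

**Cell shapes.**  Segmented polygons in chart coordinates are embedded on
the surface, projected on the local tangent frame $(\hat s, \hat\phi)$, and
summarized by the second-moment shape tensor with eigenvalues
$I_1 \ge I_2$: aspect ratio $a/b = \sqrt{I_1/I_2}$ and orientation
$\theta$.  Population statistics are area-weighted,

$$\langle a/b\rangle = \frac{\sum_i A_i\, a_i/b_i}{\sum_i A_i},\qquad
  \langle\theta\rangle = \arctan\!\left[\frac{\sum_i A_i \sin\theta_i}
  {\sum_i A_i \cos\theta_i}\right],$$

with standard errors from a subsample-size-extrapolated bootstrap.
`tubekin.cells` also detects T1 neighbor exchanges, tracks cell areas, and
quantifies relative motion of muscle–endoderm nuclei pairs.

**Calcium transients.**  Triplets of frames seconds apart are reduced to
$\delta I = |I_1-I_2| + |I_2-I_3| + |I_1-I_3|$, cleaned with a Gaussian
blur and white top-hat, summed along the circumferential axis into AP
profiles, normalized per embryo as
$\delta I \to (\delta I - \delta I_{bg})/(\delta I_{max} - \delta I_{bg})$,
and assembled into onset-aligned kymographs (`tubekin.calcium`).

**Comparison statistics** (`tubekin.stats`): the two-sample z-score
$Z = (\bar x_a - \bar x_b)/\sqrt{s_a^2/n_a + s_b^2/n_b}$, its one-sided
normal p-value $p = \tfrac12\,\mathrm{erfc}(-Z/\sqrt2)$, the Bernoulli
proportion SE $\sqrt{\hat p(1-\hat p)/N}$, and fold-count comparisons.

## Worked example

The default pipeline generates an axisymmetric tube (rest radius 30 µm,
length 200 µm) developing one Gaussian constriction to 60 % depth over
30 one-minute steps under an exactly area-preserving Lagrangian flow, runs
the kinematic, shear and cell-shape stages, and writes tidy CSVs plus a
JSON report:

```bash
tubekin run --seed 1 --out demo/
```

prints (abridged):

```json
{
 "kinematics": {"pearson_r": 0.9976, "slope": 1.0121, "max_abs_residual": 0.0021},
 "shear": {"max_abs_mu_final": 0.679, "peak_s": 90.6},
 "cells": {"n_cells": 602, "weighted_mean_aspect": 2.509, "bootstrap_se": 0.010}
}
```

Reading the numbers: the out-of-plane deformation $2Hv_n$ and in-plane
divergence correlate at 99.8 % with slope ≈ 1 across 320 patches per
timepoint — the discrete pipeline recovers the incompressibility of the
generated flow, with a residual area-growth rate two orders of magnitude
below the deformation scale.  Shear accumulates up to $|\mu| = 0.68$
($K \approx 5$) localized at the constriction (s ≈ 90–100 µm of a 200 µm
tube).  The synthetic tessellation was generated with true circumferential
aspect ratio 2.5, and the full measurement pipeline returns
⟨a/b⟩ = 2.509 ± 0.010.

Other subcommands (`simulate`, `geometry`, `kinematics`, `shear`, `cells`,
`calcium`, `stats`) expose the stages individually; meshes travel as
OBJ/PLY with a `(vertex_id, s, phi)` chart sidecar CSV, movies as
multi-page TIFF, tables as tidy CSV.

## Layout

```
src/tubekin/
  geometry.py    meshes, curvature, charts, centerlines, tangent frames
  synthetic.py   generators: constricting tube, tessellations, tracks, movies
  kinematics.py  velocity decomposition, covariant divergence, residuals
  shear.py       material charts, Beltrami coefficient, kymographs
  cells.py       shape tensors, bootstrap, T1 events, layer motion
  calcium.py     triplet differences, AP profiles, kymographs
  stats.py       z-scores, one-sided p, proportion SE
  io.py, cli.py  formats, configuration, pipeline runner, CLI
docs/methods.md  models, conventions, parameter choices, limitations
```
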