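# volsurf

Accurate bidirectional mappings between a **volumetric template**
coordinate system (an MNI152-style grid) and a **surface template**
coordinate system (an fsaverage-style spherical mesh), built by
*registration fusion*: concatenating each subject's volume-side and
surface-side registrations and averaging the composed mappings over a
cohort.

Neuroimaging results are reported either in a volumetric space or on a
template surface, and translating between the two is lossy: the two
templates were built by different averaging procedures and no single
registration connects them well. Registration fusion sidesteps the
direct template-to-template registration. For a cohort of subjects,
each with (a) a registration between its anatomy and the volumetric
template and (b) a spherical registration between its cortical surface
and the surface template, the composition (b)∘(a)⁻¹ maps every surface
vertex to a volumetric coordinate *through that subject*; averaging the
per-subject coordinates over the cohort gives the fused mapping.

The toolkit implements, for consumers of existing registrations (it
estimates none itself):

- **`transforms`** — affine and dense displacement-field algebra:
  composition chains (lazy, with baking), trilinear sampling,
  fixed-point field inversion, pull-back image resampling.
- **`surfaces`** — spherical mesh machinery: nearest-vertex queries,
  barycentric location on the sphere, subject↔template resampling.
- **`fusion`** — the core: cohort-averaged volume→surface and
  surface→volume mappings; per-voxel cortical **coverage fractions**
  thresholded (≥) into a *tight* (50%) and *loose* (15%) mask; nearest-
  neighbor **dilation** of the tight-mask mapping into the loose mask;
  affine and single-registration baselines on the same machinery.
- **`projection`** — applying finished mappings to data, probabilistic
  maps (fraction of subjects per label), winner-takes-all parcellations,
  boundary extraction.
- **`evaluation`** — the NAD metric
  (`Σ|projected − truth| / Σ truth`), Dice overlap, paired *t*-tests
  with Benjamini–Hochberg FDR control, approach comparison and
  convergence-versus-cohort-size experiments.
- **`synthetic`** — a fully specified phantom world (spherical-shell
  "ribbon", icosphere surfaces, seeded warps and registration jitter)
  with exact ground truth, so the whole pipeline is testable with no
  external data.
- **`cli`** — a thin `volsurf` command (`simulate`, `build`, `project`,
  `evaluate`) over the library.

## Worked example

```sh
python examples/02_build_fusion_mappings.py
```

```
vol2surf over 8 subjects: mean vertex error 0.054 mm, max 0.089 mm
surf2vol coverage: tight mask 12928 voxels (>= 50% of subjects), loose mask 12928 voxels (>= 15%)
after dilation + finalize: 12928 voxels carry a template vertex index (equals the loose mask: 12928)
```

Eight phantom subjects carry 1 mm zero-mean registration jitter; the
fused volume→surface mapping lands each of the 642 template vertices
within 0.09 mm of its exact ground-truth coordinate — the averaging has
cancelled most of the per-subject jitter. In the other direction every
ribbon voxel was cortex in ≥ 50% of subjects (the phantom's ribbons are
consistently warped copies of one shell), so tight and loose masks
coincide and every loose voxel receives a template vertex.

`examples/04_evaluate_and_compare.py` scores the fused mapping against
an affine-only baseline and a single-registration baseline (mean NAD
0.0002 vs 0.24 vs 0.006 at this scale) and prints the error-versus-
cohort-size curve; `examples/01_*.py` and `examples/03_*.py` cover
simulation and projection. The same workflows run from the shell:

```sh
volsurf simulate --n 8 --seed 1 --amplitude 1.0 --out cohort/
volsurf build --cohort cohort/ --method rf --direction both --out mapping/
volsurf project --mapping mapping/ --direction vol2surf --input stat.nii --out stat.txt
volsurf evaluate --experiment ordering --seed 1 --out report/
```

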