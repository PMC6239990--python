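"""Project data through finished mappings in both directions.

A smooth scalar field defined on the template surface travels into the
template volume and back; a probabilistic map built from subject
parcellations travels from the volume to the surface.
"""

import numpy as np

from volsurf.formats_io import VolumeImage
from volsurf.fusion import (
    build_surf2vol,
    build_vol2surf,
    dilate_mapping,
    finalize_surf2vol,
)
from volsurf.projection import (
    make_prob_maps,
    project_surf_to_vol,
    project_vol_to_surf,
    winner_takes_all,
)
from volsurf.synthetic import (
    PhantomSpec,
    make_cohort,
    make_evaluation_data,
    make_template,
)

spec = PhantomSpec(n_subjects=4, amplitude=0.0, jitter_deg=0.0, seed=1)
template = make_template(spec)
cohort, truth = make_cohort(spec, template)
v2s = build_vol2surf(cohort, template.sphere)
s2v = finalize_surf2vol(
    dilate_mapping(build_surf2vol(cohort, template.shape, template.affine)),
    template.sphere,
)

# surface scalar -> volume -> surface
field = template.sphere.vertices[:, 2]  # a first-order spherical harmonic
vol = project_surf_to_vol(field, s2v, interp="barycentric",
                          template_sphere=template.sphere)
back = project_vol_to_surf(vol, v2s, interp="trilinear")
span = field.max() - field.min()
print(f"surface->volume->surface round trip: max error "
      f"{np.abs(back - field).max():.4f} ({np.abs(back - field).max() / span:.2%} "
      "of the field range)")

# subject parcellations -> volumetric probabilistic maps -> surface
ed = make_evaluation_data(template, cohort)
label = int(template.label_ids[0])
prob_vol = VolumeImage(ed.vol_probs.probs[0], template.affine)
on_surface = project_vol_to_surf(prob_vol, v2s, interp="trilinear")
support = template.vertex_labels == label
print(f"parcel {label}: projected probability averages "
      f"{on_surface[support].mean():.3f} on its own vertices and "
      f"{on_surface[~support].mean():.3f} elsewhere")

wta = winner_takes_all(make_prob_maps([ed.vol_truth.labels]))
print(f"winner-takes-all reproduces the single input parcellation: "
      f"{np.array_equal(wta.labels, ed.vol_truth.labels)}")
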