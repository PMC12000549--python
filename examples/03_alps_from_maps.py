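"""Compute the ALPS index for one synthetic subject, both ROI routes.

Builds a subject whose true side-averaged ALPS index is 1.275, places
manual 6 mm cubes and atlas-derived automatic ROIs, and compares the two
index estimates to the ground truth.
"""

from dtialps.alps import compute_bilateral
from dtialps.pipeline import atlas_code_maps, manual_roi_centers
from dtialps.roi import RestrictionConfig, RoiSet, build_automatic_rois, build_manual_roi
from dtialps.synthetic import (
    GeometryConfig,
    generate_atlas,
    generate_subject_volumes,
    generate_transforms,
    make_ground_truth,
)

geom = GeometryConfig()
transform = generate_transforms(geom, ["demo"], seed=5)["demo"]
truth = make_ground_truth("demo", alps_left=1.30, alps_right=1.25, geom=geom,
                          transform=transform)
maps = generate_subject_volumes(truth, geom)

atlas, atlas_affine = generate_atlas(geom)
slf_codes, cst_codes = atlas_code_maps()
auto_rois = build_automatic_rois(
    atlas, atlas_affine, slf_codes, cst_codes, RestrictionConfig(), transform
)
manual_rois = RoiSet({
    key: build_manual_roi(tuple(center), geom.shape, geom.affine,
                          label=key[0], hemisphere=key[1])
    for key, center in manual_roi_centers(geom, transform).items()
})

for method, rois in (("automatic", auto_rois), ("manual", manual_rois)):
    res = compute_bilateral(maps, rois, subject_id="demo", method=method)
    print(f"{method:>9}: left {res.left:.6f}  right {res.right:.6f}  "
          f"average {res.average:.6f}")
print(f"    truth: left {truth.alps_left:.6f}  right {truth.alps_right:.6f}  "
      f"average {truth.alps_average:.6f}")
print(
    "\nBoth ROI routes sit inside the homogeneous synthetic tract columns,"
    "\nso each recovers the configured index exactly; on noisy fitted maps"
    "\nthey differ and their agreement is what the reliability analysis tests."
)
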