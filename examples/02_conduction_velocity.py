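"""Estimate conduction velocity from activation times by triangulation.

A focal wave crosses a disc containing a slow-conducting patch (0.3 m/s in
0.8 m/s tissue).  Delaunay triples of mapping points are fitted with local
planar wavefronts, screened by the four acceptance constraints, and the
surviving velocities interpolated into a CV map.
"""

import numpy as np

import eamap
from eamap.velocity import CvConstraints, cv_field, fit_and_screen, triples_frame

mesh = eamap.make_mesh("disc", 1.5, 40.0)
centre = (15.0, 0.0, 0.0)
speed = eamap.make_speed_field(mesh, 0.8, patches=[(centre, 10.0, 0.3)])
truth = eamap.simulate_activation(mesh, "focal", speed, origin=(-35.0, 0.0, 0.0))

points = eamap.sample_mapping_points(mesh, truth, 6000, seed=0,
                                     synth_traces=False)
triples = fit_and_screen(points, CvConstraints.relaxed())
audit = triples_frame(triples)
mesh.fields["cv"] = cv_field(triples, mesh)

d = np.linalg.norm(mesh.vertices - np.asarray(centre), axis=1)
print(f"triples fitted/accepted:  {len(audit)} / {int(audit.accepted.sum())}")
for name in ("edge_distance", "delta_t", "min_cv", "min_angle"):
    print(f"  rejected by {name:13s}: {int((~audit[f'pass_{name}']).sum())}")
print(f"patch-interior mean CV:   {np.nanmean(mesh.fields['cv'][d < 6]):.2f} m/s (truth 0.30)")
print(f"background mean CV:       {np.nanmean(mesh.fields['cv'][d > 14]):.2f} m/s (truth 0.80)")
print(f"slow-CV area (<0.6 m/s):  {100 * eamap.area_fraction_below(mesh, 'cv', 0.6):.1f} %")
print("Slow-CV regions mark substrate that sustains re-entry even where voltage is preserved.")
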