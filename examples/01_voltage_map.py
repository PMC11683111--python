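"""Build a voltage map from synthetic electrograms and quantify low-voltage area.

Simulates a left-atrium-like disc with fibrosis-like low-amplitude patches,
samples >1,000 mapping points with electrograms, measures peak-to-peak
bipolar voltage per point, and interpolates a voltage map.
"""

import numpy as np

import eamap
from eamap.io import PipelineConfig
from eamap.pipeline import process_points

mesh = eamap.make_mesh("disc", resolution_mm=2.0, radius_mm=40.0)
truth = eamap.simulate_activation(mesh, "planar", speed_m_per_s=0.7)
truth.amplitude_mV = eamap.make_amplitude_field(mesh, mean_mV=1.2, seed=1)

points = eamap.sample_mapping_points(mesh, truth, n_points=1200,
                                     noise=eamap.EgmNoise(rms_mV=0.01), seed=1)
process_points(points, PipelineConfig())  # filter, screen, annotate, measure

acc = [p for p in points if p.quality == "accepted"]
pos = np.stack([p.position for p in acc])
mesh.fields["bip_voltage"] = eamap.interpolate_field(
    pos, np.array([p.bip_mV for p in acc]), mesh
)
lva = eamap.area_fraction_below(mesh, "bip_voltage", 0.5)
mean_v = np.nanmean(mesh.fields["bip_voltage"])

print(f"accepted points:        {len(acc)} / {len(points)}")
print(f"map-mean voltage:       {mean_v:.2f} mV")
print(f"low-voltage area (<0.5 mV): {100 * lva:.1f} % of mapped surface")
print("The LVA fraction is the standard surrogate for fibrotic substrate;")
print("values above ~20-30% mark an advanced atrial substrate.")
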