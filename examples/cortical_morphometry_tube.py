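"""Cortical morphometry of a hollow-cylinder phantom.

Builds a mid-diaphysis-like tube with known section properties,
segments it, and compares the measured cortical metrics with the
closed-form ground truth.
"""
from bonefrag.morphometry import SegmentationParams, cortical_morphometry, segment_volume
from bonefrag.phantoms import make_cortical_tube_phantom

vol, truth = make_cortical_tube_phantom(
    outer_radius_mm=1.0, inner_radius_mm=0.6, length_mm=0.05,
    voxel_size_um=12.0, tmd_mean=1100.0, noise_sd=60.0, seed=1)
mask = segment_volume(vol, SegmentationParams(gauss_sigma=1.2, threshold=550.0))
metrics = cortical_morphometry(mask, vol)

print("metric        measured   truth")
for key, label in [("ct_ar", "Ct.Ar mm^2"), ("tt_ar", "Tt.Ar mm^2"),
                   ("ct_th", "Ct.Th mm"), ("i_min", "I_min mm^4"),
                   ("z_min", "Z mm^3")]:
    print(f"{label:12s}  {getattr(metrics, key):8.4f}  {truth[key]:8.4f}")
print(f"Ct.TMD {metrics.ct_tmd:.0f} mg HA/cm^3 (phantom tissue density 1100)")
# Measured values should sit within a few percent of the closed forms;
# the residual gap is voxelization error at 12 um.
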