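"""Bound-water volume fraction from a CPMG echo train.

Simulates the acquisition (10,000 echoes at 100 us spacing) for a bone
with a 0.3 ul bound-water pool, inverts the decay to a T2 spectrum,
calibrates against a 21.2 ul water-sphere reference, and normalizes by
the Archimedes bone volume.
"""
from bonefrag.phantoms import simulate_cpmg_signal
from bonefrag.relaxometry import archimedes_volume, invert_cpmg, quantify_bound_water

sample_sig, truth = simulate_cpmg_signal(
    [(0.3, 300e-6), (1.0, 100e-3)],   # (volume ul, T2 s): bound + pore water
    noise_sd=1.3 / 500, seed=11)
ref_sig, _ = simulate_cpmg_signal([(21.2, 1.0)], noise_sd=21.2 / 500, seed=12)

spectrum = invert_cpmg(sample_sig)
reference = invert_cpmg(ref_sig)
bone_volume = archimedes_volume(50.0, 30.03, 0.9982)  # mg, mg, mg/mm^3
bw = quantify_bound_water(spectrum, reference, bone_volume_ul=bone_volume)

print(f"bone volume (Archimedes): {bw.bone_volume:.2f} ul")
print(f"bound water volume:       {bw.bw_volume:.3f} ul  (true 0.300)")
print(f"bound water fraction:     {bw.bw_fraction:.4f}   (true 0.0150)")
# The bound pool is the short-T2 peak (50 us - 1 ms window); its mass
# converts to microlitres through the reference-sphere calibration.
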