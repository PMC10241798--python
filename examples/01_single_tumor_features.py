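"""Generate one synthetic PET tumor, delineate it, and print its features.

A 12-SUV ellipsoidal tumor with moderate intra-tumor texture is built on a
4 x 4 x 5 mm grid, delineated at the standard 35%-of-SUVmax threshold, and
the full radiomic record is computed.
"""

import petromics as pm

spec = pm.PhantomSpec(suv_peak=12.0, heterogeneity_sd=0.5)
volume, truth = pm.generate_phantom(spec, seed=7)

features = pm.extract_features(volume, truth.true_mask.bounding_box(margin=3))

print(f"true MTV        : {truth.true_mtv_cm3:.2f} cm^3 (ground truth)")
print(f"delineated MTV  : {features['mtv_cm3']:.2f} cm^3 (35% threshold)")
print(f"SUVmax / SUVmean: {features['suv_max']:.2f} / {features['suv_mean']:.2f}")
print(f"TLG             : {features['tlg']:.1f}  (SUVmean x MTV)")
print(f"COV             : {features['cov']:.3f} (SD/mean, heterogeneity index)")
print(f"asphericity     : {features['asp']:.3f} (0 = perfect sphere)")
print(f"entropy         : {features['entropy_bits']:.2f} bits (64-bin histogram)")
print(
    "GLCM            : contrast %.2f, correlation %.2f, energy %.3f, "
    "homogeneity %.3f" % (
        features["glcm_contrast"], features["glcm_correlation"],
        features["glcm_energy"], features["glcm_homogeneity"],
    )
)
print()
print("Delineated and true MTV differ slightly: PSF blur pushes the 35%")
print("level outside the true edge, while texture peaks raise SUVmax and")
print("hence the threshold; the two biases partly cancel here.")
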