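"""Sensitivity of MTV and texture features to the delineation threshold.

The 35% fixed threshold is a convention; this script re-extracts the same
phantom cohort at 35% and 50% of SUVmax and shows that every patient's MTV
shrinks monotonically while texture features shift, illustrating why the
threshold must be reported with any radiomic result.
"""

import petromics as pm

bundle = pm.generate_cohort(pm.CohortSpec(n_patients=10, seed=3))

f35 = pm.extract_bundle(bundle, pm.PipelineConfig(threshold_fraction=0.35))
f50 = pm.extract_bundle(bundle, pm.PipelineConfig(threshold_fraction=0.50))
merged = f35.merge(f50, on=["patient_id", "timepoint"], suffixes=("_35", "_50"))

pre = merged[merged.timepoint == "pre"]
print("patient   MTV@35%   MTV@50%   homogeneity@35%  homogeneity@50%")
for _, r in pre.iterrows():
    print(
        f"{r.patient_id:8} {r.mtv_cm3_35:8.1f} {r.mtv_cm3_50:9.1f}"
        f" {r.glcm_homogeneity_35:15.3f} {r.glcm_homogeneity_50:16.3f}"
    )
shrunk = (merged.mtv_cm3_50 <= merged.mtv_cm3_35).all()
print()
print(f"MTV monotonically smaller at the higher threshold for all rows: {shrunk}")
print("A higher threshold keeps only the hotter tumor core, so the volume")
print("drops and the remaining region is more uniform.")
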