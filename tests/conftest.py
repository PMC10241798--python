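import numpy as np
import pandas as pd
import pytest

import petromics as pm

#: The four associations planted for the parameter-recovery experiment,
#: at the magnitudes reported for the clinical cohort the phantoms emulate.
RECOVERY_EFFECTS = (
    ("pre_cov", "recurrence", 0.34),
    ("post_glcm_energy", "response", 0.54),
    ("post_glcm_homogeneity", "response", 0.46),
    ("post_glcm_contrast", "age", 0.30),
)

N_RECOVERY_SEEDS = 20
N_RECOVERY_PATIENTS = 200


@pytest.fixture(scope="session")
def recovery_experiment():
    """Run the 20-cohort parameter-recovery experiment once per session.

    Returns realized Spearman rho per planted effect per seed, plus the
    paired pre/post Wilcoxon Z and p for the metabolic features per seed.
    """
    rhos = {e[:2]: [] for e in RECOVERY_EFFECTS}
    wilcoxon = {f: [] for f in ("suv_max", "suv_mean", "mtv_cm3", "tlg")}
    for seed in range(N_RECOVERY_SEEDS):
        cspec = pm.CohortSpec(
            n_patients=N_RECOVERY_PATIENTS,
            seed=seed,
            planted_effects=RECOVERY_EFFECTS,
        )
        bundle = pm.generate_cohort(cspec)
        features = pm.extract_bundle(bundle)
        report = pm.run_cohort_analysis(features, bundle.clinical)
        corr = report.correlations
        for feat, cov, _ in RECOVERY_EFFECTS:
            row = corr[(corr.feature == feat) & (corr.covariate == cov)]
            rhos[(feat, cov)].append(float(row.rho.values[0]))
        paired = report.paired_change.set_index("feature")
        for f in wilcoxon:
            wilcoxon[f].append(
                (float(paired.loc[f, "z"]), float(paired.loc[f, "p_value"]))
            )
    return {"rhos": rhos, "wilcoxon": wilcoxon}


@pytest.fixture()
def small_phantom():
    """A modest noiseless-background phantom reused across feature tests."""
    spec = pm.PhantomSpec(
        grid_shape=(24, 24, 20),
        voxel_spacing=(4.0, 4.0, 5.0),
        tumor_radii=(14.0, 13.0, 12.0),
        suv_peak=10.0,
    )
    vol, truth = pm.generate_phantom(spec, seed=42)
    return spec, vol, truth


@pytest.fixture()
def table1_clinical():
    """Clinical CSV fixture rebuilt from the published cohort-composition table."""
    rows = []
    figo = [s for s, c in [("IIIC1", 2), ("IIIC2", 52), ("IVB", 29)] for _ in range(c)]
    recurrence = ["none"] * 45 + ["local"] * 13 + ["distant"] * 25
    regimen = (
        ["paclitaxel+cisplatin"] * 77
        + ["paclitaxel+carboplatin"] * 3
        + ["paclitaxel+carboplatin+bevacizumab"] * 2
        + ["etoposide+cisplatin"] * 1
    )
    cycles = [6] * 69 + [5] * 7 + [4] * 5 + [3] * 1 + [7] * 1
    ages = list(np.clip(np.linspace(24, 76, 83).round().astype(int), 24, 76))
    for i in range(83):
        rows.append(
            dict(
                patient_id=f"T{i + 1:03d}",
                age=ages[i],
                figo=figo[i],
                response="responder" if i % 2 == 0 else "non-responder",
                recurrence=recurrence[i],
                cycles=cycles[i],
                regimen=regimen[i],
            )
        )
    return pd.DataFrame(rows)
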