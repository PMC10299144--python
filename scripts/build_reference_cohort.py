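"""Deterministic builder for the packaged synthetic reference cohort.

Regenerates src/octadme/data/synthetic_reference_cohort.csv from a fixed
seed; run from the repository root.  The published marginal counts are
asserted before writing.
"""
import numpy as np
import pandas as pd
from scipy import stats

rng = np.random.default_rng(20230606)
n = 66

# 62 patients, 4 with two eyes (last 4 patients repeat)
patient_ids = [f"P{i:03d}" for i in range(1, 63)] + ["P059", "P060", "P061", "P062"]
eye_ids = [f"E{i:03d}" for i in range(1, 67)]

# diabetes type per patient: first 27 type 1, rest type 2
ptype = {f"P{i:03d}": (1 if i <= 27 else 2) for i in range(1, 63)}
diabetes_type = [ptype[p] for p in patient_ids]
hba1c = np.round([rng.normal(7.94 if t == 1 else 7.55, 1.0) for t in diabetes_type], 1)
hba1c = np.clip(hba1c, 5.5, 11.5)

# CMT strata: rows 0..35 high (>=373), rows 36..65 low (<373); shuffle later
def tnorm(lo, hi, mean, sd, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

cmt_high = np.round(tnorm(373, 900, 420.9, 103.7, 36), 1)
cmt_low = np.round(tnorm(150, 372.9, 420.9, 103.7, 30), 1)

lac_high10 = np.round(tnorm(0.41, 1.2, 0.50, 0.10, 10), 3)
lac_low26 = np.round(tnorm(0.05, 0.405, 0.33, 0.08, 26), 3)
lac_lowcmt = np.round(tnorm(0.05, 0.405, 0.33, 0.08, 30), 3)

rows = []
for i in range(66):
    if i < 10:
        cmt, lac, final = cmt_high[i], lac_high10[i], 65
    elif i < 36:
        cmt, lac, final = cmt_high[i], lac_low26[i - 10], 73
    else:
        cmt, lac, final = cmt_low[i - 36], lac_lowcmt[i - 36], 78
    rows.append((cmt, lac, final))
perm = rng.permutation(66)
cmt_baseline = np.array([rows[j][0] for j in perm])
lac_dcp = np.array([rows[j][1] for j in perm])
bcva_final = np.array([rows[j][2] for j in perm])

assert (cmt_baseline >= 373).sum() == 36
assert ((cmt_baseline >= 373) & (lac_dcp >= 0.41)).sum() == 10
assert bcva_final[(cmt_baseline >= 373)].mean().round(2) == 70.78

bcva_baseline = np.clip(np.round(rng.normal(64.77, 12.73, n)), 5, 95)
cmt_final = np.clip(np.round(cmt_baseline - rng.normal(72, 55, n), 1), 160, None)
n_injections = np.clip(np.round(rng.normal(6.07, 2.4, n)), 3, 12).astype(int)

def flag(k):
    col = np.zeros(n, dtype=int)
    col[rng.permutation(n)[:k]] = 1
    return col

def subset_flag(base, k):
    idx = np.flatnonzero(base)
    col = np.zeros(n, dtype=int)
    col[rng.permutation(idx)[:k]] = 1
    return col

microaneurysms = flag(48)
irma = flag(49)
neovascularization = flag(22)
macular_cysts = flag(63)
subretinal_fluid = flag(16)
hard_exudates = flag(22)
ez_alteration = flag(45)
macular_cysts_m12 = subset_flag(macular_cysts, 31)
subretinal_fluid_m12 = subset_flag(subretinal_fluid, 4)
hard_exudates_m12 = subset_flag(hard_exudates, 9)
ez_alteration_m12 = subset_flag(ez_alteration, 29)

def octa(mean, sd, lo, hi):
    return np.round(tnorm(lo, hi, mean, sd, n), 3)

table = pd.DataFrame({
    "eye_id": eye_ids,
    "patient_id": patient_ids,
    "diabetes_type": diabetes_type,
    "hba1c": hba1c,
    "bcva_baseline": bcva_baseline.astype(int),
    "bcva_final": bcva_final.astype(int),
    "cmt_baseline": cmt_baseline,
    "cmt_final": cmt_final,
    "vma": 0,
    "macular_cysts": macular_cysts,
    "subretinal_fluid": subretinal_fluid,
    "hard_exudates": hard_exudates,
    "ez_alteration": ez_alteration,
    "macular_cysts_m12": macular_cysts_m12,
    "subretinal_fluid_m12": subretinal_fluid_m12,
    "hard_exudates_m12": hard_exudates_m12,
    "ez_alteration_m12": ez_alteration_m12,
    "microaneurysms": microaneurysms,
    "irma": irma,
    "neovascularization": neovascularization,
    "vpd_scp": octa(0.36, 0.07, 0.10, 0.70),
    "vpd_dcp": octa(0.36, 0.07, 0.10, 0.70),
    "lac_scp": octa(0.42, 0.22, 0.05, 1.20),
    "lac_dcp": lac_dcp,
    "vpd_scp_m12": octa(0.39, 0.06, 0.10, 0.70),
    "vpd_dcp_m12": octa(0.38, 0.07, 0.10, 0.70),
    "lac_scp_m12": octa(0.37, 0.05, 0.05, 1.20),
    "lac_dcp_m12": octa(0.39, 0.16, 0.05, 1.20),
    "n_injections": n_injections,
})
out = "src/octadme/data/synthetic_reference_cohort.csv"
table.to_csv(out, index=False)
print(table.shape, "written")
print("checks:",
      (table.cmt_baseline >= 373).sum(),
      ((table.cmt_baseline >= 373) & (table.lac_dcp >= 0.41)).sum(),
      table.loc[table.cmt_baseline >= 373, "bcva_final"].mean())
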