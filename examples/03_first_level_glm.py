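"""Fit the subject-level GLM with AR(1) prewhitening and evaluate the two
conflict contrasts for one subject's ACC time course.

cI - cC is the maximum-conflict contrast (incongruent after congruent vs
congruent after congruent); I - C is the general-conflict contrast.
"""

from emostroop import (
    GENERAL_CONFLICT,
    MAX_CONFLICT,
    build_design_matrix,
    compute_contrast,
    fit_glm_ar1,
    simulate_roi_dataset,
)

dataset = simulate_roi_dataset(seed=2)
subject = dataset.subjects[0]
acc = subject.roi_series[dataset.roi_names.index("ACC")]

design = build_design_matrix(
    subject.trial_sequence, n_scans=len(acc), tr_s=dataset.tr_s,
    motion=subject.motion,
)
fit = fit_glm_ar1(acc, design)
print(f"subject {subject.subject_id} ({subject.group}), "
      f"AR(1) rho = {fit.ar1_rho:.3f}, dof = {fit.dof:.0f}")
for spec in (MAX_CONFLICT, GENERAL_CONFLICT):
    res = compute_contrast(fit, spec)
    print(f"  {spec.name}: estimate {res.estimate:+.3f}, "
          f"t = {res.t_value:+.2f}, p = {res.p_two_sided:.4f}")
# FH+ subjects carry larger conflict responses, so both contrasts tend to
# be positive for this subject
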