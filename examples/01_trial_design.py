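"""Build a counterbalanced emotional-Stroop trial sequence and its design
matrix.

The sequence alternates congruent (C) and incongruent (I) face-word trials
pseudorandomly, balancing the four previous/current pairings cC, iC, cI,
iI; the design matrix convolves each pair type's 1 s events with the
canonical HRF and appends motion, intercept and drift regressors.
"""

from emostroop import build_design_matrix, generate_trial_sequence

seq = generate_trial_sequence(n_trials=148, isi_min_s=3.0, isi_max_s=5.0, seed=1)
print(f"{len(seq)} trials over {seq.total_duration_s:.0f} s")
print("pair-type counts:", seq.pair_type_counts())
# counts differ by at most one: the counterbalancing constraint

dm = build_design_matrix(seq, n_scans=390, tr_s=2.0)
print(f"design matrix: {dm.values.shape[0]} scans x {len(dm.regressor_names)} regressors")
print("regressors:", ", ".join(dm.regressor_names))
# the four pair-type columns + error form the task model; the rest are
# nuisance (motion, intercept, low-frequency drift below 1/128 Hz)
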