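# emostroop

Task-fMRI analysis of emotional-Stroop conflict processing in adolescents
with (FH+) and without (FH−) a familial history of substance use
disorders — built for methodologists who want the full chain from trial
design to group classification as tested, reusable Python, exercisable
end to end on synthetic data that emulates the statistical structure of
such a study (two groups of 11 and 7 subjects, 148 counterbalanced
congruent/incongruent trials at TR = 2 s).

The chain:

1. **Task design** — pseudorandom C/I sequences counterbalanced over the
   cC/iC/cI/iI previous×current pairings; first-level design matrices
   (HRF-convolved 1 s boxcars per pair type, error regressor, six motion
   covariates, DCT drift basis below 1/128 Hz).
2. **First-level GLM** — iterated AR(1) prewhitening (Cochrane–Orcutt);
   t contrasts cI−cC (maximum conflict) and I−C (general conflict):
   t = wᵀβ̂ / √(σ̂² wᵀ(XᵀX)⁻¹w) on the whitened design.
3. **Group inference** — pooled-variance two-sample t maps;
   cluster-extent correction with k estimated by Monte-Carlo simulation
   of smoothed Gaussian null volumes (voxelwise p = 0.01, α = 0.05,
   8 mm FWHM); cluster extraction and ROI summaries (mean or first
   eigenvariate).
4. **Effective connectivity** — Granger causality indices between ROI
   time courses, GCI = ln(RSS_restricted/RSS_full) for an AR model of the
   target without vs with the source's past; mediated variants route a
   source through the thalamus (joint or conditional).
5. **Classification** — linear SVM and maximum-uncertainty LDA
   (pooled-scatter eigenvalues below their mean raised to the mean) on
   contrast + GCI features; repeated five-fold / leave-one-out /
   leave-M-blocks CV; permutation tests; hyperplane contributions |wᵢ|.
6. **Behaviour** — conflict adaptation (RT iI − cI per group),
   per-condition group t-tests and a 2×2 mixed ANOVA.

A synthetic-data generator (`emostroop.synthetic`) produces ROI time
courses with known directed VAR coupling calibrated to target GCI group
summaries, miniature 4D NIfTI volumes with planted activation blobs, and
reaction-time tables reproducing the published conflict-adaptation
pattern — so every stage has a ground truth to be tested against.

## Worked example

```python
from emostroop import simulate_roi_dataset
from emostroop.granger import Channel, gci_group_stats, subject_gci_table

dataset = simulate_roi_dataset(seed=1)          # 11 FH+ vs 7 FH-, 10 ROIs
table = subject_gci_table(dataset, [Channel("IFG", "ACC")])
print(gci_group_stats(table))
```

prints (see `examples/02_simulate_dataset.py`):

```
18 subjects, ROIs: ACC, MFG, SFG, SMG, IFG, Insula, Hippocampus, Putamen, Thalamus, VTA
groups: 11 FH+ / 7 FH-
IFG->ACC GCI: FH+ 0.052 +/- 0.039, FH- 0.228 +/- 0.103, t = -5.20
```

The generator is calibrated so the frontal-to-cingulate channel carries
weaker causal influence in the FH+ group; the negative pooled t
recovers that direction from one simulated cohort at the study's group
sizes.  The behavioural stage (`examples/07_behavior.py`) likewise
reproduces the adaptation dissociation — FH+ slower after conflict
(+27.5 ms in the example run), FH− faster (−10.2 ms) — while every
per-condition group comparison stays non-significant, as the large
between-subject speed variance implies.

Each `examples/` script is a short narrative of one capability:
trial/design construction, dataset simulation, first-level GLM, cluster
inference, Granger causality, classification, behaviour, and the full
pipeline (`emostroop run --config ... --seed ... --out ...` from the
shell writes the same report bundle).

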