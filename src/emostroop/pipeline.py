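"""End-to-end orchestration: simulate -> GLM -> group inference -> GCI ->
classification -> behavior, with seeded reproducibility and a report bundle.

A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence.spawn``, so each stage is independently
reproducible.  All tabular outputs are tidy CSV; the manifest records the
configuration, seed and package versions needed to reproduce the bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import conflict_adaptation, rt_group_comparisons
from .classify import (
    CvScheme,
    cross_validate,
    feature_contributions,
    permutation_test,
    select_features,
    train_mlda,
    train_svm_linear,
    evaluate_sensitivity_specificity,
)
from .glm import (
    GENERAL_CONFLICT,
    MAX_CONFLICT,
    compute_contrast,
    fit_contrast_maps,
    fit_glm_ar1,
)
from .granger import Channel, gci_group_stats, subject_gci_table
from .group import (
    ClusterThresholdSpec,
    clusters_to_frame,
    extract_clusters,
    extract_roi_summary,
    monte_carlo_cluster_threshold,
    two_sample_t_map,
)
from .synthetic import (
    GROUP_POS,
    BlobSpec,
    GroundTruth,
    simulate_reaction_times,
    simulate_roi_dataset,
    simulate_volume_dataset,
)
from .task_design import build_design_matrix

__all__ = ["RunConfig", "validate_config", "run_pipeline", "default_channels"]


def default_channels() -> list[Channel]:
    """The nine causality channels analysed by default."""
    return [
        Channel("MFG", "SMG"),
        Channel("IFG", "SMG"),
        Channel("Insula", "ACC"),
        Channel("IFG", "ACC"),
        Channel("IFG", "Hippocampus"),
        Channel("IFG", "Putamen"),
        Channel("IFG", "VTA"),
        Channel("Putamen", "IFG", "Thalamus"),
        Channel("VTA", "IFG", "Thalamus"),
    ]


@dataclass
class RunConfig:
    """Validated pipeline configuration with documented defaults."""

    seed: int
    out_dir: str = "emostroop_out"
    # design / simulation
    n_per_group: tuple[int, int] = (11, 7)
    n_trials: int = 148
    n_scans: int = 390
    tr_s: float = 2.0
    highpass_cutoff_hz: float = 1.0 / 128.0
    # volume stage
    volume_shape: tuple[int, int, int] = (16, 16, 16)
    volume_n_scans: int = 150
    volume_n_trials: int = 28
    blobs: list[dict] = field(default_factory=lambda: [
        {"center": [5, 5, 8], "radius": 2.5, "condition": "cI",
         "amp_pos": 1.2, "amp_neg": 0.1, "between_sd": 0.3},
        {"center": [11, 10, 7], "radius": 2.5, "condition": "iI",
         "amp_pos": 1.2, "amp_neg": 0.1, "between_sd": 0.3},
    ])
    # cluster inference
    voxel_p: float = 0.01
    alpha_fw: float = 0.05
    fwhm_mm: float = 8.0
    mc_iterations: int = 1000
    connectivity: int = 18
    roi_summary_method: str = "mean"
    # GCI
    gci_order: int = 1
    channels: list[dict] = field(default_factory=lambda: [
        {"source": c.source, "target": c.target, "mediator": c.mediator,
         "mode": c.mode} for c in default_channels()
    ])
    # classification
    selection_p: float = 0.05
    selection_mode: str = "as_published"
    classifier: str = "svm"
    svm_C: float = 1.0
    cv_repeats: int = 200
    n_permutations: int = 200
    learning_curve: bool = True

    def __post_init__(self):
        errors = []
        if self.seed is None:
            errors.append("seed: mandatory")
        if not 0 < self.voxel_p < 1:
            errors.append(f"voxel_p: {self.voxel_p} outside (0, 1)")
        if not 0 < self.alpha_fw < 1:
            errors.append(f"alpha_fw: {self.alpha_fw} outside (0, 1)")
        if self.connectivity not in (6, 18, 26):
            errors.append(f"connectivity: {self.connectivity} not in {{6, 18, 26}}")
        if self.selection_mode not in ("as_published", "nested"):
            errors.append(f"selection_mode: {self.selection_mode!r}")
        if self.classifier not in ("svm", "mlda"):
            errors.append(f"classifier: {self.classifier!r}")
        if len(self.n_per_group) != 2 or min(self.n_per_group) < 2:
            errors.append(f"n_per_group: {self.n_per_group} needs two counts >= 2")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        self.n_per_group = tuple(self.n_per_group)
        self.volume_shape = tuple(self.volume_shape)

    def channel_objects(self) -> list[Channel]:
        return [
            Channel(
                source=c["source"],
                target=c["target"],
                mediator=c.get("mediator"),
                mode=c.get("mode") or "joint",
            )
            for c in self.channels
        ]


def validate_config(source) -> RunConfig:
    """Load and validate a config mapping or YAML file path.

    Unknown keys are reported; missing keys take documented defaults.
    """
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in data:
        raise ValueError("invalid configuration: seed: mandatory")
    return RunConfig(**data)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def roi_contrast_table(dataset, cutoff_hz: float = 1.0 / 128.0) -> pd.DataFrame:
    """Per-subject, per-ROI contrast estimates (cI-cC and I-C).

    Fits the AR(1)-prewhitened GLM per ROI series on each subject's own
    design matrix and evaluates both conflict contrasts.
    """
    rows = []
    n_scans = dataset.subjects[0].roi_series.shape[1]
    for subj in dataset.subjects:
        design = build_design_matrix(
            subj.trial_sequence,
            n_scans=n_scans,
            tr_s=dataset.tr_s,
            cutoff_hz=cutoff_hz,
            motion=subj.motion,
        )
        for i, roi in enumerate(dataset.roi_names):
            fit = fit_glm_ar1(subj.roi_series[i], design)
            for spec in (MAX_CONFLICT, GENERAL_CONFLICT):
                res = compute_contrast(fit, spec)
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "group": subj.group,
                        "roi": roi,
                        "contrast": spec.name,
                        "estimate": res.estimate,
                        "t": res.t_value,
                    }
                )
    return pd.DataFrame(rows)


def volume_group_analysis(
    volume_ds,
    spec: ClusterThresholdSpec,
    cutoff_hz: float = 1.0 / 128.0,
    contrasts=(MAX_CONFLICT, GENERAL_CONFLICT),
    roi_summary_method: str = "mean",
):
    """Subject contrast maps -> group t map -> Monte-Carlo k -> clusters.

    Returns a dict with the per-contrast t maps, the extent threshold k,
    cluster tables and per-subject cluster summaries (feature candidates).
    """
    maps = {c.name: [] for c in contrasts}
    groups = []
    for subj in volume_ds.subjects:
        design = build_design_matrix(
            subj.trial_sequence,
            n_scans=subj.data.shape[3],
            tr_s=volume_ds.tr_s,
            cutoff_hz=cutoff_hz,
        )
        est = fit_contrast_maps(subj.data, design, list(contrasts))
        for name, m in est.items():
            maps[name].append(m)
        groups.append(subj.group)
    groups = np.asarray(groups)
    mask = np.ones(volume_ds.shape, dtype=bool)
    k = monte_carlo_cluster_threshold(mask, spec)
    result = {"k": k, "groups": groups, "contrasts": {}}
    for name, lst in maps.items():
        arr = np.stack(lst)
        t_map, dof = two_sample_t_map(arr[groups == GROUP_POS], arr[groups != GROUP_POS])
        clusters = extract_clusters(
            t_map, spec.voxel_p, dof, k=k,
            connectivity=spec.connectivity, affine=volume_ds.affine,
        )
        summaries = {
            f"{name}_cluster{j + 1}": extract_roi_summary(
                arr, cl, method=roi_summary_method
            )
            for j, cl in enumerate(clusters)
        }
        result["contrasts"][name] = {
            "t_map": t_map,
            "dof": dof,
            "clusters": clusters,
            "table": clusters_to_frame(clusters),
            "subject_summaries": pd.DataFrame(summaries),
        }
    return result


def _classification_stage(cfg: RunConfig, candidates, labels, origins, seed):
    trainer = "svm" if cfg.classifier == "svm" else "mlda"
    features, manifest = select_features(
        candidates, labels, p_threshold=cfg.selection_p, mode=cfg.selection_mode
    )
    nested_p = cfg.selection_p if cfg.selection_mode == "nested" else None
    rows = []
    reports = {}
    seeds = _stage_seeds(seed, 4)
    for kind, label in (("kfold", "five-fold CV"), ("loo_random", "leave-one-out CV")):
        scheme = CvScheme(kind=kind, n_repeats=cfg.cv_repeats, seed=seeds[0])
        rep = permutation_test(
            trainer, features, scheme=scheme,
            n_permutations=cfg.n_permutations, seed=seeds[1],
            C=cfg.svm_C, nested_selection_p=nested_p,
        )
        rows.append(
            {
                "scheme": label,
                "mean_accuracy_pct": rep.mean_accuracy,
                "accuracy_sd_pct": rep.accuracy_sd,
                "permutation_p": rep.permutation_p,
            }
        )
        reports[kind] = rep
    curve_rows = []
    if cfg.learning_curve:
        for m in range(1, 5):
            scheme = CvScheme(
                kind="leave_blocks", n_repeats=cfg.cv_repeats,
                m_training_blocks=m, seed=seeds[2],
            )
            rep = cross_validate(trainer, features, scheme=scheme, C=cfg.svm_C,
                                 nested_selection_p=nested_p)
            curve_rows.append(
                {
                    "training_blocks": m,
                    "mean_accuracy_pct": rep.mean_accuracy,
                    "accuracy_sd_pct": rep.accuracy_sd,
                }
            )
    # MLDA on the full sample for hyperplane contributions, plus exhaustive
    # LOO predictions for sensitivity/specificity
    Xz = (features.values - features.values.mean(0)) / np.where(
        features.values.std(0) > 0, features.values.std(0), 1.0
    )
    mlda = train_mlda(Xz, features.labels)
    contrib = feature_contributions(mlda, features.feature_names)
    preds = []
    n = features.n_subjects
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        mu, sd = features.values[tr].mean(0), features.values[tr].std(0)
        sd = np.where(sd > 0, sd, 1.0)
        m = train_mlda((features.values[tr] - mu) / sd, features.labels[tr])
        preds.append(m.predict((features.values[[i]] - mu) / sd)[0])
    sens, spec_ = evaluate_sensitivity_specificity(
        np.asarray(preds), features.labels, positive_class=GROUP_POS
    )
    return {
        "accuracy_table": pd.DataFrame(rows),
        "learning_curve": pd.DataFrame(curve_rows),
        "contributions": contrib,
        "selection_manifest": manifest,
        "sensitivity_pct": sens,
        "specificity_pct": spec_,
        "reports": reports,
    }


def run_pipeline(config, write: bool = True) -> dict:
    """Execute every stage and (optionally) write the report bundle.

    Returns a dict of in-memory results; with ``write=True`` the bundle is
    written under ``config.out_dir``: cluster_table.csv, gci_group_table.csv,
    accuracy_table.csv, learning_curve.csv, adaptation.csv, anova.csv,
    contributions.csv and manifest.json.
    """
    cfg = validate_config(config)
    seeds = _stage_seeds(cfg.seed)
    results: dict = {"config": cfg}

    # 1. synthetic data
    truth = GroundTruth(seed=seeds[0])
    roi_ds = simulate_roi_dataset(
        truth, n_per_group=cfg.n_per_group, n_scans=cfg.n_scans,
        tr_s=cfg.tr_s, n_trials=cfg.n_trials, seed=seeds[0],
    )
    blobs = [BlobSpec(
        center=tuple(b["center"]), radius=b["radius"], condition=b["condition"],
        amp_pos=b["amp_pos"], amp_neg=b["amp_neg"], between_sd=b["between_sd"],
    ) for b in cfg.blobs]
    vol_ds = simulate_volume_dataset(
        blobs, shape=cfg.volume_shape, n_per_group=cfg.n_per_group,
        n_scans=cfg.volume_n_scans, tr_s=cfg.tr_s,
        n_trials=cfg.volume_n_trials, seed=seeds[1],
    )
    rt = simulate_reaction_times(n_per_group=cfg.n_per_group, seed=seeds[2])
    results["roi_dataset"] = roi_ds
    results["rt_table"] = rt

    # 2. first-level GLM on ROI series
    contrast_tab = roi_contrast_table(roi_ds, cutoff_hz=cfg.highpass_cutoff_hz)
    results["contrast_table"] = contrast_tab

    # 3. volume group analysis with Monte-Carlo cluster threshold
    spec = ClusterThresholdSpec(
        voxel_p=cfg.voxel_p, alpha_fw=cfg.alpha_fw, fwhm_mm=cfg.fwhm_mm,
        voxel_size_mm=(3.0, 3.0, 3.0), n_iterations=cfg.mc_iterations,
        connectivity=cfg.connectivity, seed=seeds[3],
    )
    vol_res = volume_group_analysis(
        vol_ds, spec, cutoff_hz=cfg.highpass_cutoff_hz,
        roi_summary_method=cfg.roi_summary_method,
    )
    results["volume"] = vol_res

    # 4. Granger causality
    gci_tab = subject_gci_table(roi_ds, cfg.channel_objects(), order=cfg.gci_order)
    gci_stats = gci_group_stats(gci_tab)
    results["gci_table"] = gci_tab
    results["gci_stats"] = gci_stats

    # 5. classification features: ROI contrast estimates + GCI channels
    wide = contrast_tab.pivot_table(
        index="subject_id", columns=["contrast", "roi"], values="estimate"
    )
    wide.columns = [f"{c}:{r}" for c, r in wide.columns]
    origins = {c: ("contrast_" + c.split(":")[0]) for c in wide.columns}
    gci_wide = gci_tab.drop(columns="group")
    for c in gci_wide.columns:
        origins[f"gci:{c}"] = "gci"
    gci_wide = gci_wide.rename(columns={c: f"gci:{c}" for c in gci_wide.columns})
    candidates = wide.join(gci_wide)
    labels = gci_tab["group"].reindex(candidates.index).to_numpy()
    cls = _classification_stage(cfg, candidates, labels, origins, seeds[4])
    results["classification"] = cls

    # 6. behavior
    results["adaptation"] = conflict_adaptation(rt)
    results["rt_comparisons"] = rt_group_comparisons(rt)

    if write:
        _write_bundle(cfg, results)
    return results


def _write_bundle(cfg: RunConfig, results: dict) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = []
    for name, sub in results["volume"]["contrasts"].items():
        t = sub["table"].copy()
        t.insert(0, "contrast", name)
        tables.append(t)
    pd.concat(tables, ignore_index=True).to_csv(out / "cluster_table.csv", index=False)
    results["gci_stats"].to_csv(out / "gci_group_table.csv")
    results["gci_table"].to_csv(out / "gci_subject_table.csv")
    cls = results["classification"]
    cls["accuracy_table"].to_csv(out / "accuracy_table.csv", index=False)
    cls["learning_curve"].to_csv(out / "learning_curve.csv", index=False)
    pd.Series(cls["contributions"], name="contribution").rename_axis(
        "feature"
    ).to_csv(out / "contributions.csv")
    results["contrast_table"].to_csv(out / "contrast_table.csv", index=False)
    results["rt_table"].to_csv(out / "rt_table.csv", index=False)
    adapt = pd.DataFrame(
        [
            {
                "group": a.group,
                "adaptation_ms": a.adaptation_ms,
                **{f"mean_{k}": v for k, v in a.per_condition_means.items()},
                **{f"se_{k}": v for k, v in a.per_condition_ses.items()},
            }
            for a in results["adaptation"].values()
        ]
    )
    adapt.to_csv(out / "adaptation.csv", index=False)
    results["rt_comparisons"]["anova"].to_csv(out / "anova.csv")
    cfg_dict = asdict(cfg)
    manifest = {
        "package": "emostroop",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "cluster_extent_k": int(results["volume"]["k"]),
        "versions": _library_versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _library_versions() -> dict:
    import nibabel
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "nibabel": nibabel.__version__,
    }
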