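"""Emotional-Stroop trial structure and first-level design matrices.

The task presents face stimuli whose overlaid emotion word is congruent (C)
or incongruent (I) with the facial expression.  Each trial is classified
jointly by its own congruency and that of the preceding trial, giving the
four pair types cC, iC, cI, iI (lowercase = previous trial).  Sequences are
pseudorandom but counterbalanced so the four pair types occur in maximally
equal numbers.

The design matrix follows standard event-related GLM practice: one
HRF-convolved boxcar regressor per pair type (correct trials only), a
separate error-trial regressor, six motion covariates, an intercept, and a
discrete-cosine drift basis implementing high-pass filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Trial",
    "TrialSequence",
    "HrfSpec",
    "DesignMatrix",
    "generate_trial_sequence",
    "canonical_hrf",
    "dct_highpass_basis",
    "build_design_matrix",
]

PAIR_TYPES = ("cC", "iC", "cI", "iI")
CONDITIONS = ("C", "I")


@dataclass(frozen=True)
class Trial:
    index: int
    onset_s: float
    condition: str  # "C" or "I"
    pair_type: str  # one of PAIR_TYPES, or "undefined" for the first trial
    correct: bool = True


@dataclass(frozen=True)
class TrialSequence:
    """Ordered trials with onsets and pair-type labels."""

    trials: tuple[Trial, ...]
    total_duration_s: float
    stimulus_duration_s: float = 1.0

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def conditions(self) -> list[str]:
        return [t.condition for t in self.trials]

    def pair_type_counts(self) -> dict[str, int]:
        counts = {p: 0 for p in PAIR_TYPES}
        for t in self.trials:
            if t.pair_type in counts:
                counts[t.pair_type] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [t.onset_s for t in self.trials],
                "duration_s": self.stimulus_duration_s,
                "condition": [t.condition for t in self.trials],
                "pair_type": [t.pair_type for t in self.trials],
                "correct": [t.correct for t in self.trials],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialSequence":
        trials = tuple(
            Trial(
                index=i,
                onset_s=float(r.onset_s),
                condition=str(r.condition),
                pair_type=str(r.pair_type),
                correct=bool(r.correct),
            )
            for i, r in enumerate(df.itertuples())
        )
        dur = float(df["duration_s"].iloc[0]) if "duration_s" in df else 1.0
        total = float(df["onset_s"].iloc[-1]) + dur + 4.0
        return cls(trials=trials, total_duration_s=total, stimulus_duration_s=dur)

    @classmethod
    def from_csv(cls, path) -> "TrialSequence":
        return cls.from_frame(pd.read_csv(path))


def pair_types_from_conditions(conditions: list[str]) -> list[str]:
    """Recount pair types from a condition list (first trial is undefined)."""
    out = ["undefined"]
    for prev, cur in zip(conditions[:-1], conditions[1:]):
        out.append(prev.lower() + cur)
    return out


def _balanced_pair_counts(n_pairs: int, rng: np.random.Generator) -> dict[str, int]:
    """Split n_pairs over the four pair types with max-min <= 1, feasibly.

    A condition sequence realizes pair counts m iff it is a walk on the
    two-node graph {C, I}; this requires |m_cI - m_iC| <= 1.  The remainder
    pair types are drawn at random subject to that constraint.
    """
    base, rem = divmod(n_pairs, 4)
    counts = {p: base for p in PAIR_TYPES}
    if rem == 0:
        return counts
    # enumerate remainder assignments that a walk on {C, I} can realize:
    # near-balanced crossings, and no two disconnected self-loop blocks
    feasible = []
    for combo in _combinations(PAIR_TYPES, rem):
        trial = dict(counts)
        for p in combo:
            trial[p] += 1
        balanced = abs(trial["cI"] - trial["iC"]) <= 1
        connected = not (
            trial["cI"] + trial["iC"] == 0
            and trial["cC"] > 0
            and trial["iI"] > 0
        )
        if balanced and connected:
            feasible.append(combo)
    combo = feasible[rng.integers(len(feasible))]
    for p in combo:
        counts[p] += 1
    return counts


def _combinations(items, r):
    from itertools import combinations

    return list(combinations(items, r))


def _sequence_from_counts(
    counts: dict[str, int], rng: np.random.Generator, max_restarts: int = 200
) -> list[str]:
    """Random walk on {C, I} consuming the requested transition counts.

    Greedy randomized construction with restarts; for a two-node multigraph
    the failure probability per attempt is small.
    """
    n_pairs = sum(counts.values())
    for _ in range(max_restarts):
        remaining = dict(counts)
        # choose a feasible start node: if cI > iC start at C, if iC > cI at I
        if remaining["cI"] > remaining["iC"]:
            node = "C"
        elif remaining["iC"] > remaining["cI"]:
            node = "I"
        else:
            node = CONDITIONS[rng.integers(2)]
        seq = [node]
        ok = True
        for _ in range(n_pairs):
            stay = remaining[node.lower() + node]
            if node == "C":
                leave = remaining["cI"]
                nxt_leave = "I"
            else:
                leave = remaining["iC"]
                nxt_leave = "C"
            total = stay + leave
            if total == 0:
                ok = False
                break
            if rng.random() < stay / total:
                nxt = node
            else:
                nxt = nxt_leave
            remaining[node.lower() + nxt] -= 1
            seq.append(nxt)
            node = nxt
        if ok and all(v == 0 for v in remaining.values()):
            return seq
    raise RuntimeError(
        "could not realize counterbalanced pair counts "
        f"{counts} in {max_restarts} restarts"
    )


def generate_trial_sequence(
    n_trials: int = 148,
    stimulus_duration_s: float = 1.0,
    isi_min_s: float = 3.0,
    isi_max_s: float = 5.0,
    seed: int | np.random.Generator = 0,
    error_rate: float = 0.0,
    first_onset_s: float = 0.0,
) -> TrialSequence:
    """Generate a pseudorandom, counterbalanced congruent/incongruent sequence.

    Pair-type counts over the ``n_trials - 1`` classifiable pairs are
    maximally balanced (max - min <= 1).  ISIs are uniform on
    [isi_min_s, isi_max_s], so the mean ISI is their midpoint in expectation.
    Deterministic given ``seed``.

    Parameters
    ----------
    error_rate : probability that a trial is marked incorrect (default 0:
        all trials correct).
    """
    if n_trials < 2:
        raise ValueError(f"n_trials must be >= 2, got {n_trials}")
    if isi_min_s > isi_max_s:
        raise ValueError("isi_min_s must be <= isi_max_s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counts = _balanced_pair_counts(n_trials - 1, rng)
    conditions = _sequence_from_counts(counts, rng)
    pair_types = pair_types_from_conditions(conditions)

    isis = rng.uniform(isi_min_s, isi_max_s, size=n_trials)
    onsets = first_onset_s + np.concatenate(
        [[0.0], np.cumsum(stimulus_duration_s + isis[:-1])]
    )
    correct = rng.random(n_trials) >= error_rate

    trials = tuple(
        Trial(
            index=i,
            onset_s=float(onsets[i]),
            condition=conditions[i],
            pair_type=pair_types[i],
            correct=bool(correct[i]),
        )
        for i in range(n_trials)
    )
    total = float(onsets[-1] + stimulus_duration_s + isis[-1])
    return TrialSequence(
        trials=trials,
        total_duration_s=total,
        stimulus_duration_s=stimulus_duration_s,
    )


@dataclass(frozen=True)
class HrfSpec:
    """Double-gamma hemodynamic response function parameters.

    Defaults are the canonical shape used throughout event-related fMRI:
    response peaking at 6 s, undershoot at 16 s, unit dispersions,
    peak:undershoot amplitude ratio 6.
    """

    dt_s: float = 0.125
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0

    def __post_init__(self):
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.length_s < self.peak_delay_s:
            raise ValueError("length_s must cover the peak delay")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")


def canonical_hrf(spec: HrfSpec = HrfSpec()) -> np.ndarray:
    """Sample the double-gamma HRF on a grid of step ``spec.dt_s``.

    h(t) = Gamma(peak_delay/disp + 1, disp).pdf(t)
         - Gamma(undershoot_delay/disp + 1, disp).pdf(t) / ratio,
    normalised to unit peak.  The gamma shapes are chosen so each lobe's
    mode falls exactly at its configured delay; h(0) = 0.
    """
    t = np.arange(int(np.ceil(spec.length_s / spec.dt_s))) * spec.dt_s
    peak = stats.gamma.pdf(
        t, spec.peak_delay_s / spec.peak_dispersion + 1.0,
        scale=spec.peak_dispersion,
    )
    under = stats.gamma.pdf(
        t,
        spec.undershoot_delay_s / spec.undershoot_dispersion + 1.0,
        scale=spec.undershoot_dispersion,
    )
    h = peak - under / spec.peak_undershoot_ratio
    return h / np.max(np.abs(h))


def dct_highpass_basis(n_scans: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift basis for high-pass filtering.

    Returns the DCT columns (excluding the constant) with frequency below
    ``cutoff_hz``; with period T = n_scans * tr_s the k-th component has
    frequency k / (2T), so the number of columns is
    floor(2 * n_scans * tr_s * cutoff_hz).  Columns are mutually orthogonal.
    """
    if n_scans < 2:
        raise ValueError("n_scans must be >= 2")
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    nyquist = 1.0 / (2.0 * tr_s)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz: the drift basis "
            "would span all frequencies"
        )
    n_basis = int(np.floor(2.0 * n_scans * tr_s * cutoff_hz))
    t = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans))
        for k in range(1, n_basis + 1)
    ]
    if not cols:
        return np.empty((n_scans, 0))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """Time x regressor matrix with names and sampling metadata."""

    values: np.ndarray
    regressor_names: list[str]
    tr_s: float
    highpass_cutoff_hz: float
    n_scans: int

    def __post_init__(self):
        if self.values.shape != (self.n_scans, len(self.regressor_names)):
            raise ValueError("values shape inconsistent with names / n_scans")

    task_regressors: tuple[str, ...] = field(
        default=("cC", "iC", "cI", "iI", "error"), repr=False
    )

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.regressor_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.regressor_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _sampled_regressor(
    onsets: np.ndarray,
    n_scans: int,
    tr_s: float,
    hrf_kernel: np.ndarray,
    dt_s: float,
    duration_s: float,
    as_sticks: bool,
) -> np.ndarray:
    """Boxcar (or stick) at microtime resolution, convolved and downsampled."""
    n_fine = int(np.ceil(n_scans * tr_s / dt_s)) + len(hrf_kernel)
    u = np.zeros(n_fine)
    for onset in onsets:
        i0 = int(np.round(onset / dt_s))
        if as_sticks:
            u[i0] += 1.0
        else:
            i1 = max(i0 + 1, int(np.round((onset + duration_s) / dt_s)))
            u[i0:i1] += 1.0
    x = np.convolve(u, hrf_kernel)[:n_fine]
    # sample at slice-middle acquisition times
    scan_t = (np.arange(n_scans) + 0.5) * tr_s
    idx = np.clip(np.round(scan_t / dt_s).astype(int), 0, n_fine - 1)
    return x[idx]


def build_design_matrix(
    seq: TrialSequence,
    n_scans: int,
    tr_s: float = 2.0,
    hrf: HrfSpec | None = None,
    cutoff_hz: float = 1.0 / 128.0,
    motion: np.ndarray | None = None,
    oversampling: int = 16,
    events_as_sticks: bool = False,
) -> DesignMatrix:
    """Assemble the first-level design matrix for one subject.

    Columns: cC, iC, cI, iI (correct trials only, 1 s boxcars convolved with
    the HRF), an error regressor built from incorrect trials, six motion
    parameters, an intercept, and the DCT drift basis below ``cutoff_hz``.

    The first trial, whose pair type is undefined, is assigned to the
    regressor of its own condition with a congruent prior (C -> cC, I -> cI).
    """
    hrf = hrf or HrfSpec(dt_s=tr_s / oversampling)
    dt = tr_s / oversampling
    if abs(hrf.dt_s - dt) > 1e-12:
        hrf = HrfSpec(
            dt_s=dt,
            peak_delay_s=hrf.peak_delay_s,
            undershoot_delay_s=hrf.undershoot_delay_s,
            peak_dispersion=hrf.peak_dispersion,
            undershoot_dispersion=hrf.undershoot_dispersion,
            peak_undershoot_ratio=hrf.peak_undershoot_ratio,
            length_s=hrf.length_s,
        )
    if motion is None:
        motion = np.zeros((n_scans, 6))
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_scans, 6):
        raise ValueError(f"motion must be ({n_scans}, 6), got {motion.shape}")
    last_onset = max(t.onset_s for t in seq.trials)
    if last_onset >= n_scans * tr_s:
        raise ValueError(
            f"trial onset {last_onset:.1f}s beyond scan duration {n_scans * tr_s:.1f}s"
        )

    kernel = canonical_hrf(hrf)
    onsets_by_type: dict[str, list[float]] = {p: [] for p in PAIR_TYPES}
    error_onsets: list[float] = []
    import warnings

    for t in seq.trials:
        if not t.correct:
            error_onsets.append(t.onset_s)
            continue
        p = t.pair_type
        if p == "undefined":
            p = "c" + t.condition
        onsets_by_type[p].append(t.onset_s)

    columns, names = [], []
    for p in PAIR_TYPES:
        if not onsets_by_type[p]:
            warnings.warn(f"condition {p} has no correct trials: zero column")
            columns.append(np.zeros(n_scans))
        else:
            columns.append(
                _sampled_regressor(
                    np.asarray(onsets_by_type[p]),
                    n_scans,
                    tr_s,
                    kernel,
                    dt,
                    seq.stimulus_duration_s,
                    events_as_sticks,
                )
            )
        names.append(p)
    if error_onsets:
        err = _sampled_regressor(
            np.asarray(error_onsets),
            n_scans,
            tr_s,
            kernel,
            dt,
            seq.stimulus_duration_s,
            events_as_sticks,
        )
    else:
        err = np.zeros(n_scans)
    columns.append(err)
    names.append("error")

    for j in range(6):
        columns.append(motion[:, j])
        names.append(f"mot{j + 1}")
    columns.append(np.ones(n_scans))
    names.append("intercept")
    drift = dct_highpass_basis(n_scans, tr_s, cutoff_hz)
    for j in range(drift.shape[1]):
        columns.append(drift[:, j])
        names.append(f"drift{j + 1}")

    return DesignMatrix(
        values=np.column_stack(columns),
        regressor_names=names,
        tr_s=tr_s,
        highpass_cutoff_hz=cutoff_hz,
        n_scans=n_scans,
    )
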