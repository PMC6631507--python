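"""Experimental harness: training-cycle ablation, paired statistics, reports.

Reproduces the benchmark design: both armband profiles acquire the *same*
master-signal realizations (the simultaneous-wear pairing), each classifier
is trained on the first k = 1..4 training cycles and tested on all four
test cycles, per-participant accuracies (deep models averaged over runs)
are compared across armbands with a two-tailed Wilcoxon signed-rank test
over participants, and a last-cycle-only retraining variant probes the
warm-up question.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import deep_models, synthetic_semg
from .baseline_htd_lda import htd_features, lda_fit, lda_predict
from .device_frontend import AcquiredRecording, DeviceProfile, acquire, builtin_profile
from .preprocessing import (StftConfig, WindowingConfig, butterworth_highpass,
                            extract_windows, spectrogram_tensor)
from .synthetic_semg import (ProtocolConfig, generate_participant_sessions,
                             make_gesture_bank, make_participant, variability_for)

__all__ = [
    "EvalConfig",
    "ExperimentResult",
    "SyntheticStudy",
    "StatsConfig",
    "compare_profiles",
    "confusion_matrix",
    "generate_study",
    "last_cycle_experiment",
    "report",
    "run_comparison",
    "wilcoxon_signed_rank",
]

CLASSIFIERS = ("lda", "raw", "spectrogram", "oracle", "random")
N_GESTURES = 11


# --------------------------------------------------------------------------
# synthetic study container
# --------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """In-memory study: both profiles' recordings of shared master signals."""

    profiles: dict[str, DeviceProfile]
    recordings: dict[tuple[int, str, str], AcquiredRecording]  # (pid, session, profile)
    protocol: ProtocolConfig
    bank: list
    seed: int
    difficulty: str

    @property
    def participant_ids(self) -> list[int]:
        return sorted({pid for pid, _, _ in self.recordings})

    @property
    def profile_names(self) -> list[str]:
        return sorted(self.profiles)

    def recording(self, pid: int, session: str, profile: str) -> AcquiredRecording:
        return self.recordings[(pid, session, profile)]

    def cycle(self, pid: int, session: str, cycle: int, profile: str) -> AcquiredRecording:
        rec = self.recording(pid, session, profile)
        per = int(round(self.protocol.cycle_duration_s * rec.rate))
        a, b = cycle * per, (cycle + 1) * per
        if b > rec.codes.shape[1]:
            raise KeyError(f"cycle {cycle} out of range for participant {pid}")
        t0 = a / rec.rate
        bounds = [(g, s - t0, e - t0) for g, s, e in rec.boundaries
                  if s >= t0 - 1e-9 and e <= b / rec.rate + 1e-9]
        return AcquiredRecording(codes=rec.codes[:, a:b], rate=rec.rate,
                                 labels=rec.labels[a:b], profile=rec.profile,
                                 boundaries=bounds)


def generate_study(
    n_participants: int = 22,
    seed: int = 0,
    difficulty: str = "default",
    profiles: Sequence[DeviceProfile] | None = None,
    protocol: ProtocolConfig = ProtocolConfig(),
    variability=None,
) -> SyntheticStudy:
    """Generate the full synthetic comparison study.

    Every participant's master signals are rendered once on the union
    electrode ring and acquired through every profile, so the per-participant
    pairing across armbands is physically meaningful.
    """
    if profiles is None:
        profiles = (builtin_profile("3dc"), builtin_profile("myo"))
    rng = np.random.default_rng(seed)
    bank = make_gesture_bank(seed, difficulty)
    if variability is None:
        variability = variability_for(difficulty)
    recs: dict[tuple[int, str, str], AcquiredRecording] = {}
    for pid in range(n_participants):
        participant = make_participant(pid, rng, variability)
        train, test = generate_participant_sessions(
            participant, bank, protocol, variability)
        for session, master in (("train", train), ("test", test)):
            for prof in profiles:
                noise_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
                recs[(pid, session, prof.name)] = acquire(
                    master, prof, fidelity="fast", rng=noise_rng)
    return SyntheticStudy(profiles={p.name: p for p in profiles}, recordings=recs,
                          protocol=protocol, bank=bank, seed=seed, difficulty=difficulty)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    n_participants: int = 22

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class EvalConfig:
    train_cycle_counts: tuple[int, ...] = (1, 2, 3, 4)
    n_runs_deep: int = 20           # averaging runs for the stochastic models
    seed: int = 0
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    stft: StftConfig = field(default_factory=StftConfig)
    training: deep_models.TrainingConfig = field(default_factory=deep_models.TrainingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

class WilcoxonResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def wilcoxon_signed_rank(paired_a, paired_b, two_tailed: bool = True,
                         method: str = "auto") -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (Wilcoxon's original rule); tied absolute
    differences receive mid-ranks.  The null distribution is enumerated
    exactly (sign-assignment DP) when n ≤ 25 and there are no ties, and
    approximated by a continuity-corrected normal (with tie-corrected
    variance) otherwise.  Returns min(W+, W−) as the statistic.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, degenerate=True)
    ranks = sp_stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    has_ties = np.unique(np.abs(d)).size < n

    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    if method == "exact" and has_ties:
        raise ValueError("exact enumeration requires untied absolute differences")
    use_exact = method == "exact" or (method == "auto" and n <= 25 and not has_ties)
    if use_exact:
        # exact: subset-sum DP over ranks 1..n
        total = n * (n + 1) // 2
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in range(1, n + 1):
            counts[r:] += counts[:-r].copy()
        cdf = counts[: int(round(w)) + 1].sum() / 2.0**n
        p = 2.0 * cdf if two_tailed else cdf
    else:
        mu = n * (n + 1) / 4.0
        _, t_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(t_counts**3 - t_counts) / 48.0
        z = (w - mu + 0.5) / math.sqrt(var)
        p = 2.0 * sp_stats.norm.cdf(z) if two_tailed else sp_stats.norm.cdf(z)
    return WilcoxonResult(w, float(min(p, 1.0)))


def confusion_matrix(true, predicted, n_classes: int = N_GESTURES) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    t = np.asarray(true, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


# --------------------------------------------------------------------------
# pipelines
# --------------------------------------------------------------------------

def _cycle_windows(study, profile: str, pid: int, session: str,
                   cycles: Iterable[int], cfg: EvalConfig):
    """High-pass filter each cycle, then window it: (X raw windows, labels)."""
    xs, ys = [], []
    for c in cycles:
        rec = study.cycle(pid, session, c, profile)
        filt = butterworth_highpass(rec.volts, rec.rate)
        for wex in extract_windows(filt, rec.labels, rec.rate, cfg.windowing):
            xs.append(wex.payload)
            ys.append(wex.label)
    return np.stack(xs), np.asarray(ys), study.cycle(pid, session, 0, profile).rate


def _standardize(train: np.ndarray, test: np.ndarray, channel_axis: int = 1):
    """Channel-wise zero-mean/unit-variance using training statistics only."""
    axes = tuple(i for i in range(train.ndim) if i != channel_axis)
    mu = train.mean(axis=axes, keepdims=True)
    sd = train.std(axis=axes, keepdims=True) + 1e-12
    return (train - mu) / sd, (test - mu) / sd


def _run_cell(classifier: str, Xtr, ytr, Xte, yte, rate, cfg: EvalConfig,
              seed: int) -> tuple[float, np.ndarray]:
    """Train/evaluate one grid cell; returns (accuracy, confusion)."""
    if classifier == "oracle":
        pred = yte.copy()
    elif classifier == "random":
        pred = np.random.default_rng(seed).integers(0, N_GESTURES, size=yte.size)
    elif classifier == "lda":
        ftr = np.stack([htd_features(w) for w in Xtr])
        fte = np.stack([htd_features(w) for w in Xte])
        model = lda_fit(ftr, ytr)
        pred = lda_predict(model, fte)
    elif classifier in ("raw", "spectrogram"):
        if classifier == "raw":
            Atr, Ate = _standardize(Xtr, Xte)
            model = deep_models.build_raw_convnet(Atr.shape[1:])
            lr = deep_models.RAW_LR
        else:
            Str = np.stack([spectrogram_tensor(w, cfg.stft, rate).payload for w in Xtr])
            Ste = np.stack([spectrogram_tensor(w, cfg.stft, rate).payload for w in Xte])
            Atr, Ate = _standardize(Str, Ste, channel_axis=2)
            reduced = not (Atr.shape[2] // 4 >= 2 and Atr.shape[3] // 4 >= 3)
            model = deep_models.build_spectrogram_convnet(Atr.shape[1:], myo_reduced=reduced)
            lr = deep_models.SPECTROGRAM_LR
        tc = replace(cfg.training, lr=lr)
        deep_models.train(model, Atr, ytr, tc, seed=seed)
        pred = deep_models.predict(model, Ate)
    else:
        raise ValueError(f"unknown classifier {classifier!r}; expected one of {CLASSIFIERS}")
    acc = float(np.mean(pred == yte))
    return acc, confusion_matrix(yte, pred)


# --------------------------------------------------------------------------
# experiment grid
# --------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Accuracies and confusion matrices on the full evaluation grid.

    ``accuracy[(profile, classifier, k, participant, run)]`` in [0, 1];
    ``confusion`` holds the matching 11×11 count matrices.
    """

    accuracy: dict[tuple, float] = field(default_factory=dict)
    confusion: dict[tuple, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def per_participant(self, profile: str, classifier: str, k: int) -> np.ndarray:
        """Run-averaged accuracy per participant (the Wilcoxon pairing unit)."""
        pids = sorted({key[3] for key in self.accuracy
                       if key[:3] == (profile, classifier, k)})
        out = []
        for pid in pids:
            runs = [v for key, v in self.accuracy.items()
                    if key[:4] == (profile, classifier, k, pid)]
            out.append(float(np.mean(runs)))
        return np.asarray(out)

    def mean_accuracy(self, profile: str, classifier: str, k: int) -> float:
        return float(np.mean(self.per_participant(profile, classifier, k)))

    def sd_across_participants(self, profile: str, classifier: str, k: int) -> float:
        return float(np.std(self.per_participant(profile, classifier, k), ddof=1))

    def total_confusion(self, profile: str, classifier: str, k: int) -> np.ndarray:
        mats = [m for key, m in self.confusion.items()
                if key[:3] == (profile, classifier, k)]
        return np.sum(mats, axis=0)

    def cells(self):
        return sorted({key[:3] for key in self.accuracy})

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"profile": p, "classifier": c, "n_train_cycles": k,
                 "participant": pid, "run": r, "accuracy": v}
                for (p, c, k, pid, r), v in self.accuracy.items()]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "meta": self.meta,
            "accuracy": [[list(k), v] for k, v in self.accuracy.items()],
            "confusion": [[list(k), m.tolist()] for k, m in self.confusion.items()],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentResult":
        payload = json.loads(Path(path).read_text())
        return cls(
            accuracy={tuple(k): float(v) for k, v in payload["accuracy"]},
            confusion={tuple(k): np.asarray(m) for k, m in payload["confusion"]},
            meta=payload.get("meta", {}),
        )


def run_comparison(
    study: SyntheticStudy,
    profiles: Sequence[str] = ("3dc", "myo"),
    classifiers: Sequence[str] = ("lda",),
    config: EvalConfig = EvalConfig(),
    train_cycle_sets: dict[int, tuple[int, ...]] | None = None,
    participants: Sequence[int] | None = None,
) -> ExperimentResult:
    """Run the training-cycle ablation over the grid.

    For each (profile, classifier, k): train on the first k training cycles
    (k = 1..4 by default; ``train_cycle_sets`` can override, e.g. the
    last-cycle experiment), test on all four test cycles.  Deterministic
    classifiers run once; stochastic ones are averaged over
    ``config.n_runs_deep`` seeded runs.
    """
    if train_cycle_sets is None:
        train_cycle_sets = {k: tuple(range(k)) for k in config.train_cycle_counts}
    pids = list(participants) if participants is not None else study.participant_ids
    for p in profiles:
        if p not in study.profiles:
            raise KeyError(f"profile {p!r} not present in the study")
    for c in classifiers:
        if c not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {c!r}; expected one of {CLASSIFIERS}")
    test_cycles = tuple(range(study.protocol.cycles_per_session))

    result = ExperimentResult(meta={
        "seed": config.seed, "difficulty": study.difficulty,
        "n_runs_deep": config.n_runs_deep,
        "train_cycle_sets": {k: list(v) for k, v in train_cycle_sets.items()},
    })
    for profile in profiles:
        for pid in pids:
            Xte, yte, rate = _cycle_windows(study, profile, pid, "test", test_cycles, config)
            for k, cycles in train_cycle_sets.items():
                Xtr, ytr, _ = _cycle_windows(study, profile, pid, "train", cycles, config)
                for classifier in classifiers:
                    stochastic = classifier in ("raw", "spectrogram", "random")
                    n_runs = config.n_runs_deep if stochastic else 1
                    for run in range(n_runs):
                        seed = (config.seed * 1_000_003 + hash((profile, classifier))
                                % 65_521 + 97 * pid + 13 * k + run) % (2**31 - 1)
                        acc, cm = _run_cell(classifier, Xtr, ytr, Xte, yte, rate,
                                            config, seed)
                        key = (profile, classifier, k, pid, run)
                        result.accuracy[key] = acc
                        result.confusion[key] = cm
    return result


def last_cycle_experiment(
    study: SyntheticStudy,
    classifiers: Sequence[str] = ("lda",),
    config: EvalConfig = EvalConfig(),
    profiles: Sequence[str] = ("3dc", "myo"),
) -> ExperimentResult:
    """Retrain with only the *last* training cycle (longest warm-up)."""
    last = study.protocol.cycles_per_session - 1
    return run_comparison(study, profiles, classifiers, config,
                          train_cycle_sets={1: (last,)})


def compare_profiles(result: ExperimentResult, classifier: str, k: int,
                     profile_a: str = "3dc", profile_b: str = "myo") -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank across participants for one grid cell."""
    a = result.per_participant(profile_a, classifier, k)
    b = result.per_participant(profile_b, classifier, k)
    return wilcoxon_signed_rank(a, b)


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def report(result: ExperimentResult, out_dir: str | Path,
           alpha: float = 0.05) -> dict[str, Path]:
    """Write CSV summaries and figures for an experiment grid.

    ``summary.csv``: mean and across-participant standard deviation per
    cell.  ``comparison.csv``: Wilcoxon p per (classifier, k); the
    annotation column is filled only when the null is rejected at ``alpha``
    (mirroring how the benchmark's figures print p-values).  Bar charts and
    confusion heatmaps are rendered as PNG.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    cells = result.cells()
    rows = [{"profile": p, "classifier": c, "n_train_cycles": k,
             "mean_accuracy": result.mean_accuracy(p, c, k),
             "sd_across_participants": result.sd_across_participants(p, c, k)}
            for p, c, k in cells]
    summary = pd.DataFrame(rows)
    written["summary"] = out / "summary.csv"
    summary.to_csv(written["summary"], index=False)

    profiles = sorted({p for p, _, _ in cells})
    comp_rows = []
    if len(profiles) == 2:
        pa, pb = profiles
        for c in sorted({c for _, c, _ in cells}):
            for k in sorted({k for _, cc, k in cells if cc == c}):
                res = wilcoxon_signed_rank(result.per_participant(pa, c, k),
                                           result.per_participant(pb, c, k))
                comp_rows.append({
                    "classifier": c, "n_train_cycles": k,
                    "profile_a": pa, "profile_b": pb,
                    "statistic": res.statistic, "p_value": res.pvalue,
                    "annotation": f"p={res.pvalue:.4g}" if res.pvalue < alpha else "",
                })
        written["comparison"] = out / "comparison.csv"
        pd.DataFrame(comp_rows).to_csv(written["comparison"], index=False)

    for c in sorted({c for _, c, _ in cells}):
        fig, ax = plt.subplots(figsize=(6, 4))
        ks = sorted({k for _, cc, k in cells if cc == c})
        width = 0.8 / max(len(profiles), 1)
        for i, p in enumerate(profiles):
            means = [result.mean_accuracy(p, c, k) for k in ks]
            sds = [result.sd_across_participants(p, c, k) for k in ks]
            ax.bar(np.arange(len(ks)) + i * width, means, width,
                   yerr=sds, capsize=3, label=p)
        ax.set_xticks(np.arange(len(ks)) + width / 2)
        ax.set_xticklabels([str(k) for k in ks])
        ax.set_xlabel("training cycles")
        ax.set_ylabel("accuracy")
        ax.set_ylim(0, 1)
        ax.set_title(f"{c}: accuracy by training cycles")
        ax.legend()
        fig.tight_layout()
        path = out / f"accuracy_{c}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written[f"accuracy_{c}"] = path

        kmax = max(ks)
        for p in profiles:
            cm = result.total_confusion(p, c, kmax)
            fig, ax = plt.subplots(figsize=(5, 4.5))
            frac = cm / np.maximum(cm.sum(axis=1, keepdims=True), 1)
            im = ax.imshow(frac, cmap="viridis", vmin=0, vmax=1)
            ax.set_xlabel("predicted gesture")
            ax.set_ylabel("true gesture")
            ax.set_title(f"{p} / {c} / {kmax} cycles")
            fig.colorbar(im)
            fig.tight_layout()
            path = out / f"confusion_{p}_{c}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written[f"confusion_{p}_{c}"] = path
    return written
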