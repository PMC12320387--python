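"""Evaluation protocols: within-subject k-fold, leave-one-subject-out,
the static-vs-dynamic ablation, and the attention-head sensitivity sweep.

Two protocols mirror standard practice in EEG emotion recognition:

* **subject-dependent**: each subject's data is split 5-fold (80/20) and a
  fresh model is trained per fold; the reported figure is the mean and
  standard deviation of per-subject accuracies.
* **subject-independent (LOSO)**: each subject is held out in turn, a
  model is trained on everyone else, and per-held-out-subject accuracies
  are summarized.

Folds are formed at *trial* granularity by default — all analysis windows
of a trial land in the same fold — which prevents near-duplicate windows
from leaking between train and test. A window-level mode is available for
comparison with pipelines that split at the window level.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .model import DGATClassifier, DGATResults, EvalReport, ModelConfig, _confusion
from .montage import DEFeatureTensor

__all__ = [
    "subject_dependent_cv",
    "loso_cv",
    "ablation_static_vs_dynamic",
    "head_count_sweep",
    "trial_folds",
]


def trial_folds(
    tensor: DEFeatureTensor,
    k: int,
    rng: np.random.Generator,
    granularity: str = "trial",
) -> list[np.ndarray]:
    """Partition window indices into k folds.

    ``granularity="trial"`` shuffles trials and deals them round-robin into
    folds so every window of a trial shares a fold; ``"window"`` deals
    individual windows. Folds are pairwise disjoint and cover all windows.
    """
    if granularity == "trial":
        units = np.unique(tensor.trial_index)
        if len(units) < k:
            raise ValueError(f"need >= {k} trials for {k}-fold splitting, have {len(units)}")
        perm = rng.permutation(units)
        unit_fold = {int(u): i % k for i, u in enumerate(perm)}
        assign = np.array([unit_fold[int(t)] for t in tensor.trial_index])
    elif granularity == "window":
        n = tensor.n_windows
        if n < k:
            raise ValueError(f"need >= {k} windows, have {n}")
        assign = np.empty(n, dtype=int)
        assign[rng.permutation(n)] = np.arange(n) % k
    else:
        raise ValueError("granularity must be 'trial' or 'window'")
    return [np.flatnonzero(assign == f) for f in range(k)]


def _fit_eval(
    tensor: DEFeatureTensor,
    config: ModelConfig,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[EvalReport, DGATResults]:
    res = DGATClassifier(tensor, config).fit(train_idx)
    report = res.evaluate(tensor.values[test_idx], tensor.labels[test_idx])
    return report, res


def subject_dependent_cv(
    features_by_subject: list[DEFeatureTensor],
    config: ModelConfig,
    k: int = 5,
    granularity: str = "trial",
) -> EvalReport:
    """Within-subject k-fold cross-validation, averaged over subjects.

    For every subject the windows are split into k folds (trial-level by
    default), one model is trained per fold on the remaining k-1 folds,
    and the subject's accuracy is the pooled accuracy over its test folds.
    Fold assignment and training are deterministic given ``config.seed``.
    """
    if not features_by_subject:
        raise ValueError("no subjects given")
    confusion = np.zeros((config.n_classes, config.n_classes), dtype=int)
    per_subject: dict[str, float] = {}
    for si, tensor in enumerate(features_by_subject):
        rng = np.random.default_rng(config.seed * 100003 + si)
        folds = trial_folds(tensor, k, rng, granularity)
        subj_conf = np.zeros_like(confusion)
        for f, test_idx in enumerate(folds):
            train_idx = np.concatenate([folds[j] for j in range(k) if j != f])
            fold_cfg = replace(config, seed=config.seed + 1000 * si + f)
            report, _ = _fit_eval(tensor, fold_cfg, train_idx, test_idx)
            subj_conf += report.confusion
        confusion += subj_conf
        per_subject[tensor.subject_id] = float(
            np.trace(subj_conf) / subj_conf.sum()
        )
    return EvalReport.from_confusion(confusion, per_subject)


def _concat(tensors: list[DEFeatureTensor]) -> DEFeatureTensor:
    base = tensors[0]
    return DEFeatureTensor(
        values=np.concatenate([t.values for t in tensors]),
        band_edges=base.band_edges,
        window_s=base.window_s,
        montage=base.montage,
        labels=np.concatenate([t.labels for t in tensors]),
        subject_id="pooled",
        trial_index=np.concatenate(
            [t.trial_index + 10_000 * i for i, t in enumerate(tensors)]
        ),
    )


def loso_cv(
    features_by_subject: list[DEFeatureTensor], config: ModelConfig
) -> EvalReport:
    """Leave-one-subject-out: train on all other subjects, test on one."""
    if len(features_by_subject) < 2:
        raise ValueError("LOSO needs at least two subjects")
    confusion = np.zeros((config.n_classes, config.n_classes), dtype=int)
    per_subject: dict[str, float] = {}
    for si, held_out in enumerate(features_by_subject):
        rest = [t for j, t in enumerate(features_by_subject) if j != si]
        pooled = _concat(rest)
        cfg = replace(config, seed=config.seed + 1000 * si)
        res = DGATClassifier(pooled, cfg).fit()
        report = res.evaluate(held_out.values, held_out.labels)
        confusion += report.confusion
        per_subject[held_out.subject_id] = report.accuracy
    return EvalReport.from_confusion(confusion, per_subject)


def ablation_static_vs_dynamic(
    features_by_subject: list[DEFeatureTensor],
    config: ModelConfig,
    k: int = 5,
    protocol: str = "subject-dependent",
) -> dict[str, EvalReport]:
    """Matched comparison of the dynamic model against a static-adjacency arm.

    Both arms use identical seeds, folds, and hyperparameters; the static
    arm freezes the adjacency at the Gaussian-kernel initialization
    (momentum 1, non-trainable buffer), so its attention cannot adapt to
    the data while everything else is unchanged.
    """
    dynamic_cfg = config
    static_cfg = replace(config, beta=1.0, adjacency_trainable=False)
    run = (
        (lambda c: subject_dependent_cv(features_by_subject, c, k))
        if protocol == "subject-dependent"
        else (lambda c: loso_cv(features_by_subject, c))
    )
    return {"dynamic": run(dynamic_cfg), "static": run(static_cfg)}


def head_count_sweep(
    features_by_subject: list[DEFeatureTensor],
    config: ModelConfig,
    ks: list[int],
    k_folds: int = 5,
) -> dict[int, EvalReport]:
    """Re-run the subject-dependent protocol for each attention-head count."""
    if not ks:
        raise ValueError("no head counts given")
    out: dict[int, EvalReport] = {}
    for n_heads in ks:
        cfg = replace(config, n_heads=int(n_heads))
        out[n_heads] = subject_dependent_cv(features_by_subject, cfg, k_folds)
    return out
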