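"""Evaluation metrics for transition models."""

from __future__ import annotations

import numpy as np

from .dataset import ExampleSet

__all__ = ["evaluate", "mean_tv_distance"]


def _predict(model, examples: ExampleSet):
    X = examples.X if getattr(model, "requires_features", True) else None
    ctx = examples.context if getattr(model, "requires_context", False) else None
    return model.predict(X, context=ctx)


def _align(p: np.ndarray, class_ids: np.ndarray, union: np.ndarray) -> np.ndarray:
    out = np.zeros((len(p), len(union)))
    pos = {int(s): i for i, s in enumerate(union)}
    cols = [pos[int(s)] for s in class_ids]
    out[:, cols] = p
    return out


def mean_tv_distance(
    p: np.ndarray, p_ids: np.ndarray, q: np.ndarray, q_ids: np.ndarray
) -> float:
    """Mean total-variation distance between two sets of distributions whose
    columns may cover different state supports."""
    union = np.union1d(p_ids, q_ids)
    pa = _align(p, p_ids, union)
    qa = _align(q, q_ids, union)
    return float(0.5 * np.abs(pa - qa).sum(axis=1).mean())


def evaluate(model, test: ExampleSet, reference=None) -> dict[str, float]:
    """Top-1 / top-3 accuracies of both heads; optionally the mean TV
    distance of the target-state head to a reference model's distributions
    (computed over uncensored rows).

    The timing head is scored on all rows (censored class included); the
    state head only where a transition was observed.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    p_dr, p_st = _predict(model, test)
    out: dict[str, float] = {}
    out["top1_dr"] = float((p_dr.argmax(axis=1) == test.y_dr).mean())

    unc = test.y_dr != 0
    class_ids = np.asarray(model.state_class_ids)
    if unc.any():
        order = np.argsort(-p_st[unc], axis=1)
        top = class_ids[order[:, :3]]
        truth = test.y_state[unc][:, None]
        out["top1_state"] = float((top[:, :1] == truth).any(axis=1).mean())
        out["top3_state"] = float((top == truth).any(axis=1).mean())
    else:
        out["top1_state"] = float("nan")
        out["top3_state"] = float("nan")

    if reference is not None and unc.any():
        _, q_st = _predict(reference, test)
        out["mean_tv_state"] = mean_tv_distance(
            p_st[unc], class_ids, q_st[unc], np.asarray(reference.state_class_ids)
        )
    return out
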