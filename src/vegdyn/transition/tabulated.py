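"""Tabulated and kernel-derived transition models.

These serve as empirical baselines and as exact oracles on synthetic data:

* :func:`fit_tabulated` — empirical conditional frequencies over a set of
  discretized key predictors, with marginal backoff for unseen keys;
* :func:`kernel_tabulated` — a lookup table computed from a ground-truth
  kernel's probabilities (the Bayes classifier on data generated by it);
* :class:`KernelDirectModel` — evaluates the kernel's closed-form
  probabilities directly from a raw context frame.

Kernel objects are duck-typed: they expose ``state_ids``, ``hazard``,
``target_support`` and ``target_probs_batch`` (see ``vegdyn.synthetic``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TabulatedModel",
    "fit_tabulated",
    "kernel_tabulated",
    "KernelDirectModel",
    "dr_distribution_from_hazard",
]


class TabulatedModel:
    """Lookup-table transition model keyed on discretized context columns."""

    requires_features = False
    requires_context = True

    def __init__(
        self,
        keys: tuple[str, ...],
        table: dict[tuple, tuple[np.ndarray, np.ndarray]],
        marginal: tuple[np.ndarray, np.ndarray],
        state_class_ids: np.ndarray,
        horizon: int = 10,
        bins: dict[str, np.ndarray] | None = None,
        r_cap: int | None = None,
    ) -> None:
        self.keys = tuple(keys)
        self.table = table
        self.marginal = marginal
        self.state_class_ids = np.asarray(state_class_ids, dtype=np.int64)
        self.horizon = horizon
        self.n_dr = horizon + 1
        self.bins = bins or {}
        self.r_cap = r_cap
        self.backoff_count = 0  # unseen keys served from the marginal

    def _key_columns(self, context: pd.DataFrame) -> list[np.ndarray]:
        cols = []
        for key in self.keys:
            v = context[key].to_numpy()
            if key == "R" and self.r_cap is not None:
                v = np.minimum(v.astype(np.int64), self.r_cap)
            if key in self.bins:
                v = np.digitize(v.astype(float), self.bins[key])
            cols.append(v)
        return cols

    def predict(
        self, X: np.ndarray | None = None, context: pd.DataFrame | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        if context is None:
            raise ValueError("tabulated model needs a context frame")
        cols = self._key_columns(context)
        n = len(context)
        p_dr = np.empty((n, self.n_dr))
        p_st = np.empty((n, len(self.state_class_ids)))
        self.backoff_count = 0
        # group rows by key to avoid a per-row dict lookup
        key_rows: dict[tuple, list[int]] = {}
        for i, key in enumerate(zip(*cols)):
            key_rows.setdefault(tuple(np.asarray(key).tolist()), []).append(i)
        for key, rows in key_rows.items():
            if key in self.table:
                dr, st = self.table[key]
            else:
                dr, st = self.marginal
                self.backoff_count += len(rows)
            p_dr[rows] = dr
            p_st[rows] = st
        return p_dr, p_st


def fit_tabulated(
    examples,
    keys: tuple[str, ...] = ("state_id", "R"),
    bins: dict[str, np.ndarray] | None = None,
    alpha: float = 0.0,
    r_cap: int | None = None,
) -> TabulatedModel:
    """Empirical conditional distributions over discretized key predictors.

    With ``alpha = 0`` (default) the stored distributions are the exact
    empirical conditionals; ``alpha > 0`` applies Laplace smoothing. Groups
    without any uncensored row fall back to the marginal state distribution.
    """
    horizon = examples.schema.horizon
    n_dr = horizon + 1
    state_ids = np.unique(examples.y_state[examples.y_dr != 0])
    state_pos = {s: i for i, s in enumerate(state_ids)}

    model = TabulatedModel(
        keys, {}, (np.ones(n_dr) / n_dr, np.ones(len(state_ids)) / len(state_ids)),
        state_ids, horizon, bins, r_cap,
    )
    cols = model._key_columns(examples.context)

    def _dist(counts: np.ndarray) -> np.ndarray:
        c = counts + alpha
        total = c.sum()
        return c / total if total > 0 else np.ones_like(c) / len(c)

    marg_dr = np.bincount(examples.y_dr, minlength=n_dr).astype(float)
    unc = examples.y_dr != 0
    marg_st = np.bincount(
        [state_pos[s] for s in examples.y_state[unc]], minlength=len(state_ids)
    ).astype(float)
    model.marginal = (_dist(marg_dr), _dist(marg_st))

    groups: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    counts: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for i, key in enumerate(zip(*cols)):
        key = tuple(np.asarray(key).tolist())
        if key not in counts:
            counts[key] = (np.zeros(n_dr), np.zeros(len(state_ids)))
        cdr, cst = counts[key]
        cdr[examples.y_dr[i]] += 1
        if examples.y_dr[i] != 0:
            cst[state_pos[examples.y_state[i]]] += 1
    for key, (cdr, cst) in counts.items():
        st = _dist(cst) if cst.sum() + alpha > 0 else model.marginal[1]
        groups[key] = (_dist(cdr), st)
    model.table = groups
    return model


def dr_distribution_from_hazard(kernel, state_id: int, r: int, temp: float, horizon: int = 10) -> np.ndarray:
    """Timing distribution implied by the kernel's annual hazard at fixed
    temperature: P(d) = h(r+d-1) * prod_{j<d-1} (1-h(r+j)); class 0 is the
    survival probability of the whole horizon."""
    rs = np.arange(r, r + horizon)
    h = kernel.hazard(
        np.full(horizon, state_id), rs, np.full(horizon, temp)
    )
    surv = np.concatenate([[1.0], np.cumprod(1.0 - h)])
    p = np.empty(horizon + 1)
    p[1:] = surv[:-1] * h
    p[0] = surv[-1]
    return p


def _full_state_dist(kernel, state_id, probs, state_class_ids) -> np.ndarray:
    """Embed successor-support probabilities into the full class vector."""
    pos = {s: i for i, s in enumerate(state_class_ids)}
    out = np.zeros(len(state_class_ids))
    for s, p in zip(kernel.target_support(state_id), probs):
        out[pos[int(s)]] = p
    return out


def kernel_tabulated(
    kernel,
    r_max: int,
    fixed_temperature: float | None = None,
    temp_centers: np.ndarray | None = None,
    temp_bin_edges: np.ndarray | None = None,
    horizon: int = 10,
    tier1: np.ndarray | None = None,
    tier2: np.ndarray | None = None,
) -> TabulatedModel:
    """Exact Bayes lookup table built from truth-kernel probabilities.

    Keyed on (state, residence time) at a single fixed temperature, or on
    (state, residence time, temperature bin) when ``temp_centers`` and
    matching ``temp_bin_edges`` are given. Neighbourhood shares are frozen
    at ``tier1``/``tier2`` (zeros by default), so this oracle is exact only
    for kernels whose targets ignore the neighbourhood.
    """
    pool = len(kernel.table.pool)
    t1 = np.zeros((1, pool)) if tier1 is None else np.asarray(tier1, float).reshape(1, -1)
    t2 = np.zeros((1, pool)) if tier2 is None else np.asarray(tier2, float).reshape(1, -1)
    state_class_ids = np.asarray(kernel.state_ids, dtype=np.int64)

    if temp_centers is None:
        if fixed_temperature is None:
            raise ValueError("provide fixed_temperature or temp_centers")
        temps = [(None, float(fixed_temperature))]
        keys: tuple[str, ...] = ("state_id", "R")
        bins = None
    else:
        if temp_bin_edges is None:
            raise ValueError("temp_centers requires temp_bin_edges")
        idx = np.digitize(np.asarray(temp_centers, float), temp_bin_edges)
        if len(set(idx.tolist())) != len(temp_centers):
            raise ValueError("temperature centers must fall into distinct bins")
        temps = [(int(i), float(t)) for i, t in zip(idx, temp_centers)]
        keys = ("state_id", "R", "tmean")
        bins = {"tmean": np.asarray(temp_bin_edges, float)}

    table: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for s in state_class_ids:
        for tbin, temp in temps:
            st_probs = kernel.target_probs_batch(
                int(s), t1, t2, np.array([temp])
            )[0]
            st_full = _full_state_dist(kernel, int(s), st_probs, state_class_ids)
            for r in range(r_max + 1):
                dr = dr_distribution_from_hazard(kernel, int(s), r, temp, horizon)
                key = (int(s), r) if tbin is None else (int(s), r, tbin)
                table[key] = (dr, st_full)
    n_dr = horizon + 1
    marginal = (np.ones(n_dr) / n_dr, np.ones(len(state_class_ids)) / len(state_class_ids))
    return TabulatedModel(keys, table, marginal, state_class_ids, horizon, bins, r_cap=r_max)


class KernelDirectModel:
    """Evaluates the truth kernel's probabilities for raw contexts.

    This is the Bayes-optimal transition model for data generated by the
    same kernel, including neighbourhood- and temperature-dependent targets.
    The timing head holds temperature constant over the horizon, which is
    exact under stationary climate.
    """

    requires_features = False
    requires_context = True

    def __init__(self, kernel, horizon: int = 10) -> None:
        self.kernel = kernel
        self.horizon = horizon
        self.n_dr = horizon + 1
        self.state_class_ids = np.asarray(kernel.state_ids, dtype=np.int64)

    def predict(
        self, X: np.ndarray | None = None, context: pd.DataFrame | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        if context is None:
            raise ValueError("kernel model needs a context frame")
        n = len(context)
        states = context["state_id"].to_numpy(np.int64)
        R = context["R"].to_numpy(np.int64)
        T = context["tmean"].to_numpy(float)
        species = self.kernel.table.pool.species
        t1 = context[[f"t1_{s}" for s in species]].to_numpy(float)
        t2 = context[[f"t2_{s}" for s in species]].to_numpy(float)

        # timing head: survival over hazards at offsets 0..horizon-1
        p_dr = np.empty((n, self.n_dr))
        surv = np.ones(n)
        for d in range(1, self.horizon + 1):
            h = self.kernel.hazard(states, R + d - 1, T)
            p_dr[:, d] = surv * h
            surv = surv * (1.0 - h)
        p_dr[:, 0] = surv

        p_st = np.zeros((n, len(self.state_class_ids)))
        pos = {int(s): i for i, s in enumerate(self.state_class_ids)}
        for s in np.unique(states):
            rows = np.flatnonzero(states == s)
            probs = self.kernel.target_probs_batch(int(s), t1[rows], t2[rows], T[rows])
            cols = [pos[int(t)] for t in self.kernel.target_support(int(s))]
            p_st[np.ix_(rows, cols)] = probs
        return p_dr, p_st
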