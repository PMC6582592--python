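"""Synthetic succession generator with a known ground-truth kernel.

Stands in for the process-based simulator that would normally supply
training trajectories. The kernel is a semi-Markov transition law with

* an annual leaving hazard, logistic in residence time with an additive
  temperature term: ``h = base * sigmoid(k*(R - midpoint) + c_T*(T - T_ref))``
  (so ``h(R=midpoint) = base/2`` at the reference temperature), and
* target-state log-weights combining fixed base logits, a linear bonus from
  neighbourhood species shares (a seed-input proxy), and a quadratic
  penalty on the mismatch between temperature and the successor's thermal
  optimum.

All coefficients are explicit, so closed-form oracles (timing
distributions, stationary occupancy) are available for every experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .climate import ClimateDriver, make_climate
from .spatial import tier_shares_at, tier_share_grids, distance_to_edge_grid
from .states import CompositionClass, SpeciesPool, StateTable
from .transition.dataset import ExampleSet
from .transition.features import FeatureSchema, build_feature_matrix

__all__ = [
    "SiteGrid",
    "HazardParams",
    "KernelConfig",
    "TruthKernel",
    "make_truth_kernel",
    "Trajectory",
    "simulate_trajectories",
    "extract_training_examples",
    "StationaryResult",
    "analytic_stationary",
    "make_site_grid",
    "synth_attribute_records",
    "simple_pool",
    "three_state_kernel",
    "eight_state_kernel",
    "neighbourhood_kernel",
    "gradient_kernel",
]


# ---------------------------------------------------------------------------
# site grid


@dataclass
class SiteGrid:
    """Congruent rasters of time-invariant site variables at 100 m grain."""

    soil_depth: np.ndarray  # cm
    soil_fertility: np.ndarray  # index 0..1
    region_id: np.ndarray  # climate region per cell
    active: np.ndarray  # simulated-area mask
    cell_size: float = 100.0

    def __post_init__(self) -> None:
        shape = self.soil_depth.shape
        for name in ("soil_fertility", "region_id", "active"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"site raster {name} not congruent with soil_depth")
        act = self.active.astype(bool)
        for name in ("soil_depth", "soil_fertility"):
            vals = getattr(self, name)[act]
            if not np.isfinite(vals).all():
                raise ValueError(f"non-finite {name} on active cells")
        self.active = act
        self.region_id = self.region_id.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.soil_depth.shape

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def make_site_grid(
    rows: int,
    cols: int,
    n_regions: int = 1,
    region_axis: str = "row",
    seed: int | np.random.Generator = 0,
    active: np.ndarray | None = None,
) -> SiteGrid:
    """Random site grid with regions striped along one axis."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth = rng.uniform(30.0, 150.0, (rows, cols))
    fert = rng.uniform(0.2, 1.0, (rows, cols))
    if region_axis == "row":
        band = np.minimum(np.arange(rows) * n_regions // rows, n_regions - 1)
        region = np.repeat(band[:, None], cols, axis=1)
    elif region_axis == "col":
        band = np.minimum(np.arange(cols) * n_regions // cols, n_regions - 1)
        region = np.repeat(band[None, :], rows, axis=0)
    else:
        raise ValueError("region_axis must be 'row' or 'col'")
    if active is None:
        active = np.ones((rows, cols), dtype=bool)
    return SiteGrid(depth, fert, region, active)


# ---------------------------------------------------------------------------
# truth kernel


@dataclass(frozen=True)
class HazardParams:
    base: float  # asymptotic annual leaving probability
    midpoint: float  # residence time (y) at which hazard = base/2
    steepness: float = 1.0
    temp_coef: float = 0.0  # added inside the logistic per °C above temp_ref
    temp_ref: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base <= 1.0):
            raise ValueError("hazard base must be in [0, 1]")


@dataclass
class KernelConfig:
    hazards: dict[int, HazardParams]
    successors: dict[int, tuple[int, ...]]
    base_logits: dict[int, tuple[float, ...]] | None = None
    nb_coef_tier1: float = 0.0
    nb_coef_tier2: float = 0.0
    temp_sens: float = 0.0  # weight of -(T - successor optimum)^2
    logit_jitter_sd: float = 0.0  # seeded jitter on base logits


class TruthKernel:
    """Ground-truth semi-Markov transition law over a state table."""

    def __init__(self, table: StateTable, config: KernelConfig, seed: int = 0) -> None:
        self.table = table
        self.config = config
        n = len(table)
        for sid in config.hazards:
            if not (0 <= sid < n):
                raise LookupError(f"hazard references state {sid} absent from table")
        for sid, succ in config.successors.items():
            if not (0 <= sid < n):
                raise LookupError(f"successor map references state {sid} absent from table")
            for t in succ:
                if not (0 <= t < n):
                    raise LookupError(f"successor state {t} absent from table")
            if sid in succ:
                raise ValueError(f"state {sid} lists itself as successor")
        missing = set(range(n)) - set(config.hazards)
        if missing:
            raise ValueError(f"states without hazard parameters: {sorted(missing)}")

        rng = np.random.default_rng(seed)
        self.state_ids = np.arange(n, dtype=np.int64)
        hp = [config.hazards[s] for s in range(n)]
        self._base = np.array([p.base for p in hp])
        self._mid = np.array([p.midpoint for p in hp])
        self._steep = np.array([p.steepness for p in hp])
        self._tcoef = np.array([p.temp_coef for p in hp])
        self._tref = np.array([p.temp_ref for p in hp])

        self._succ: dict[int, np.ndarray] = {}
        self._logits: dict[int, np.ndarray] = {}
        for s in range(n):
            succ = np.asarray(config.successors.get(s, ()), dtype=np.int64)
            if self._base[s] > 0 and len(succ) == 0:
                raise ValueError(f"state {s} can leave but has no successors")
            self._succ[s] = succ
            base = (
                np.asarray(config.base_logits[s], dtype=float)
                if config.base_logits and s in config.base_logits
                else np.zeros(len(succ))
            )
            if len(base) != len(succ):
                raise ValueError(f"state {s}: base logits do not match successor count")
            if config.logit_jitter_sd > 0:
                base = base + rng.normal(0.0, config.logit_jitter_sd, len(succ))
            self._logits[s] = base

        self._weight = table.species_weight_matrix()
        pool = table.pool
        optima = np.zeros(n)
        has_opt = np.zeros(n, dtype=bool)
        for s in table:
            members = s.composition.members
            if members and pool.thermal_optimum is not None:
                optima[s.state_id] = float(
                    np.mean([pool.optimum(m) for m in members])
                )
                has_opt[s.state_id] = True
        self._optima = optima
        self._has_opt = has_opt

    # -- hazards ----------------------------------------------------------

    def hazard(self, states: np.ndarray, R: np.ndarray, T: np.ndarray) -> np.ndarray:
        """Annual leaving probability for (state, residence time, annual mean T)."""
        s = np.asarray(states, dtype=np.int64)
        z = (
            self._steep[s] * (np.asarray(R, float) - self._mid[s])
            + self._tcoef[s] * (np.asarray(T, float) - self._tref[s])
        )
        return self._base[s] / (1.0 + np.exp(-z))

    # -- targets ----------------------------------------------------------

    def target_support(self, state_id: int) -> np.ndarray:
        return self._succ[state_id]

    def target_logits_batch(
        self, state_id: int, tier1: np.ndarray, tier2: np.ndarray, T: np.ndarray
    ) -> np.ndarray:
        """Unnormalized log-weights over successors; rows = contexts."""
        succ = self._succ[state_id]
        if len(succ) == 0:
            raise ValueError(f"state {state_id} has no successors")
        cfg = self.config
        w_succ = self._weight[succ]  # (k, pool)
        logits = np.broadcast_to(self._logits[state_id], (len(T), len(succ))).copy()
        if cfg.nb_coef_tier1 != 0.0:
            logits += cfg.nb_coef_tier1 * np.asarray(tier1, float) @ w_succ.T
        if cfg.nb_coef_tier2 != 0.0:
            logits += cfg.nb_coef_tier2 * np.asarray(tier2, float) @ w_succ.T
        if cfg.temp_sens != 0.0:
            dT2 = (np.asarray(T, float)[:, None] - self._optima[succ][None, :]) ** 2
            dT2 = np.where(self._has_opt[succ][None, :], dT2, 0.0)
            logits -= cfg.temp_sens * dT2
        return logits

    def target_probs_batch(
        self, state_id: int, tier1: np.ndarray, tier2: np.ndarray, T: np.ndarray
    ) -> np.ndarray:
        z = self.target_logits_batch(state_id, tier1, tier2, T)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def make_truth_kernel(table: StateTable, config: KernelConfig, seed: int = 0) -> TruthKernel:
    """Build a kernel from explicit coefficients; deterministic given ``seed``."""
    return TruthKernel(table, config, seed)


# ---------------------------------------------------------------------------
# trajectory simulation


@dataclass
class Trajectory:
    """Per-cell annual state and residence-time record.

    ``states``/``res_time`` have shape (years + 1, rows, cols); index 0 is
    the initial condition. Residence time resets to 0 in the year a cell
    enters a new state and otherwise increments by exactly 1.
    """

    states: np.ndarray
    res_time: np.ndarray
    active: np.ndarray
    year0: int

    @property
    def n_years(self) -> int:
        return self.states.shape[0] - 1

    def occupancy(self, last_n: int | None = None, n_states: int | None = None) -> np.ndarray:
        """State frequencies over active cells, optionally over the last
        ``last_n`` recorded years (time-and-space average)."""
        sl = self.states if last_n is None else self.states[-last_n:]
        vals = sl[:, self.active].ravel()
        n = n_states if n_states is not None else int(vals.max()) + 1
        return np.bincount(vals, minlength=n) / len(vals)

    def to_frame(self) -> pd.DataFrame:
        rows_idx, cols_idx = np.nonzero(self.active)
        frames = []
        for t in range(self.states.shape[0]):
            frames.append(
                pd.DataFrame(
                    {
                        "cell_row": rows_idx,
                        "cell_col": cols_idx,
                        "year": self.year0 + t,
                        "state_id": self.states[t, rows_idx, cols_idx],
                        "R": self.res_time[t, rows_idx, cols_idx],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, shape: tuple[int, int]) -> "Trajectory":
        frame = pd.read_csv(path, comment="#")
        years = np.sort(frame["year"].unique())
        year0 = int(years[0])
        active = np.zeros(shape, dtype=bool)
        first = frame[frame["year"] == year0]
        active[first["cell_row"], first["cell_col"]] = True
        states = np.zeros((len(years), *shape), dtype=np.int32)
        res = np.zeros_like(states)
        for t, y in enumerate(years):
            sub = frame[frame["year"] == y]
            states[t, sub["cell_row"], sub["cell_col"]] = sub["state_id"]
            res[t, sub["cell_row"], sub["cell_col"]] = sub["R"]
        return cls(states, res, active, year0)


def simulate_trajectories(
    kernel: TruthKernel,
    site: SiteGrid,
    climate: ClimateDriver,
    years: int,
    initial_states: np.ndarray,
    seed: int,
    initial_r: np.ndarray | int = 0,
    year0: int | None = None,
    horizon: int = 10,
) -> Trajectory:
    """Simulate the kernel forward on the site grid for ``years`` annual steps.

    Climate must cover the simulated span plus the prediction horizon beyond
    its last year (so training windows can always be built).
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rows, cols = site.shape
    init = np.asarray(initial_states, dtype=np.int32)
    if init.shape != (rows, cols):
        raise ValueError("initial states not congruent with site grid")
    if ((init[site.active] < 0) | (init[site.active] >= len(kernel.table))).any():
        raise ValueError("initial states outside the state table")
    if year0 is None:
        year0 = max(climate.year_range(r)[0] for r in climate.regions)
    climate.check_coverage(year0, year0 + years + horizon - 1)

    rng = np.random.default_rng(seed)
    states = np.zeros((years + 1, rows, cols), dtype=np.int32)
    res = np.zeros((years + 1, rows, cols), dtype=np.int32)
    states[0] = init
    res[0] = np.broadcast_to(np.asarray(initial_r, dtype=np.int32), (rows, cols))

    act_r, act_c = np.nonzero(site.active)
    regions = site.region_id[act_r, act_c]
    weight = kernel.table.species_weight_matrix()

    for t in range(years):
        cur_s = states[t]
        cur_r = res[t]
        tmap = climate.annual_mean_temp_map(year0 + t)
        T = np.array([tmap[r] for r in regions])
        s_act = cur_s[act_r, act_c]
        r_act = cur_r[act_r, act_c]
        h = kernel.hazard(s_act, r_act, T)
        leave = rng.random(len(h)) < h

        nxt_s = cur_s.copy()
        nxt_r = cur_r.copy()
        nxt_r[act_r, act_c] = r_act + 1
        if leave.any():
            lr, lc = act_r[leave], act_c[leave]
            t1, t2 = tier_shares_at(cur_s, site.active, weight, lr, lc)
            lT = T[leave]
            new_states = np.empty(len(lr), dtype=np.int32)
            ls = s_act[leave]
            for s in np.unique(ls):
                rows_s = np.flatnonzero(ls == s)
                probs = kernel.target_probs_batch(int(s), t1[rows_s], t2[rows_s], lT[rows_s])
                cum = probs.cumsum(axis=1)
                u = rng.random(len(rows_s))
                picks = (u[:, None] > cum).sum(axis=1)
                new_states[rows_s] = kernel.target_support(int(s))[picks]
            nxt_s[lr, lc] = new_states
            nxt_r[lr, lc] = 0
        states[t + 1] = nxt_s
        res[t + 1] = nxt_r

    return Trajectory(states, res, site.active.copy(), year0)


# ---------------------------------------------------------------------------
# training-example extraction


def extract_training_examples(
    traj: Trajectory,
    site: SiteGrid,
    climate: ClimateDriver,
    table: StateTable,
    schema: FeatureSchema | None = None,
    horizon: int = 10,
    stride_years: int = 1,
    cell_mask: np.ndarray | None = None,
    scenario: str | None = None,
) -> ExampleSet:
    """One training example per (cell, year) with at least ``horizon``
    recorded years remaining.

    Labels: timing class = years until the next state change if within the
    horizon, else 0 (censored); target state = the state entered at that
    change (absent on censored rows).
    """
    if traj.n_years <= horizon:
        raise ValueError("trajectory shorter than the prediction horizon")
    if schema is None:
        schema = FeatureSchema(
            state_ids=tuple(range(len(table))),
            species=table.pool.species,
            horizon=horizon,
        )
    mask = traj.active if cell_mask is None else (traj.active & cell_mask)
    rows_idx, cols_idx = np.nonzero(mask)
    weight = table.species_weight_matrix()
    edge = distance_to_edge_grid(site.active)
    regions = site.region_id[rows_idx, cols_idx]
    depth = site.soil_depth[rows_idx, cols_idx]
    fert = site.soil_fertility[rows_idx, cols_idx]

    changed = traj.states[1:] != traj.states[:-1]  # (n_years, rows, cols)
    frames = []
    for t in range(0, traj.n_years - horizon + 1, stride_years):
        s_t = traj.states[t, rows_idx, cols_idx]
        r_t = traj.res_time[t, rows_idx, cols_idx]
        label_dr = np.zeros(len(rows_idx), dtype=np.int64)
        label_state = np.full(len(rows_idx), -1, dtype=np.int64)
        pending = np.ones(len(rows_idx), dtype=bool)
        for d in range(1, horizon + 1):
            ch = changed[t + d - 1, rows_idx, cols_idx] & pending
            if ch.any():
                label_dr[ch] = d
                label_state[ch] = traj.states[t + d, rows_idx[ch], cols_idx[ch]]
                pending[ch] = False
        t1g, t2g = tier_share_grids(traj.states[t], traj.active, weight)
        tmap = climate.annual_mean_temp_map(traj.year0 + t)
        frame = pd.DataFrame(
            {
                "cell_row": rows_idx,
                "cell_col": cols_idx,
                "year": traj.year0 + t,
                "region": regions,
                "state_id": s_t,
                "R": r_t,
                "soil_depth": depth,
                "soil_fertility": fert,
                "tmean": np.array([tmap[r] for r in regions]),
                "edge_dist": edge[rows_idx, cols_idx],
            }
        )
        for j, sp in enumerate(table.pool.species):
            frame[f"t1_{sp}"] = t1g[rows_idx, cols_idx, j]
            frame[f"t2_{sp}"] = t2g[rows_idx, cols_idx, j]
        frame["label_dr"] = label_dr
        frame["label_state"] = label_state
        frames.append(frame)

    full = pd.concat(frames, ignore_index=True)
    if scenario is not None:
        full["scenario"] = scenario
    y_dr = full.pop("label_dr").to_numpy(np.int64)
    y_state = full.pop("label_state").to_numpy(np.int64)
    X = build_feature_matrix(full, climate, schema)
    return ExampleSet(X, y_dr, y_state, full, schema)


# ---------------------------------------------------------------------------
# analytic oracle


@dataclass
class StationaryResult:
    occupancy: np.ndarray | None  # per-state probabilities, or None
    absorbing: list[int]
    note: str = ""


def analytic_stationary(
    kernel: TruthKernel,
    fixed_temperature: float,
    fixed_tier1: np.ndarray | None = None,
    fixed_tier2: np.ndarray | None = None,
    r_max: int = 200,
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> StationaryResult:
    """Stationary occupancy of the embedded Markov chain on (state, R) pairs.

    Residence time is capped at ``r_max`` (the hazard is evaluated at the
    cap from there on). Neighbourhood shares are held fixed, so the result
    is exact for kernels whose targets ignore the simulated neighbourhood.
    Non-ergodic chains are reported via their absorbing/recurrent classes
    instead of a distribution.
    """
    n_s = len(kernel.state_ids)
    pool = len(kernel.table.pool)
    t1 = np.zeros((1, pool)) if fixed_tier1 is None else np.asarray(fixed_tier1, float).reshape(1, -1)
    t2 = np.zeros((1, pool)) if fixed_tier2 is None else np.asarray(fixed_tier2, float).reshape(1, -1)
    Tv = np.array([fixed_temperature])

    absorbing = [
        int(s)
        for s in range(n_s)
        if kernel.hazard(np.full(r_max + 1, s), np.arange(r_max + 1), np.full(r_max + 1, fixed_temperature)).max() < 1e-12
    ]
    if absorbing:
        return StationaryResult(None, absorbing, "absorbing states present")

    nr = r_max + 1
    P = np.zeros((n_s * nr, n_s * nr))
    for s in range(n_s):
        h = kernel.hazard(np.full(nr, s), np.arange(nr), np.full(nr, fixed_temperature))
        succ = kernel.target_support(s)
        probs = kernel.target_probs_batch(s, t1, t2, Tv)[0]
        for r in range(nr):
            i = s * nr + r
            stay_r = min(r + 1, r_max)
            P[i, s * nr + stay_r] += 1.0 - h[r]
            for s2, p in zip(succ, probs):
                P[i, s2 * nr + 0] += h[r] * p

    def _iterate(pi0: np.ndarray) -> np.ndarray:
        pi = pi0
        for _ in range(max_iter):
            nxt = 0.5 * pi + 0.5 * (pi @ P)  # damping kills periodicity
            if np.abs(nxt - pi).sum() < tol:
                return nxt
            pi = nxt
        return pi

    pi_a = _iterate(np.full(n_s * nr, 1.0 / (n_s * nr)))
    e0 = np.zeros(n_s * nr)
    e0[0] = 1.0
    pi_b = _iterate(e0)
    if np.abs(pi_a - pi_b).sum() > 1e-6:
        # multiple recurrent classes: report the terminal SCCs
        n_comp, labels = connected_components(csr_matrix(P > 0), connection="strong")
        terminal = []
        for c in range(n_comp):
            members = np.flatnonzero(labels == c)
            if not (P[members][:, np.setdiff1d(np.arange(len(P)), members)] > 0).any():
                terminal.append(sorted({int(m // nr) for m in members}))
        flat = sorted({s for grp in terminal for s in grp})
        return StationaryResult(None, flat, "chain is not ergodic")
    occ = pi_a.reshape(n_s, nr).sum(axis=1)
    occ = occ / occ.sum()
    return StationaryResult(occ, [], "")


# ---------------------------------------------------------------------------
# attribute synthesis (for the attribute database)


def synth_attribute_records(
    traj: Trajectory,
    table: StateTable,
    seed: int,
    max_records: int | None = None,
) -> pd.DataFrame:
    """Per-(cell, year) ecosystem attributes derived from state and residence
    time: live carbon grows with canopy height and saturating residence
    time; tree diversity is the member count with observation noise."""
    rng = np.random.default_rng(seed)
    rows_idx, cols_idx = np.nonzero(traj.active)
    s = traj.states[:, rows_idx, cols_idx].ravel()
    r = traj.res_time[:, rows_idx, cols_idx].ravel()
    if max_records is not None and len(s) > max_records:
        pick = rng.choice(len(s), size=max_records, replace=False)
        s, r = s[pick], r[pick]
    heights = np.array([st.height_class for st in table])
    n_members = np.array([len(st.composition.members) for st in table])
    carbon = (
        (heights[s] + 0.5) * 12.0 * (1.0 + 0.25 * np.log1p(r))
        + rng.normal(0.0, 5.0, len(s))
    )
    carbon = np.clip(carbon, 0.0, None)
    carbon[n_members[s] == 0] = 0.0
    diversity = np.clip(n_members[s] + rng.normal(0.0, 0.15, len(s)), 0.0, None)
    diversity[n_members[s] == 0] = 0.0
    return pd.DataFrame(
        {"state_id": s, "R": r, "live_carbon": carbon, "tree_diversity": diversity}
    )


# ---------------------------------------------------------------------------
# preset pools, tables and kernels used by experiments and tests


def simple_pool() -> SpeciesPool:
    """Three-species pool with distinct thermal optima (cold to warm)."""
    return SpeciesPool(
        ("piab", "fasy", "quro"),
        thermal_optimum={"piab": 6.0, "fasy": 9.0, "quro": 12.0},
    )


def _dominated_table(pool: SpeciesPool, height_lai: list[tuple[int, int]]) -> StateTable:
    table = StateTable(pool)
    for code in pool.species:
        for h, l in height_lai:
            table.add_state(CompositionClass("dominated", (code,)), h, l)
    return table


def three_state_kernel(seed: int = 0) -> tuple[StateTable, TruthKernel]:
    """Cyclic 3-state kernel with R-dependent hazards and two-way targets;
    temperature- and neighbourhood-independent, so the tabulated oracle and
    the analytic stationary distribution are both exact."""
    pool = simple_pool()
    table = _dominated_table(pool, [(5, 1)])
    config = KernelConfig(
        hazards={
            0: HazardParams(base=0.9, midpoint=4.0, steepness=0.8),
            1: HazardParams(base=0.6, midpoint=8.0, steepness=0.6),
            2: HazardParams(base=0.8, midpoint=6.0, steepness=1.0),
        },
        successors={0: (1, 2), 1: (2, 0), 2: (0, 1)},
        base_logits={0: (1.0, 0.0), 1: (0.5, -0.5), 2: (0.8, -0.2)},
    )
    return table, make_truth_kernel(table, config, seed)


def eight_state_kernel(seed: int = 0) -> tuple[StateTable, TruthKernel]:
    """Eight states (young/mature per species, two mixtures) with
    temperature-modified hazards and thermally structured targets."""
    pool = simple_pool()
    table = StateTable(pool)
    for code in pool.species:  # ids 0,2,4 young; 1,3,5 mature
        table.add_state(CompositionClass("dominated", (code,)), 2, 1)
        table.add_state(CompositionClass("dominated", (code,)), 5, 2)
    table.add_state(CompositionClass("mixture", ("piab", "fasy")), 4, 1)  # id 6
    table.add_state(CompositionClass("mixture", ("fasy", "quro")), 4, 1)  # id 7
    young = {0: "piab", 2: "fasy", 4: "quro"}
    mature = {1: "piab", 3: "fasy", 5: "quro"}
    hazards = {}
    successors = {}
    base_logits = {}
    for sid in young:
        hazards[sid] = HazardParams(base=0.85, midpoint=5.0, steepness=0.7, temp_coef=0.25, temp_ref=9.0)
        successors[sid] = (sid + 1, 6, 7)  # mostly grow up, sometimes mix
        base_logits[sid] = (2.0, 0.0, 0.0)
    for sid in mature:
        hazards[sid] = HazardParams(base=0.55, midpoint=12.0, steepness=0.45, temp_coef=0.35, temp_ref=9.0)
        successors[sid] = tuple(sorted(set(young) - {sid - 1})) + (6, 7)
        base_logits[sid] = (0.6, 0.6, 0.0, 0.0)
    hazards[6] = HazardParams(base=0.7, midpoint=8.0, steepness=0.6, temp_coef=0.3, temp_ref=9.0)
    successors[6] = (0, 2, 5)
    base_logits[6] = (0.5, 0.5, 0.0)
    hazards[7] = HazardParams(base=0.7, midpoint=8.0, steepness=0.6, temp_coef=0.3, temp_ref=9.0)
    successors[7] = (2, 4, 1)
    base_logits[7] = (0.5, 0.5, 0.0)
    config = KernelConfig(
        hazards=hazards,
        successors=successors,
        base_logits=base_logits,
        temp_sens=0.12,
    )
    return table, make_truth_kernel(table, config, seed)


def neighbourhood_kernel(seed: int = 0, nb_coef: float = 6.0) -> tuple[StateTable, TruthKernel]:
    """Three dominated states whose targets depend strongly on local species
    shares — the substrate for the spatial-context ablation."""
    pool = simple_pool()
    table = _dominated_table(pool, [(5, 1)])
    config = KernelConfig(
        hazards={s: HazardParams(base=0.8, midpoint=4.0, steepness=0.8) for s in range(3)},
        successors={0: (1, 2), 1: (0, 2), 2: (0, 1)},
        nb_coef_tier1=nb_coef,
        nb_coef_tier2=nb_coef / 2.0,
    )
    return table, make_truth_kernel(table, config, seed)


def gradient_kernel(seed: int = 0, temp_sens: float = 0.8) -> tuple[StateTable, TruthKernel]:
    """Three species x {young, mature} with strongly thermally structured
    targets, used for the temperature-gradient zonation experiment.

    The young/mature split lets a well-adapted species persist through
    transitions (mature -> young of the same species), so climate sorts the
    landscape into species bands. Optima are spaced so a 5.5 °C gradient
    centred on 9 °C yields three roughly equal bands.
    """
    pool = SpeciesPool(
        ("piab", "fasy", "quro"),
        thermal_optimum={"piab": 6.9, "fasy": 9.0, "quro": 11.1},
    )
    table = StateTable(pool)
    young, mature = {}, {}
    for code in pool.species:
        young[code] = table.add_state(CompositionClass("dominated", (code,)), 2, 1).state_id
        mature[code] = table.add_state(CompositionClass("dominated", (code,)), 6, 2).state_id
    hazards = {}
    successors = {}
    base_logits = {}
    for code in pool.species:
        y, m = young[code], mature[code]
        others = [c for c in pool.species if c != code]
        hazards[y] = HazardParams(base=0.8, midpoint=4.0, steepness=0.8)
        successors[y] = (m,) + tuple(young[c] for c in others)
        base_logits[y] = (1.0,) + (0.0,) * len(others)
        hazards[m] = HazardParams(base=0.6, midpoint=8.0, steepness=0.6)
        successors[m] = tuple(young[c] for c in pool.species)
        base_logits[m] = (0.0,) * len(pool.species)
    config = KernelConfig(
        hazards=hazards,
        successors=successors,
        base_logits=base_logits,
        temp_sens=temp_sens,
        nb_coef_tier1=0.5,
    )
    return table, make_truth_kernel(table, config, seed)
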