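"""Annual-step raster simulation of state transitions.

Each cell carries a state, a residence time and (optionally) a scheduled
transition year drawn from the timing head of a transition model. Per year:

* cells whose scheduled year has arrived sample a target state from the
  state head (features current at transition time), reset residence time
  and draw a fresh schedule;
* all other cells age by one year; cells whose censored 10-year window
  expired are re-queried;
* ecosystem attributes are refreshed from the attribute database.

Neighbourhood predictors are computed from the start-of-year snapshot
(synchronous update), so cell update order cannot create artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attributes import AttributeDB
from .climate import ClimateDriver
from .spatial import distance_to_edge_grid, tier_shares_at
from .states import StateTable
from .synthetic import SiteGrid
from .transition.features import FeatureSchema, build_feature_matrix

logger = logging.getLogger(__name__)

__all__ = ["Landscape", "OutputBundle", "run", "step", "landscape_summary", "make_rng_streams"]

NO_SCHEDULE = -1


@dataclass
class Landscape:
    """Mutable per-cell simulation state on a site grid."""

    site: SiteGrid
    table: StateTable
    state: np.ndarray
    res_time: np.ndarray
    sched: np.ndarray = field(default=None)  # absolute year of next transition
    requery: np.ndarray = field(default=None)  # year to re-draw after censoring
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.site.shape
        self.state = np.asarray(self.state, dtype=np.int32)
        self.res_time = np.asarray(self.res_time, dtype=np.int32)
        if self.state.shape != shape or self.res_time.shape != shape:
            raise ValueError("landscape rasters not congruent with site grid")
        act = self.site.active
        if ((self.state[act] < 0) | (self.state[act] >= len(self.table))).any():
            raise ValueError("active cells carry invalid state ids")
        if (self.res_time[act] < 0).any():
            raise ValueError("negative residence times")
        if self.sched is None:
            self.sched = np.full(shape, NO_SCHEDULE, dtype=np.int64)
        if self.requery is None:
            self.requery = np.full(shape, NO_SCHEDULE, dtype=np.int64)

    @property
    def n_active(self) -> int:
        return self.site.n_active

    def copy(self) -> "Landscape":
        return Landscape(
            self.site,
            self.table,
            self.state.copy(),
            self.res_time.copy(),
            self.sched.copy(),
            self.requery.copy(),
            {k: v.copy() for k, v in self.attributes.items()},
        )


@dataclass
class OutputBundle:
    year0: int
    years: int
    seed: int
    summary: pd.DataFrame
    state_rasters: dict[int, np.ndarray]
    attribute_rasters: dict[str, np.ndarray]
    final: Landscape


def make_rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named streams off one master seed, so toggling one
    consumer does not shift the draws of the others."""
    ss = np.random.SeedSequence(seed)
    names = ("schedule", "target", "attribute")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# feature/context assembly


def _cell_contexts(
    land: Landscape,
    rows: np.ndarray,
    cols: np.ndarray,
    year: int,
    climate: ClimateDriver,
    snapshot_state: np.ndarray,
    edge: np.ndarray,
) -> pd.DataFrame:
    site = land.site
    weight = land.table.species_weight_matrix()
    t1, t2 = tier_shares_at(snapshot_state, site.active, weight, rows, cols)
    regions = site.region_id[rows, cols]
    tmap = climate.annual_mean_temp_map(year)
    ctx = pd.DataFrame(
        {
            "cell_row": rows,
            "cell_col": cols,
            "year": year,
            "region": regions,
            "state_id": land.state[rows, cols],
            "R": land.res_time[rows, cols],
            "soil_depth": site.soil_depth[rows, cols],
            "soil_fertility": site.soil_fertility[rows, cols],
            "tmean": np.array([tmap[r] for r in regions]),
            "edge_dist": edge[rows, cols],
        }
    )
    for j, sp in enumerate(land.table.pool.species):
        ctx[f"t1_{sp}"] = t1[:, j]
        ctx[f"t2_{sp}"] = t2[:, j]
    return ctx


def _predict(model, ctx: pd.DataFrame, climate: ClimateDriver, schema: FeatureSchema | None):
    X = None
    if getattr(model, "requires_features", True):
        if schema is None:
            schema = model.schema
        X = build_feature_matrix(ctx, climate, schema)
    context = ctx if getattr(model, "requires_context", False) else None
    return model.predict(X, context=context)


def _sample_rows(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a probability matrix."""
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("model returned unnormalized distributions")
    cum = p.cumsum(axis=1)
    u = rng.random(len(p))
    return (u[:, None] > cum).sum(axis=1)


def schedule_transition(
    model, ctx: pd.DataFrame, climate: ClimateDriver, schema, rng
) -> np.ndarray:
    """Sample the timing head; returns year offsets (0 = censored)."""
    p_dr, _ = _predict(model, ctx, climate, schema)
    return _sample_rows(p_dr, rng)


def _apply_schedules(land: Landscape, rows, cols, offsets: np.ndarray, year: int, horizon: int) -> None:
    cens = offsets == 0
    land.sched[rows[cens], cols[cens]] = NO_SCHEDULE
    land.requery[rows[cens], cols[cens]] = year + horizon
    land.sched[rows[~cens], cols[~cens]] = year + offsets[~cens]
    land.requery[rows[~cens], cols[~cens]] = NO_SCHEDULE


def initialize_schedules(
    land: Landscape, model, climate: ClimateDriver, year: int, rng, schema=None
) -> None:
    """Draw schedules for every active cell using its initial residence time."""
    rows, cols = np.nonzero(land.site.active)
    edge = distance_to_edge_grid(land.site.active)
    horizon = getattr(model, "n_dr", 11) - 1
    ctx = _cell_contexts(land, rows, cols, year, climate, land.state, edge)
    offsets = schedule_transition(model, ctx, climate, schema, rng)
    _apply_schedules(land, rows, cols, offsets, year, horizon)


def step(
    land: Landscape,
    model,
    climate: ClimateDriver,
    year: int,
    attribute_db: AttributeDB | None,
    rngs: dict[str, np.random.Generator],
    schema: FeatureSchema | None = None,
    edge: np.ndarray | None = None,
) -> dict[str, int]:
    """Advance the landscape from ``year`` to ``year + 1`` in place."""
    active = land.site.active
    n_active_before = int(active.sum())
    if edge is None:
        edge = distance_to_edge_grid(active)
    horizon = getattr(model, "n_dr", 11) - 1
    snapshot = land.state.copy()
    new_year = year + 1

    trans_mask = active & (land.sched == new_year)
    tr, tc = np.nonzero(trans_mask)
    n_trans = len(tr)
    n_flicker = 0
    if n_trans:
        ctx = _cell_contexts(land, tr, tc, new_year, climate, snapshot, edge)
        _, p_state = _predict(model, ctx, climate, schema)
        # a transition must change the state: mask out self-transitions
        class_ids = np.asarray(model.state_class_ids)
        cur = land.state[tr, tc]
        p = p_state.copy()
        self_cols = np.searchsorted(class_ids, cur)
        ok_self = (self_cols < len(class_ids)) & (class_ids[np.minimum(self_cols, len(class_ids) - 1)] == cur)
        p[np.flatnonzero(ok_self), self_cols[ok_self]] = 0.0
        mass = p.sum(axis=1)
        movable = mass > 1e-9
        n_flicker = int((~movable).sum())
        if movable.any():
            pm = p[movable] / mass[movable, None]
            picks = _sample_rows(pm, rngs["target"])
            land.state[tr[movable], tc[movable]] = class_ids[picks]
            land.res_time[tr[movable], tc[movable]] = 0
        # unmovable cells behave like censored cells: age and re-query now
        stay = ~movable
        land.res_time[tr[stay], tc[stay]] += 1
        land.sched[tr, tc] = NO_SCHEDULE

    age_mask = active & ~trans_mask
    land.res_time[age_mask] += 1

    # fresh schedules: transitioned cells and expired censored windows
    redraw_mask = trans_mask | (active & (land.requery == new_year))
    rr, rc = np.nonzero(redraw_mask)
    if len(rr):
        ctx = _cell_contexts(land, rr, rc, new_year, climate, snapshot, edge)
        offsets = schedule_transition(model, ctx, climate, schema, rngs["schedule"])
        _apply_schedules(land, rr, rc, offsets, new_year, horizon)

    if attribute_db is not None:
        ar, ac = np.nonzero(active)
        for name in attribute_db.attributes:
            land.attributes.setdefault(name, np.full(land.site.shape, np.nan))
            land.attributes[name][ar, ac] = attribute_db.sample_many(
                land.state[ar, ac], land.res_time[ar, ac], name, rngs["attribute"]
            )

    if int(active.sum()) != n_active_before:
        raise RuntimeError("active cell count changed during a step")
    if ((land.state[active] < 0) | (land.state[active] >= len(land.table))).any():
        raise RuntimeError("invalid state id produced during a step")
    return {"transitions": n_trans - n_flicker, "requeries": len(rr), "blocked_self": n_flicker}


def run(
    land: Landscape,
    model,
    climate: ClimateDriver,
    years: int,
    seed: int,
    attribute_db: AttributeDB | None = None,
    year0: int | None = None,
    output_every: int = 0,
    schema: FeatureSchema | None = None,
    summary_top_n: int = 18,
) -> OutputBundle:
    """Run the simulation; reproducible bit-for-bit given ``seed``."""
    if years < 0:
        raise ValueError("years must be >= 0")
    if year0 is None:
        year0 = max(climate.year_range(r)[0] for r in climate.regions)
    horizon = getattr(model, "n_dr", 11) - 1
    climate.check_coverage(year0, year0 + years + horizon - 1)
    rngs = make_rng_streams(seed)
    edge = distance_to_edge_grid(land.site.active)

    initialize_schedules(land, model, climate, year0, rngs["schedule"], schema)
    if attribute_db is not None:
        ar, ac = np.nonzero(land.site.active)
        for name in attribute_db.attributes:
            land.attributes.setdefault(name, np.full(land.site.shape, np.nan))
            land.attributes[name][ar, ac] = attribute_db.sample_many(
                land.state[ar, ac], land.res_time[ar, ac], name, rngs["attribute"]
            )

    rows = [landscape_summary(land, year0, top_n=summary_top_n)]
    rasters = {year0: land.state.copy()}
    for t in range(years):
        year = year0 + t
        stats = step(land, model, climate, year, attribute_db, rngs, schema, edge)
        logger.info(
            "year %d: %d transitions, %d schedule queries",
            year + 1, stats["transitions"], stats["requeries"],
        )
        rows.append(landscape_summary(land, year + 1, top_n=summary_top_n))
        if output_every and ((t + 1) % output_every == 0):
            rasters[year + 1] = land.state.copy()
    rasters[year0 + years] = land.state.copy()

    summary = pd.DataFrame(rows).fillna(0.0)
    attr_rasters = {k: v.copy() for k, v in land.attributes.items()}
    return OutputBundle(year0, years, seed, summary, rasters, attr_rasters, land)


def landscape_summary(land: Landscape, year: int, top_n: int = 18) -> dict[str, float]:
    """One time-series row: composition-class frequencies (top ``top_n``
    plus an 'other' bucket), height- and LAI-class distributions, and
    attribute quantiles over active cells."""
    active = land.site.active
    if not active.any():
        raise ValueError("landscape has no active cells")
    states = land.state[active]
    n = len(states)
    row: dict[str, float] = {"year": year}

    counts = np.bincount(states, minlength=len(land.table))
    comp_freq: dict[str, float] = {}
    for s in land.table:
        if counts[s.state_id]:
            label = s.composition.label()
            comp_freq[label] = comp_freq.get(label, 0.0) + counts[s.state_id] / n
    ranked = sorted(comp_freq.items(), key=lambda kv: (-kv[1], kv[0]))
    other = 0.0
    for i, (label, freq) in enumerate(ranked):
        if i < top_n:
            row[f"comp:{label}"] = freq
        else:
            other += freq
    row["comp:other"] = other

    heights = np.array([s.height_class for s in land.table])[states]
    lais = np.array([s.lai_class for s in land.table])[states]
    for h in range(land.table.n_height_classes):
        f = float((heights == h).mean())
        if f:
            row[f"height:{h}"] = f
    for l in range(land.table.n_lai_classes):
        row[f"lai:{l}"] = float((lais == l).mean())

    for name, grid in land.attributes.items():
        vals = grid[active]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            row[f"{name}:mean"] = float(vals.mean())
            for q, lbl in ((0, "min"), (25, "q25"), (50, "median"), (75, "q75"), (100, "max")):
                row[f"{name}:{lbl}"] = float(np.percentile(vals, q))
    return row
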