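"""Self-contained demonstration pipeline.

Runs the whole chain — synthesize a landscape and trajectories from a
known kernel, extract training examples, train the transition network,
evaluate it against the kernel's exact probabilities, and simulate with
the trained model — on a small grid, with no external inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import engine
from .attributes import build_attribute_db
from .climate import make_climate
from .config import ProjectConfig, config_hash
from .synthetic import (
    analytic_stationary,
    eight_state_kernel,
    extract_training_examples,
    make_site_grid,
    simulate_trajectories,
    synth_attribute_records,
    three_state_kernel,
)
from .transition import (
    FeatureSchema,
    KernelDirectModel,
    ModelConfig,
    evaluate,
    fit_dnn,
    kernel_tabulated,
)

__all__ = ["demo_pipeline"]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"demo pipeline failed in stage {stage!r}: {cause}")


def demo_pipeline(
    seed: int,
    workdir: str | Path | None = None,
    rows: int = 30,
    cols: int = 30,
    train_years: int = 80,
    sim_years: int = 40,
    epochs: int = 4,
) -> dict:
    """Run synth -> extract -> train -> simulate -> summarize end to end.

    Deterministic given ``seed``; returns a JSON-serializable report with
    recovery metrics (trained network vs exact kernel probabilities) and an
    oracle-equivalence check (simulated vs analytic stationary occupancy).
    """
    report: dict = {"seed": int(seed), "stages": []}
    cfg = ProjectConfig()
    report["config_hash"] = config_hash(cfg)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(8)]
    stage_t0 = time.perf_counter()

    def _done(name: str) -> None:
        nonlocal stage_t0
        report["stages"].append(
            {"stage": name, "seconds": round(time.perf_counter() - stage_t0, 2)}
        )
        stage_t0 = time.perf_counter()

    # -- synth ------------------------------------------------------------
    try:
        table, kernel = eight_state_kernel(seed=seeds[0])
        site = make_site_grid(rows, cols, n_regions=3, seed=seeds[1])
        climate = make_climate(
            {0: 7.5, 1: 9.0, 2: 10.5},
            year0=2000,
            n_years=train_years + sim_years + 12,
            temp_noise_sd=0.2,
            seed=seeds[2],
        )
        rng = np.random.default_rng(seeds[3])
        init = rng.integers(0, len(table), size=(rows, cols)).astype(np.int32)
        traj = simulate_trajectories(kernel, site, climate, train_years, init, seed=seeds[4])
    except Exception as e:  # noqa: BLE001
        raise StageFailure("synth", e) from e
    _done("synth")

    # -- extract ----------------------------------------------------------
    try:
        schema = FeatureSchema(
            state_ids=tuple(range(len(table))),
            species=table.pool.species,
            climate_encoding="decadal_means",
        )
        examples = extract_training_examples(
            traj, site, climate, table, schema=schema, stride_years=2
        )
        train, val = examples.split_by_cell_block(0.25, block=5, seed=seeds[5])
        report["n_examples"] = {"train": len(train), "val": len(val)}
    except Exception as e:  # noqa: BLE001
        raise StageFailure("extract", e) from e
    _done("extract")

    # -- train ------------------------------------------------------------
    try:
        model = fit_dnn(
            train,
            val,
            ModelConfig(hidden=(48, 48), dropout=0.0, epochs=epochs, seed=seeds[6]),
        )
    except Exception as e:  # noqa: BLE001
        raise StageFailure("train", e) from e
    _done("train")

    # -- evaluate (recovery vs exact kernel probabilities) ----------------
    try:
        oracle = KernelDirectModel(kernel)
        metrics = evaluate(model, val, reference=oracle)
        oracle_metrics = evaluate(oracle, val)
        report["recovery"] = {
            **{k: round(v, 4) for k, v in metrics.items()},
            "oracle_top1_dr": round(oracle_metrics["top1_dr"], 4),
            "oracle_top1_state": round(oracle_metrics["top1_state"], 4),
        }
    except Exception as e:  # noqa: BLE001
        raise StageFailure("evaluate", e) from e
    _done("evaluate")

    # -- oracle equivalence (tabulated kernel model vs analytic) ----------
    try:
        table3, kernel3 = three_state_kernel(seed=0)
        site3 = make_site_grid(36, 42, seed=seeds[1])
        clim3 = make_climate({0: 9.0}, 2000, 150 + 12, temp_noise_sd=0.0, seed=0)
        tab = kernel_tabulated(kernel3, r_max=80, fixed_temperature=9.0)
        land3 = engine.Landscape(
            site3, table3,
            np.zeros((36, 42), np.int32), np.zeros((36, 42), np.int32),
        )
        out3 = engine.run(land3, tab, clim3, years=150, seed=seeds[7])
        occ = np.bincount(out3.final.state[site3.active], minlength=len(table3))
        occ = occ / occ.sum()
        ana = analytic_stationary(kernel3, 9.0, r_max=80)
        err = float(np.abs(occ - ana.occupancy).max())
        report["oracle_equivalence"] = {
            "max_abs_occupancy_error": round(err, 4),
            "occupancy": [round(v, 4) for v in occ],
            "analytic": [round(v, 4) for v in ana.occupancy],
        }
    except Exception as e:  # noqa: BLE001
        raise StageFailure("oracle_equivalence", e) from e
    _done("oracle_equivalence")

    # -- simulate with the trained network --------------------------------
    try:
        records = synth_attribute_records(traj, table, seed=seeds[3], max_records=50_000)
        db = build_attribute_db(records)
        land = engine.Landscape(site, table, init.copy(), np.zeros((rows, cols), np.int32))
        out = engine.run(
            land, model, climate, years=sim_years, seed=seeds[7],
            attribute_db=db, year0=2000,
        )
        final = out.summary.iloc[-1]
        report["simulation"] = {
            "years": sim_years,
            "final_mean_live_carbon": round(float(final.get("live_carbon:mean", float("nan"))), 2),
            "final_mean_tree_diversity": round(float(final.get("tree_diversity:mean", float("nan"))), 3),
            "state_raster_sha": hashlib.sha256(out.final.state.tobytes()).hexdigest()[:16],
        }
    except Exception as e:  # noqa: BLE001
        raise StageFailure("simulate", e) from e
    _done("simulate")

    if workdir is not None:
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        (workdir / "demo_report.json").write_text(json.dumps(report, indent=1))
    return report
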