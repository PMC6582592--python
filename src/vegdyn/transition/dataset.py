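"""Training example sets for the transition model."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..climate import ClimateDriver
from .features import FeatureSchema, build_feature_matrix

__all__ = ["ExampleSet"]


@dataclass
class ExampleSet:
    """Feature matrix plus the two label vectors and their provenance.

    ``y_dr`` is the timing label: 0 = censored (no transition within the
    horizon), 1..horizon = years until the next transition. ``y_state`` is
    the entered state id, -1 on censored rows. ``context`` keeps the raw
    (unencoded) predictors, one row per example, for tabulated models and
    for serialization.
    """

    X: np.ndarray
    y_dr: np.ndarray
    y_state: np.ndarray
    context: pd.DataFrame
    schema: FeatureSchema

    def __post_init__(self) -> None:
        n = len(self.y_dr)
        if not (len(self.X) == n == len(self.y_state) == len(self.context)):
            raise ValueError("inconsistent example-set lengths")
        if self.X.shape[1] != self.schema.length:
            raise ValueError("feature matrix does not match schema length")
        if ((self.y_dr < 0) | (self.y_dr > self.schema.horizon)).any():
            raise ValueError("timing labels out of range")
        censored = self.y_dr == 0
        if (self.y_state[censored] != -1).any():
            raise ValueError("censored rows must carry no target-state label")
        if (self.y_state[~censored] < 0).any():
            raise ValueError("uncensored rows must carry a target-state label")

    def __len__(self) -> int:
        return len(self.y_dr)

    # -- selection --------------------------------------------------------

    def select(self, mask_or_index: np.ndarray) -> "ExampleSet":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExampleSet(
            self.X[idx],
            self.y_dr[idx],
            self.y_state[idx],
            self.context.iloc[idx].reset_index(drop=True),
            self.schema,
        )

    def subsample(self, n: int, rng: np.random.Generator) -> "ExampleSet":
        if n >= len(self):
            return self
        return self.select(rng.choice(len(self), size=n, replace=False))

    def split_by_scenario(self, held_out) -> tuple["ExampleSet", "ExampleSet"]:
        """Train/validation split holding out one whole scenario."""
        if "scenario" not in self.context.columns:
            raise ValueError("examples carry no scenario column")
        mask = (self.context["scenario"] == held_out).to_numpy()
        if not mask.any() or mask.all():
            raise ValueError(f"scenario {held_out!r} split is degenerate")
        return self.select(~mask), self.select(mask)

    def split_by_cell_block(
        self, val_fraction: float, block: int, seed: int
    ) -> tuple["ExampleSet", "ExampleSet"]:
        """Hold out square blocks of cells so train/val cells are disjoint."""
        br = self.context["cell_row"].to_numpy() // block
        bc = self.context["cell_col"].to_numpy() // block
        blocks = np.unique(np.stack([br, bc], axis=1), axis=0)
        rng = np.random.default_rng(seed)
        n_val = max(1, int(round(val_fraction * len(blocks))))
        chosen = rng.choice(len(blocks), size=n_val, replace=False)
        val_set = {tuple(blocks[i]) for i in chosen}
        mask = np.array([(r, c) in val_set for r, c in zip(br, bc)])
        if mask.all():
            raise ValueError("validation split swallowed every example")
        return self.select(~mask), self.select(mask)

    def zero_tier_features(self) -> "ExampleSet":
        """Copy with neighbourhood tier-share predictors zeroed out
        (information removed), for spatial-context ablations."""
        X = self.X.copy()
        cols = [
            i
            for i, name in enumerate(self.schema.column_names)
            if name.startswith(("t1_", "t2_"))
        ]
        X[:, cols] = 0.0
        ctx = self.context.copy()
        for c in ctx.columns:
            if c.startswith(("t1_", "t2_")):
                ctx[c] = 0.0
        return ExampleSet(X, self.y_dr, self.y_state, ctx, self.schema)

    @staticmethod
    def concat(sets: list["ExampleSet"]) -> "ExampleSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        h0 = sets[0].schema.schema_hash()
        if any(s.schema.schema_hash() != h0 for s in sets):
            raise ValueError("cannot concatenate example sets with different schemas")
        return ExampleSet(
            np.concatenate([s.X for s in sets]),
            np.concatenate([s.y_dr for s in sets]),
            np.concatenate([s.y_state for s in sets]),
            pd.concat([s.context for s in sets], ignore_index=True),
            sets[0].schema,
        )

    # -- serialization ----------------------------------------------------
    # Context + labels are stored as CSV; the feature matrix is rebuilt from
    # the climate driver on load (it is a deterministic function of both).

    def save(self, path) -> None:
        path = Path(path)
        frame = self.context.copy()
        frame["label_dr"] = self.y_dr
        frame["label_state"] = self.y_state
        frame.to_csv(path, index=False)
        meta = {"schema_version": 1, "schema": json.loads(self.schema.to_json())}
        path.with_suffix(path.suffix + ".schema.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path, climate: ClimateDriver) -> "ExampleSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".schema.json").read_text())
        schema = FeatureSchema.from_json(json.dumps(meta["schema"]))
        frame = pd.read_csv(path, comment="#")
        y_dr = frame.pop("label_dr").to_numpy(np.int64)
        y_state = frame.pop("label_state").to_numpy(np.int64)
        X = build_feature_matrix(frame, climate, schema)
        return cls(X, y_dr, y_state, frame, schema)
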