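"""Predictor encoding with a fixed, hashed feature layout.

Layout (in order): state one-hot | residence time | soil depth, soil
fertility | climate window | tier-1 species shares | tier-2 species shares |
distance to edge. The climate window covers the 10 years from the current
simulation year, either as 240 raw monthly values (``monthly``) or as 24
decadal monthly means (``decadal_means``).

The same schema object must be used at train and predict time; models check
its hash before predicting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ..climate import ClimateDriver

__all__ = ["FeatureSchema", "build_feature_matrix", "context_columns"]

CENSORED_CLASS = 0  # class 0 of the timing head: no transition within horizon


def context_columns(species: tuple[str, ...]) -> list[str]:
    """Raw predictor columns expected in an example context frame."""
    return (
        ["cell_row", "cell_col", "year", "region", "state_id", "R",
         "soil_depth", "soil_fertility", "tmean", "edge_dist"]
        + [f"t1_{s}" for s in species]
        + [f"t2_{s}" for s in species]
    )


@dataclass(frozen=True)
class FeatureSchema:
    """Immutable description of the feature vector layout."""

    state_ids: tuple[int, ...]
    species: tuple[str, ...]
    climate_encoding: str = "monthly"  # or "decadal_means"
    horizon: int = 10
    r_cap: float = 100.0
    edge_cap: float = 1000.0

    def __post_init__(self) -> None:
        if self.climate_encoding not in ("monthly", "decadal_means"):
            raise ValueError(f"unknown climate encoding {self.climate_encoding!r}")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        object.__setattr__(self, "state_ids", tuple(int(s) for s in self.state_ids))
        object.__setattr__(self, "species", tuple(self.species))

    @property
    def n_climate(self) -> int:
        if self.climate_encoding == "monthly":
            return 2 * 12 * self.horizon
        return 24

    @property
    def length(self) -> int:
        return len(self.state_ids) + 1 + 2 + self.n_climate + 2 * len(self.species) + 1

    @property
    def column_names(self) -> list[str]:
        names = [f"state_{s}" for s in self.state_ids]
        names += ["res_time", "soil_depth", "soil_fertility"]
        if self.climate_encoding == "monthly":
            names += [f"tm_y{y}_m{m}" for y in range(self.horizon) for m in range(1, 13)]
            names += [f"pr_y{y}_m{m}" for y in range(self.horizon) for m in range(1, 13)]
        else:
            names += [f"tm_m{m}" for m in range(1, 13)]
            names += [f"pr_m{m}" for m in range(1, 13)]
        names += [f"t1_{s}" for s in self.species]
        names += [f"t2_{s}" for s in self.species]
        names += ["edge_dist"]
        return names

    def schema_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        d["state_ids"] = tuple(d["state_ids"])
        d["species"] = tuple(d["species"])
        return cls(**d)


def build_feature_matrix(
    context: pd.DataFrame, climate: ClimateDriver, schema: FeatureSchema
) -> np.ndarray:
    """Encode a context frame into the schema's feature matrix (float32).

    Deterministic; no scaling is applied here (models own their scaler,
    fitted on the training set only).
    """
    n = len(context)
    X = np.zeros((n, schema.length), dtype=np.float32)

    state_index = {s: i for i, s in enumerate(schema.state_ids)}
    states = context["state_id"].to_numpy()
    unknown = set(np.unique(states)) - set(state_index)
    if unknown:
        raise ValueError(f"context contains states absent from schema: {sorted(unknown)}")
    cols = np.array([state_index[s] for s in states])
    X[np.arange(n), cols] = 1.0

    off = len(schema.state_ids)
    X[:, off] = np.minimum(context["R"].to_numpy(float), schema.r_cap) / schema.r_cap
    X[:, off + 1] = context["soil_depth"].to_numpy(float)
    X[:, off + 2] = context["soil_fertility"].to_numpy(float)
    off += 3

    # climate windows are identical for all rows sharing (region, year)
    nclim = schema.n_climate
    cache: dict[tuple[int, int], np.ndarray] = {}
    keys = list(zip(context["region"].to_numpy(int), context["year"].to_numpy(int)))
    for key in set(keys):
        region, year = key
        tm, pr = climate.monthly_window(region, year, schema.horizon)
        if schema.climate_encoding == "monthly":
            cache[key] = np.concatenate([tm, pr])
        else:
            cache[key] = np.concatenate(
                [tm.reshape(schema.horizon, 12).mean(axis=0),
                 pr.reshape(schema.horizon, 12).mean(axis=0)]
            )
    clim_block = np.empty((n, nclim), dtype=np.float32)
    for i, key in enumerate(keys):
        clim_block[i] = cache[key]
    X[:, off : off + nclim] = clim_block
    off += nclim

    for j, s in enumerate(schema.species):
        X[:, off + j] = context[f"t1_{s}"].to_numpy(float)
    off += len(schema.species)
    for j, s in enumerate(schema.species):
        X[:, off + j] = context[f"t2_{s}"].to_numpy(float)
    off += len(schema.species)
    X[:, off] = (
        np.minimum(context["edge_dist"].to_numpy(float), schema.edge_cap) / schema.edge_cap
    )

    if not np.isfinite(X).all():
        raise ValueError("non-finite values in feature matrix")
    return X
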