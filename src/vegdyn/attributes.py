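"""Empirical ecosystem-attribute distributions per (state, residence time).

Each (state, residence-time) class stores the raw sample vector of every
attribute (nonparametric — no fitted densities). Residence time is keyed
exactly up to a cap; beyond the cap all samples pool into the cap key.
During simulation, cell attributes are drawn uniformly from the stored
samples of the cell's (S, R) class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AttributeDB", "hill_diversity", "build_attribute_db"]

DEFAULT_R_CAP = 50
MISSING = float("nan")  # sentinel for states absent from the database


def hill_diversity(shares) -> float:
    """First-order Hill number: exp of the Shannon entropy of normalized
    positive shares. All-zero (or empty) input returns 0 by convention
    (no vegetation), although exp(H) >= 1 for any non-empty community."""
    values = np.asarray(list(shares.values()) if isinstance(shares, dict) else shares, float)
    if (values < 0).any():
        raise ValueError("shares must be non-negative")
    total = values.sum()
    if total == 0:
        return 0.0
    p = values[values > 0] / total
    return float(np.exp(-(p * np.log(p)).sum()))


@dataclass
class AttributeDB:
    """Sample vectors keyed by (state_id, min(R, r_cap))."""

    r_cap: int = DEFAULT_R_CAP
    groups: dict[tuple[int, int], dict[str, np.ndarray]] = field(default_factory=dict)

    def r_key(self, r: int) -> int:
        return min(int(r), self.r_cap)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def attributes(self) -> tuple[str, ...]:
        names: set[str] = set()
        for g in self.groups.values():
            names |= set(g)
        return tuple(sorted(names))

    def _nearest_group(self, state_id: int, r_key: int) -> dict[str, np.ndarray] | None:
        keys = [k for s, k in self.groups if s == state_id]
        if not keys:
            return None
        best = min(keys, key=lambda k: (abs(k - r_key), k))
        return self.groups[(state_id, best)]

    def sample(
        self, state_id: int, r: int, attribute: str, rng: np.random.Generator
    ) -> float:
        """Uniform draw from the stored sample vector; falls back to the
        nearest stored residence-time key for the state. A state with no
        stored group at all yields NaN with a warning."""
        if attribute not in self.attributes:
            raise KeyError(f"unknown attribute {attribute!r}")
        key = (int(state_id), self.r_key(r))
        group = self.groups.get(key) or self._nearest_group(int(state_id), key[1])
        if group is None or attribute not in group:
            warnings.warn(
                f"no stored samples for state {state_id}, attribute {attribute!r}",
                stacklevel=2,
            )
            return MISSING
        vec = group[attribute]
        return float(vec[rng.integers(len(vec))])

    def sample_many(
        self,
        state_ids: np.ndarray,
        rs: np.ndarray,
        attribute: str,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Vectorized draw for congruent state/R arrays."""
        out = np.empty(len(state_ids))
        keys = np.stack([state_ids, np.minimum(rs, self.r_cap)], axis=1)
        warned = False
        for key in np.unique(keys, axis=0):
            mask = (keys == key).all(axis=1)
            group = self.groups.get((int(key[0]), int(key[1])))
            if group is None:
                group = self._nearest_group(int(key[0]), int(key[1]))
            if group is None or attribute not in group:
                if not warned:
                    warnings.warn(
                        f"no stored samples for state {key[0]}, attribute {attribute!r}",
                        stacklevel=2,
                    )
                    warned = True
                out[mask] = MISSING
                continue
            vec = group[attribute]
            out[mask] = vec[rng.integers(len(vec), size=int(mask.sum()))]
        return out

    # -- summaries --------------------------------------------------------

    def summarize(self) -> pd.DataFrame:
        """Per-attribute table of group statistics plus grand means.

        The grand mean is the unweighted mean of the per-group means (every
        S x R class counts once, regardless of its sample count).
        """
        if not self.groups:
            raise ValueError("attribute database is empty")
        rows = []
        for (s, r), group in sorted(self.groups.items()):
            for name, vec in sorted(group.items()):
                rows.append(
                    {
                        "state_id": s,
                        "R_key": r,
                        "attribute": name,
                        "n": len(vec),
                        "mean": float(vec.mean()),
                        "min": float(vec.min()),
                        "max": float(vec.max()),
                    }
                )
        table = pd.DataFrame(rows)
        grand = (
            table.groupby("attribute")["mean"]
            .mean()
            .rename("grand_mean")
            .reset_index()
        )
        combos = (
            table.groupby("attribute")
            .size()
            .rename("n_sr_combinations")
            .reset_index()
        )
        meta = grand.merge(combos, on="attribute")
        return table.merge(meta, on="attribute")

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (s, r), group in sorted(self.groups.items()):
            for name, vec in sorted(group.items()):
                for v in vec:
                    rows.append((s, r, name, float(v)))
        return pd.DataFrame(rows, columns=["state_id", "R_key", "attribute", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, r_cap: int = DEFAULT_R_CAP) -> "AttributeDB":
        frame = pd.read_csv(path, comment="#")
        db = cls(r_cap=r_cap)
        for (s, r, name), grp in frame.groupby(["state_id", "R_key", "attribute"]):
            db.groups.setdefault((int(s), int(r)), {})[str(name)] = grp["value"].to_numpy(float)
        return db


def build_attribute_db(records: pd.DataFrame, r_cap: int = DEFAULT_R_CAP) -> AttributeDB:
    """Group attribute records into (state, capped residence time) classes.

    ``records`` must have columns ``state_id``, ``R`` and one column per
    attribute. Sample counts are conserved: the group sizes sum to the
    record count for every attribute. An empty frame yields an empty DB.
    """
    required = {"state_id", "R"}
    if not required <= set(records.columns):
        raise ValueError("records need 'state_id' and 'R' columns")
    attr_cols = [c for c in records.columns if c not in required]
    db = AttributeDB(r_cap=r_cap)
    if len(records) == 0:
        return db
    for col in attr_cols:
        vals = records[col].to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValueError(f"non-finite values in attribute {col!r}")
    keys = np.stack(
        [records["state_id"].to_numpy(np.int64),
         np.minimum(records["R"].to_numpy(np.int64), r_cap)],
        axis=1,
    )
    order = np.lexsort((keys[:, 1], keys[:, 0]))
    sorted_keys = keys[order]
    boundaries = np.flatnonzero((np.diff(sorted_keys, axis=0) != 0).any(axis=1)) + 1
    for chunk in np.split(order, boundaries):
        s, r = int(keys[chunk[0], 0]), int(keys[chunk[0], 1])
        db.groups[(s, r)] = {
            col: records[col].to_numpy(float)[chunk] for col in attr_cols
        }
    return db
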