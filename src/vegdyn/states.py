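"""Discrete vegetation state space.

A vegetation state combines three classified axes:

* composition — bare ground, single-species dominance, or a small mixture;
* structure   — dominant canopy height in 4 m bins;
* functioning — leaf area index in three density classes.

A :class:`StateTable` maps class triples to dense integer ids and back.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesPool",
    "CompositionClass",
    "VegetationState",
    "StateTable",
    "height_class",
    "lai_class",
    "composition_class",
    "n_composition_classes",
    "enumerate_state_space",
]

#: default number of 4 m height bins: [0,4) ... [96,100), [100, inf)
DEFAULT_N_HEIGHT_CLASSES = 26
HEIGHT_BIN_WIDTH = 4.0
N_LAI_CLASSES = 3

#: a single species with more than this biomass fraction dominates the cell
DOMINANCE_THRESHOLD = 0.66
#: species above this fraction participate in a mixture
MIXTURE_THRESHOLD = 0.20
#: > 20% shares cannot be held by five species at once
MAX_MIXTURE_SIZE = 4

_SHARE_SUM_TOL = 1e-6


@dataclass(frozen=True)
class SpeciesPool:
    """Ordered, immutable pool of species codes.

    Parameters
    ----------
    species
        Unique short species codes (e.g. ``"piab"``, ``"fasy"``). The order
        is fixed for the lifetime of any state table built on the pool.
    thermal_optimum
        Optional per-species optimum temperature (°C). Only consumed by the
        synthetic succession kernel; classification ignores it.
    """

    species: tuple[str, ...]
    thermal_optimum: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.species) == 0:
            raise ValueError("species pool must not be empty")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species codes must be unique")
        if any(not s for s in self.species):
            raise ValueError("species codes must be non-empty strings")
        object.__setattr__(self, "species", tuple(self.species))

    def __len__(self) -> int:
        return len(self.species)

    def __contains__(self, code: str) -> bool:
        return code in self.species

    def index(self, code: str) -> int:
        try:
            return self.species.index(code)
        except ValueError:
            raise LookupError(f"unknown species code {code!r}") from None

    def optimum(self, code: str) -> float:
        if self.thermal_optimum is None or code not in self.thermal_optimum:
            raise LookupError(f"no thermal optimum for species {code!r}")
        return float(self.thermal_optimum[code])


@dataclass(frozen=True)
class CompositionClass:
    """Composition axis class: ``bare``, ``dominated`` or ``mixture``.

    ``members`` are stored in pool order; size 1 for ``dominated``,
    1–4 for ``mixture``, empty for ``bare``.
    """

    kind: str
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("bare", "dominated", "mixture"):
            raise ValueError(f"invalid composition kind {self.kind!r}")
        object.__setattr__(self, "members", tuple(self.members))
        n = len(self.members)
        if self.kind == "bare" and n != 0:
            raise ValueError("bare composition has no members")
        if self.kind == "dominated" and n != 1:
            raise ValueError("dominated composition has exactly one member")
        if self.kind == "mixture" and not (1 <= n <= MAX_MIXTURE_SIZE):
            raise ValueError(
                f"mixture must have 1..{MAX_MIXTURE_SIZE} members, got {n}"
            )
        if len(set(self.members)) != n:
            raise ValueError("duplicate members in composition class")

    def label(self) -> str:
        """Human-readable label: dominant species upper-case, mixtures joined."""
        if self.kind == "bare":
            return "bare"
        if self.kind == "dominated":
            return self.members[0].upper()
        return "+".join(self.members)


@dataclass(frozen=True)
class VegetationState:
    """One discrete state: composition x height class x LAI class."""

    state_id: int
    composition: CompositionClass
    height_class: int
    lai_class: int

    def __post_init__(self) -> None:
        if self.state_id < 0:
            raise ValueError("state_id must be non-negative")
        if self.height_class < 0 or self.lai_class < 0:
            raise ValueError("class indices must be non-negative")
        if self.composition.kind == "bare" and (
            self.height_class != 0 or self.lai_class != 0
        ):
            raise ValueError("bare composition forces height class 0 and LAI class 0")


def height_class(dominant_height: float, n_classes: int = DEFAULT_N_HEIGHT_CLASSES) -> int:
    """Classify dominant canopy height (m) into 4 m bins, capped at the top bin."""
    if not math.isfinite(dominant_height) or dominant_height < 0:
        raise ValueError(f"dominant height must be >= 0, got {dominant_height}")
    return min(int(dominant_height // HEIGHT_BIN_WIDTH), n_classes - 1)


def lai_class(lai: float) -> int:
    """Classify leaf area index: sparse (<=2) -> 0, moderate (2,4] -> 1, dense (>4) -> 2."""
    if not math.isfinite(lai) or lai < 0:
        raise ValueError(f"LAI must be >= 0, got {lai}")
    if lai <= 2.0:
        return 0
    if lai <= 4.0:
        return 1
    return 2


def composition_class(
    shares: Mapping[str, float], pool: SpeciesPool
) -> CompositionClass:
    """Classify biomass shares into a composition class.

    Shares are fractions of total biomass; they may sum to less than one
    (the remainder being unclassified biomass) and are normalized before
    thresholding, which makes the classifier invariant under rescaling by
    a positive constant. An all-zero (or empty) share map is ``bare``.
    """
    total = 0.0
    for code, v in shares.items():
        if code not in pool:
            raise LookupError(f"unknown species code {code!r}")
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"share for {code!r} must be finite and >= 0, got {v}")
        total += v
    if total > 1.0 + _SHARE_SUM_TOL:
        raise ValueError(f"shares sum to {total}, above 1 + tolerance")
    if total == 0.0:
        return CompositionClass("bare")

    # normalized shares in pool order; pool order breaks ties deterministically
    ordered = [(code, shares.get(code, 0.0) / total) for code in pool.species]
    max_code, max_share = max(ordered, key=lambda cv: cv[1])
    if max_share > DOMINANCE_THRESHOLD:
        return CompositionClass("dominated", (max_code,))
    members = [code for code, v in ordered if v > MIXTURE_THRESHOLD]
    if not members:
        members = [max_code]
    if len(members) > MAX_MIXTURE_SIZE:  # only reachable inside the sum tolerance
        members = sorted(members, key=lambda c: -shares[c])[:MAX_MIXTURE_SIZE]
        members = [c for c in pool.species if c in members]
    return CompositionClass("mixture", tuple(members))


class StateTable:
    """Bijective registry of vegetation states.

    In ``open`` mode :meth:`classify` registers unseen class triples on the
    fly; after :meth:`close` an unknown triple raises ``KeyError``. Ids are
    dense ``0..N-1`` in registration order.
    """

    def __init__(
        self,
        pool: SpeciesPool,
        n_height_classes: int = DEFAULT_N_HEIGHT_CLASSES,
        n_lai_classes: int = N_LAI_CLASSES,
        open_mode: bool = True,
    ) -> None:
        if n_height_classes < 1 or n_lai_classes < 1:
            raise ValueError("class counts must be >= 1")
        self.pool = pool
        self.n_height_classes = n_height_classes
        self.n_lai_classes = n_lai_classes
        self.open_mode = open_mode
        self._states: list[VegetationState] = []
        self._by_triple: dict[tuple, int] = {}

    # -- registry ---------------------------------------------------------

    @staticmethod
    def _key(comp: CompositionClass, h: int, lai: int) -> tuple:
        return (comp.kind, comp.members, h, lai)

    def __len__(self) -> int:
        return len(self._states)

    def __iter__(self):
        return iter(self._states)

    def __getitem__(self, state_id: int) -> VegetationState:
        return self._states[state_id]

    @property
    def states(self) -> Sequence[VegetationState]:
        return tuple(self._states)

    def close(self) -> "StateTable":
        self.open_mode = False
        return self

    def add_state(
        self, comp: CompositionClass, height_cls: int, lai_cls: int
    ) -> VegetationState:
        if comp.kind == "bare":
            height_cls, lai_cls = 0, 0
        if not (0 <= height_cls < self.n_height_classes):
            raise ValueError(f"height class {height_cls} out of range")
        if not (0 <= lai_cls < self.n_lai_classes):
            raise ValueError(f"LAI class {lai_cls} out of range")
        for m in comp.members:
            if m not in self.pool:
                raise LookupError(f"unknown species code {m!r}")
        key = self._key(comp, height_cls, lai_cls)
        if key in self._by_triple:
            return self._states[self._by_triple[key]]
        state = VegetationState(len(self._states), comp, height_cls, lai_cls)
        self._states.append(state)
        self._by_triple[key] = state.state_id
        return state

    def id_of(self, comp: CompositionClass, height_cls: int, lai_cls: int) -> int:
        if comp.kind == "bare":
            height_cls, lai_cls = 0, 0
        key = self._key(comp, height_cls, lai_cls)
        if key not in self._by_triple:
            if not self.open_mode:
                raise KeyError(
                    f"state ({comp.label()}, h{height_cls}, lai{lai_cls}) "
                    "not registered and table is closed"
                )
            return self.add_state(comp, height_cls, lai_cls).state_id
        return self._by_triple[key]

    def classify(
        self, shares: Mapping[str, float], dominant_height: float, lai: float
    ) -> int:
        """Classify raw axis values to a state id (registering if open)."""
        comp = composition_class(shares, self.pool)
        h = height_class(dominant_height, self.n_height_classes)
        l = lai_class(lai)
        return self.id_of(comp, h, l)

    def decode(self, state_id: int) -> tuple[CompositionClass, int, int]:
        s = self._states[state_id]
        return s.composition, s.height_class, s.lai_class

    # -- derived arrays ---------------------------------------------------

    def species_weight_matrix(self) -> np.ndarray:
        """Per-state species weights used for neighbourhood share averaging.

        Dominated states weight their dominant at 1, mixtures weight each of
        k members at 1/k, bare weights everything at 0.
        """
        w = np.zeros((len(self._states), len(self.pool)), dtype=float)
        for s in self._states:
            members = s.composition.members
            if members:
                for code in members:
                    w[s.state_id, self.pool.index(code)] = 1.0 / len(members)
        return w

    # -- serialization ----------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["state_id", "composition_kind", "members", "height_class", "lai_class"]
            )
            for s in self._states:
                members = "+".join(
                    c for c in self.pool.species if c in s.composition.members
                )
                writer.writerow(
                    [s.state_id, s.composition.kind, members, s.height_class, s.lai_class]
                )

    @classmethod
    def from_csv(
        cls,
        path,
        pool: SpeciesPool,
        n_height_classes: int = DEFAULT_N_HEIGHT_CLASSES,
        n_lai_classes: int = N_LAI_CLASSES,
        open_mode: bool = False,
    ) -> "StateTable":
        rows = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"state_id", "composition_kind", "members", "height_class", "lai_class"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(f"state table must have columns {sorted(required)}")
            for row in reader:
                rows.append(row)
        rows.sort(key=lambda r: int(r["state_id"]))
        ids = [int(r["state_id"]) for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate state_id in state table")
        if ids != list(range(len(ids))):
            raise ValueError("state ids must be dense 0..N-1")
        table = cls(pool, n_height_classes, n_lai_classes, open_mode=True)
        for r in rows:
            members = tuple(m for m in r["members"].split("+") if m)
            for m in members:
                if m not in pool:
                    raise ValueError(f"state table references unknown species {m!r}")
            comp = CompositionClass(r["composition_kind"], members)
            table.add_state(comp, int(r["height_class"]), int(r["lai_class"]))
        table.open_mode = open_mode
        return table


def n_composition_classes(pool_size: int, max_mixture: int = MAX_MIXTURE_SIZE) -> int:
    """Count composition classes under the implemented rule.

    bare + one dominated class per species + all mixtures of size 1..max_mixture.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    return 1 + pool_size + sum(
        math.comb(pool_size, k) for k in range(1, min(max_mixture, pool_size) + 1)
    )


def enumerate_state_space(
    pool_size: int,
    n_height_classes: int = DEFAULT_N_HEIGHT_CLASSES,
    n_lai_classes: int = N_LAI_CLASSES,
    n_composition: int | None = None,
    list_states: bool = False,
    pool: SpeciesPool | None = None,
) -> tuple[int, list[tuple[CompositionClass, int, int]] | None]:
    """Total size of the state space, optionally with the full triple list.

    ``n_composition`` overrides the composition-class count so externally
    printed per-axis factors can be multiplied verbatim; without it the count
    follows the implemented composition rule (bare + dominated + mixtures of
    size 1–4). Plain-integer arithmetic, exact beyond 10^9.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    n_comp = n_composition if n_composition is not None else n_composition_classes(pool_size)
    count = n_comp * n_height_classes * n_lai_classes
    if not list_states:
        return count, None
    if n_composition is not None:
        raise ValueError("cannot list states for an overridden composition count")
    if pool is None:
        pool = SpeciesPool(tuple(f"sp{i:02d}" for i in range(pool_size)))
    if len(pool) != pool_size:
        raise ValueError("pool size mismatch")
    comps: list[CompositionClass] = [CompositionClass("bare")]
    comps += [CompositionClass("dominated", (c,)) for c in pool.species]
    for k in range(1, min(MAX_MIXTURE_SIZE, pool_size) + 1):
        comps += [CompositionClass("mixture", m) for m in combinations(pool.species, k)]
    triples = []
    for comp in comps:
        if comp.kind == "bare":
            triples.append((comp, 0, 0))
            # bare occupies one (h0, lai0) slot; remaining bare combinations
            # are structurally identical and enumerated for the count only
            triples += [
                (comp, h, l)
                for h in range(n_height_classes)
                for l in range(n_lai_classes)
                if (h, l) != (0, 0)
            ]
        else:
            triples += [
                (comp, h, l)
                for h in range(n_height_classes)
                for l in range(n_lai_classes)
            ]
    return count, triples
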