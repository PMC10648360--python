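"""SF-6D health states and utility tariffs.

The SF-6D classifies health into six dimensions — physical functioning,
role limitations, social functioning, pain, mental health and vitality —
with (6, 4, 5, 6, 5, 5) ordinal levels respectively, 18,000 possible
states in all.  A *tariff* is a country-specific scoring function that
assigns a societal-preference utility to each state: a constant (the
utility of full health, level 1 everywhere) minus per-dimension,
per-level decrements, optionally minus extra indicator-based terms
(e.g. an additional decrement whenever any dimension is at its worst
level).  The Hong Kong tariff used throughout this package's intended
application has utility bounds (0.315, 1); its coefficients are not
redistributable here, so users supply it as a JSON file and a synthetic
stand-in ships for testing (see :func:`sf6dmap.synthetic.make_synthetic_tariff`).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

SF6D_DIMENSIONS = (
    "physical_functioning",
    "role_limitations",
    "social_functioning",
    "pain",
    "mental_health",
    "vitality",
)

#: Number of ordinal levels per SF-6D dimension, in instrument order.
SF6D_LEVELS = (6, 4, 5, 6, 5, 5)


@dataclass(frozen=True)
class ExtraTerm:
    """Indicator-based tariff adjustment.

    The decrement applies when the condition over dimension levels holds:
    ``mode="any"`` fires if any listed dimension is at or beyond its
    ``at_least`` level (e.g. the classic "most severe" term), ``mode="all"``
    only if all are (an interaction term).
    """

    name: str
    decrement: float
    when: tuple[tuple[str, int], ...]  # (dimension name, minimum level)
    mode: str = "any"

    def applies(self, state: Sequence[int], dim_index: dict[str, int]) -> bool:
        hits = (state[dim_index[d]] >= lvl for d, lvl in self.when)
        return any(hits) if self.mode == "any" else all(hits)


@dataclass
class Tariff:
    """Additive SF-6D utility tariff with optional indicator terms.

    ``decrements[d][l-1]`` is the utility decrement for level ``l`` of
    dimension ``d``; level 1 carries decrement 0 by construction.
    """

    constant: float
    dimensions: tuple[str, ...]
    decrements: tuple[tuple[float, ...], ...]
    extra_terms: tuple[ExtraTerm, ...] = ()
    min_utility: float | None = None
    max_utility: float | None = None
    _dim_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.dimensions) != len(self.decrements):
            raise ValueError("one decrement vector per dimension required")
        for name, dec in zip(self.dimensions, self.decrements):
            if abs(dec[0]) > 1e-12:
                raise ValueError(f"level-1 decrement must be 0 for {name!r}")
        self._dim_index = {d: i for i, d in enumerate(self.dimensions)}
        if self.max_utility is None:
            self.max_utility = self.constant
        if self.min_utility is None:
            self.min_utility = min(self.utility(s) for s in self.state_space())

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(len(d) for d in self.decrements)

    def n_states(self) -> int:
        return int(np.prod(self.level_counts))

    def state_space(self) -> Iterator[tuple[int, ...]]:
        """Yield every health state exactly once, lexicographically."""
        yield from itertools.product(*(range(1, L + 1) for L in self.level_counts))

    def utility(self, state: Sequence[int]) -> float:
        """Utility of a single state (levels are 1-based, one per dimension)."""
        state = tuple(int(s) for s in state)
        if len(state) != len(self.dimensions):
            raise ValueError("state length does not match tariff dimensions")
        u = self.constant
        for i, (name, lvl) in enumerate(zip(self.dimensions, state)):
            if not 1 <= lvl <= self.level_counts[i]:
                raise ValueError(
                    f"level {lvl} out of range 1..{self.level_counts[i]} "
                    f"for dimension {name!r}"
                )
            u -= self.decrements[i][lvl - 1]
        for term in self.extra_terms:
            if term.applies(state, self._dim_index):
                u -= term.decrement
        return u

    def utilities(self, states: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`utility` over an (n, n_dims) integer array."""
        states = np.asarray(states, dtype=int)
        if states.ndim == 1:
            states = states[None, :]
        u = np.full(states.shape[0], self.constant, dtype=float)
        for i in range(len(self.dimensions)):
            lv = states[:, i]
            if lv.min() < 1 or lv.max() > self.level_counts[i]:
                bad = int(lv.min()) if lv.min() < 1 else int(lv.max())
                raise ValueError(
                    f"level {bad} out of range for dimension {self.dimensions[i]!r}"
                )
            u -= np.asarray(self.decrements[i])[lv - 1]
        for term in self.extra_terms:
            hits = np.column_stack(
                [states[:, self._dim_index[d]] >= lvl for d, lvl in term.when]
            )
            fired = hits.any(axis=1) if term.mode == "any" else hits.all(axis=1)
            u -= term.decrement * fired
        return u

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "constant": self.constant,
            "dimensions": [
                {"name": n, "decrements": list(d)}
                for n, d in zip(self.dimensions, self.decrements)
            ],
            "extra_terms": [
                {
                    "name": t.name,
                    "decrement": t.decrement,
                    "when": [{"dimension": d, "at_least": l} for d, l in t.when],
                    "mode": t.mode,
                }
                for t in self.extra_terms
            ],
            "min_utility": self.min_utility,
            "max_utility": self.max_utility,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Tariff":
        return cls(
            constant=float(payload["constant"]),
            dimensions=tuple(d["name"] for d in payload["dimensions"]),
            decrements=tuple(
                tuple(float(x) for x in d["decrements"]) for d in payload["dimensions"]
            ),
            extra_terms=tuple(
                ExtraTerm(
                    name=t["name"],
                    decrement=float(t["decrement"]),
                    when=tuple((w["dimension"], int(w["at_least"])) for w in t["when"]),
                    mode=t.get("mode", "any"),
                )
                for t in payload.get("extra_terms", [])
            ),
            min_utility=payload.get("min_utility"),
            max_utility=payload.get("max_utility"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Tariff":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def utility_from_state(state: Sequence[int], tariff: Tariff) -> float:
    """Score one SF-6D state under a tariff."""
    return tariff.utility(state)


def enumerate_state_space(tariff: Tariff) -> tuple[int, Iterator[tuple[int, ...]]]:
    """Count and iterate the tariff's full health-state space."""
    return tariff.n_states(), tariff.state_space()
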