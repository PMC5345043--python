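"""Core containers: item catalog and person x wave x item response panel.

Conventions used throughout the package:

* responses are coded 0-based with **higher = worse health** (items whose
  raw direction is the opposite are reversed by :mod:`healthtrait.item_prep`);
* ``MISSING`` (-1) marks a cell that was administered but not answered;
* ``UNAVAILABLE`` (-2) marks a cell that is structurally absent because the
  item was not fielded in that wave (wave-varying items).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
UNAVAILABLE = -2


@dataclass
class ItemInfo:
    """Metadata for one ordinal item."""

    name: str
    n_categories: int
    factors: tuple[int, ...]  # first-order factor indices (>=1 entry)
    available: tuple[bool, ...]  # one flag per wave
    direction: str = "higher_is_worse"

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(f"item {self.name}: needs >=2 categories")
        if self.direction not in ("higher_is_worse", "higher_is_better"):
            raise ValueError(f"item {self.name}: unknown direction {self.direction!r}")

    @property
    def is_anchor(self) -> bool:
        return all(self.available)


@dataclass
class ItemCatalog:
    """Ordered collection of :class:`ItemInfo` sharing one wave count."""

    items: list[ItemInfo]

    def __post_init__(self) -> None:
        waves = {len(it.available) for it in self.items}
        if len(waves) > 1:
            raise ValueError("items disagree on number of waves")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i: int) -> ItemInfo:
        return self.items[i]

    @property
    def n_waves(self) -> int:
        return len(self.items[0].available)

    @property
    def names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([it.n_categories for it in self.items])

    def availability_matrix(self) -> np.ndarray:
        """Boolean (n_items, n_waves) availability mask."""
        return np.array([it.available for it in self.items], dtype=bool)

    def anchor_indices(self) -> np.ndarray:
        return np.array([i for i, it in enumerate(self.items) if it.is_anchor], dtype=int)

    def varying_indices(self) -> np.ndarray:
        return np.array([i for i, it in enumerate(self.items) if not it.is_anchor], dtype=int)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "name": it.name,
                "n_categories": it.n_categories,
                "factors": list(it.factors),
                "available": list(it.available),
                "direction": it.direction,
            }
            for it in self.items
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ItemCatalog":
        payload = json.loads(Path(path).read_text())
        return cls(
            [
                ItemInfo(
                    name=d["name"],
                    n_categories=d["n_categories"],
                    factors=tuple(d["factors"]),
                    available=tuple(bool(a) for a in d["available"]),
                    direction=d.get("direction", "higher_is_worse"),
                )
                for d in payload
            ]
        )


@dataclass
class ResponsePanel:
    """Ordinal responses on a dense (person, wave, item) grid.

    ``data`` holds the category codes; negative codes are the two missing
    sentinels.  ``person_ids`` indexes axis 0, waves are 1-based on axis 1,
    ``item_names`` indexes axis 2.
    """

    data: np.ndarray  # int16 (n_persons, n_waves, n_items)
    person_ids: np.ndarray
    item_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        if self.data.ndim != 3:
            raise ValueError("panel data must be 3-dimensional")
        if self.data.shape[0] != len(self.person_ids):
            raise ValueError("person_ids length mismatch")
        if self.data.shape[2] != len(self.item_names):
            raise ValueError("item_names length mismatch")

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_waves(self) -> int:
        return self.data.shape[1]

    @property
    def n_items(self) -> int:
        return self.data.shape[2]

    def observed_mask(self) -> np.ndarray:
        return self.data >= 0

    def copy(self) -> "ResponsePanel":
        return ResponsePanel(self.data.copy(), self.person_ids.copy(), list(self.item_names))

    def wave(self, w: int) -> np.ndarray:
        """Responses of 1-based wave ``w`` as (n_persons, n_items)."""
        return self.data[:, w - 1, :]

    def to_long(self) -> pd.DataFrame:
        """Long CSV-ready frame with one row per non-structural cell."""
        p, w, i = np.where(self.data != UNAVAILABLE)
        vals = self.data[p, w, i]
        return pd.DataFrame(
            {
                "person_id": np.asarray(self.person_ids)[p],
                "wave": w + 1,
                "item_id": np.asarray(self.item_names, dtype=object)[i],
                "response": np.where(vals == MISSING, np.nan, vals),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(
        cls,
        frame: pd.DataFrame,
        catalog: ItemCatalog | None = None,
        n_waves: int | None = None,
    ) -> "ResponsePanel":
        """Build a dense panel from long format.

        Cells absent from the frame are marked ``UNAVAILABLE`` unless the
        catalog says the item was fielded, in which case they are ``MISSING``.
        """
        persons = np.sort(frame["person_id"].unique())
        if catalog is not None:
            items = catalog.names
            n_waves = catalog.n_waves
        else:
            items = sorted(frame["item_id"].unique())
            n_waves = int(n_waves or frame["wave"].max())
        p_idx = {p: i for i, p in enumerate(persons)}
        i_idx = {it: i for i, it in enumerate(items)}
        data = np.full((len(persons), n_waves, len(items)), UNAVAILABLE, dtype=np.int16)
        if catalog is not None:
            avail = catalog.availability_matrix()  # (items, waves)
            for j in range(len(items)):
                for w in range(n_waves):
                    if avail[j, w]:
                        data[:, w, j] = MISSING
        rows_p = frame["person_id"].map(p_idx).to_numpy()
        rows_w = frame["wave"].to_numpy(dtype=int) - 1
        rows_i = frame["item_id"].map(i_idx).to_numpy()
        resp = frame["response"].to_numpy(dtype=float)
        obs = ~np.isnan(resp)
        data[rows_p[obs], rows_w[obs], rows_i[obs]] = resp[obs].astype(np.int16)
        data[rows_p[~obs], rows_w[~obs], rows_i[~obs]] = MISSING
        return cls(data, persons, list(items))

    @classmethod
    def from_csv(cls, path: str | Path, catalog: ItemCatalog | None = None) -> "ResponsePanel":
        return cls.from_long(pd.read_csv(path), catalog=catalog)
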