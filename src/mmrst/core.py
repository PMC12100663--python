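"""Core domain types shared across the analysis stages.

``AdminHierarchy`` captures the nested county → city → province → region
administrative structure (plus a rural/urban flag per county);
``SpaceTimePanel`` holds a complete unit × year rate matrix;
``LatticeGeometry`` places counties on a planar grid so contiguity can be
derived without real polygons.  All three round-trip through plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdminHierarchy",
    "LatticeGeometry",
    "SpaceTimePanel",
]


@dataclass(frozen=True)
class AdminHierarchy:
    """Nested administrative lookup: county → city → province → region.

    Parameters
    ----------
    county_ids
        Ordered unit identifiers.  The order fixes the index used by every
        array-valued quantity downstream.
    city_of, province_of, region_of
        Total maps county→city, city→province, province→region.
    urban_flag
        ``True`` for urban counties, ``False`` for rural.
    """

    county_ids: tuple[str, ...]
    city_of: Mapping[str, str]
    province_of: Mapping[str, str]
    region_of: Mapping[str, str]
    urban_flag: Mapping[str, bool]

    def __post_init__(self) -> None:
        missing = [c for c in self.county_ids if c not in self.city_of]
        if missing:
            raise ValueError(f"counties without a city: {missing[:5]}")
        for city in set(self.city_of.values()):
            if city not in self.province_of:
                raise ValueError(f"city {city!r} has no province")
        for prov in set(self.province_of.values()):
            if prov not in self.region_of:
                raise ValueError(f"province {prov!r} has no region")
        if set(self.urban_flag) < set(self.county_ids):
            raise ValueError("urban_flag must be total over county_ids")

    # -- derived views ---------------------------------------------------
    @property
    def n_counties(self) -> int:
        return len(self.county_ids)

    @property
    def cities(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.county_ids:
            seen.setdefault(self.city_of[c], None)
        return tuple(seen)

    @property
    def provinces(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for city in self.cities:
            seen.setdefault(self.province_of[city], None)
        return tuple(seen)

    @property
    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for prov in self.provinces:
            seen.setdefault(self.region_of[prov], None)
        return tuple(seen)

    def province_of_county(self, county: str) -> str:
        return self.province_of[self.city_of[county]]

    def region_of_county(self, county: str) -> str:
        return self.region_of[self.province_of_county(county)]

    def level_labels(self, county: str) -> dict[str, str]:
        """All group labels of one county, keyed by level name."""
        return {
            "rural-urban": "urban" if self.urban_flag[county] else "rural",
            "region": self.region_of_county(county),
            "province": self.province_of_county(county),
            "city": self.city_of[county],
            "county": county,
        }

    def group_indices(self, level: str) -> tuple[np.ndarray, tuple[str, ...]]:
        """Integer group index per county (in ``county_ids`` order) and labels.

        ``level`` is one of ``rural-urban``, ``region``, ``province``,
        ``city``, ``county``.
        """
        labels_per_county = [self.level_labels(c)[level] for c in self.county_ids]
        if level == "rural-urban":
            labels: tuple[str, ...] = ("rural", "urban")
        else:
            seen: dict[str, None] = {}
            for lab in labels_per_county:
                seen.setdefault(lab, None)
            labels = tuple(seen)
        lut = {lab: k for k, lab in enumerate(labels)}
        idx = np.array([lut[lab] for lab in labels_per_county], dtype=np.intp)
        return idx, labels

    # -- IO --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.county_ids:
            rows.append(
                {
                    "county_id": c,
                    "city_id": self.city_of[c],
                    "province_id": self.province_of_county(c),
                    "region_id": self.region_of_county(c),
                    "urban": int(self.urban_flag[c]),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AdminHierarchy":
        required = {"county_id", "city_id", "province_id", "region_id", "urban"}
        if not required <= set(df.columns):
            raise ValueError(f"hierarchy table needs columns {sorted(required)}")
        county_ids = tuple(df["county_id"].astype(str))
        city_of = dict(zip(county_ids, df["city_id"].astype(str)))
        province_of = dict(zip(df["city_id"].astype(str), df["province_id"].astype(str)))
        region_of = dict(zip(df["province_id"].astype(str), df["region_id"].astype(str)))
        urban = dict(zip(county_ids, df["urban"].astype(bool)))
        return cls(county_ids, city_of, province_of, region_of, urban)

    @classmethod
    def from_csv(cls, path) -> "AdminHierarchy":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class LatticeGeometry:
    """Grid placement of counties (row, col per county), a polygon stand-in."""

    coords: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        seen = set()
        for c, rc in self.coords.items():
            rc = tuple(rc)
            if rc in seen:
                raise ValueError(f"duplicate grid coordinate {rc} at {c!r}")
            seen.add(rc)

    @property
    def county_ids(self) -> tuple[str, ...]:
        return tuple(self.coords)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"county_id": c, "row": r, "col": k}
                for c, (r, k) in self.coords.items()
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LatticeGeometry":
        df = pd.read_csv(path)
        return cls(
            {
                str(row.county_id): (int(row.row), int(row.col))
                for row in df.itertuples()
            }
        )

    def to_geojson(self, path) -> None:
        """Write unit-square polygons (one per grid cell) as GeoJSON."""
        import json

        feats = []
        for c, (r, k) in self.coords.items():
            ring = [[k, r], [k + 1, r], [k + 1, r + 1], [k, r + 1], [k, r]]
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"county_id": c},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class SpaceTimePanel:
    """Complete unit × year matrix of nonnegative rates.

    ``values[i, t]`` is the rate for ``unit_ids[i]`` in ``years[t]``.
    """

    unit_ids: tuple[str, ...]
    years: tuple[int, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.unit_ids), len(self.years)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.unit_ids)} units x {len(self.years)} years"
            )
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel contains non-finite values")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_values(self, year: int) -> np.ndarray:
        try:
            t = self.years.index(year)
        except ValueError:
            raise KeyError(f"year {year} not in panel") from None
        return self.values[:, t]

    def subset_units(self, ids: Sequence[str]) -> "SpaceTimePanel":
        pos = {u: i for i, u in enumerate(self.unit_ids)}
        rows = [pos[u] for u in ids]
        return SpaceTimePanel(tuple(ids), self.years, self.values[rows])

    # -- IO --------------------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        k, t = np.meshgrid(
            np.arange(self.n_units), np.arange(self.n_years), indexing="ij"
        )
        return pd.DataFrame(
            {
                "county_id": np.asarray(self.unit_ids, dtype=object)[k.ravel()],
                "year": np.asarray(self.years)[t.ravel()],
                "value": self.values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "SpaceTimePanel":
        required = {"county_id", "year", "value"}
        if not required <= set(df.columns):
            raise ValueError(f"panel table needs columns {sorted(required)}")
        units = tuple(dict.fromkeys(df["county_id"].astype(str)))
        years = tuple(sorted(set(int(y) for y in df["year"])))
        wide = df.assign(county_id=df["county_id"].astype(str)).pivot_table(
            index="county_id", columns="year", values="value", aggfunc="first"
        )
        wide = wide.reindex(index=list(units), columns=list(years))
        if wide.isna().any().any():
            mask = wide.isna()
            missing = [(u, y) for u in units for y in years if mask.at[u, y]]
            raise ValueError(
                "panel is incomplete; missing (unit, year) cells: "
                f"{missing[:10]}"
            )
        return cls(units, years, wide.to_numpy())

    @classmethod
    def from_csv(cls, path) -> "SpaceTimePanel":
        return cls.from_long_frame(pd.read_csv(path))
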