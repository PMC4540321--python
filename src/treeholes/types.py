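"""Domain types for artificial tree-hole (cup) surveys.

A survey consists of cups fixed to tree trunks, each sampled once at one
date. For every cup we carry per-taxon counts binned into length classes,
plus the physicochemical and meteorological record used as candidate
predictors in the ordination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "TaxonSpec",
    "EnvironmentalRecord",
    "CupSample",
    "SurveyDesign",
    "ENV_VARIABLES",
    "MEIOFAUNA",
    "MACROFAUNA",
    "DEFAULT_BOTTOM_AREA_CM2",
]


class ValidationError(ValueError):
    """A data row or value violates a typed invariant."""


class ConfigurationError(ValueError):
    """A taxon configuration is missing or inconsistent."""


MEIOFAUNA = "meiofauna"
MACROFAUNA = "macrofauna"

#: Candidate environmental predictors, in canonical column order.
ENV_VARIABLES = (
    "chl_a",                  # µg cm⁻², algal biomass proxy
    "afdm",                   # mg cm⁻², ash-free dry mass (organic content)
    "o2",                     # mg L⁻¹ (may be missing, e.g. frozen cups)
    "ph",                     # unitless
    "conductivity",           # µS cm⁻¹
    "water_volume",           # mL
    "last_rain",              # days since last rain event
    "avg_daily_rain",         # mm d⁻¹
    "last_frost",             # days since last frost
    "avg_daily_temperature",  # °C
)

#: Variables that cannot physically be negative.
_NONNEGATIVE_ENV = ("chl_a", "afdm", "water_volume", "last_rain", "last_frost")

#: Bottom area of the one-liter polyethylene cups, cm².
DEFAULT_BOTTOM_AREA_CM2 = 71.0

_METHODS = ("volumetric_nematode", "box_volume", "power_law", "exponential")


@dataclass(frozen=True)
class TaxonSpec:
    """Allometric configuration of one taxon.

    Parameters
    ----------
    name : str
        Taxon label as it appears in count tables.
    group : {"meiofauna", "macrofauna"}
        Community partition: meiofauna pass a 1,000 µm mesh and are retained
        on 40 µm; macrofauna are retained on 1,000 µm.
    method : {"volumetric_nematode", "box_volume", "power_law", "exponential"}
        Length→dry-weight model.
    constants : mapping of str to float
        Model constants. ``volumetric_nematode`` and ``box_volume`` require
        ``dry_wet_ratio`` in (0, 1] and use ``width_ratio`` (and
        ``height_ratio`` for the box model) to derive the transverse
        dimensions from the representative length. ``power_law`` requires
        ``a > 0`` and ``b > 0``; ``exponential`` requires ``coef > 0`` and
        ``rate > 0``.
    size_class_edges : sequence of float
        Strictly increasing class edges in mm; at least two edges. An
        open-ended first class ("<0.25 mm") is encoded with lower edge 0.
    length_unit_for_formula : {"um", "mm"}
        Unit the allometric formula expects; edges are always mm.
    dw_output_unit : {"ug", "mg"}
        Unit the formula returns; biomass aggregation converts to µg.
    """

    name: str
    group: str
    method: str
    constants: Mapping[str, float]
    size_class_edges: tuple[float, ...]
    length_unit_for_formula: str = "mm"
    dw_output_unit: str = "ug"

    def __post_init__(self) -> None:
        if self.group not in (MEIOFAUNA, MACROFAUNA):
            raise ConfigurationError(
                f"{self.name}: group must be meiofauna or macrofauna, got {self.group!r}"
            )
        if self.method not in _METHODS:
            raise ConfigurationError(f"{self.name}: unknown method {self.method!r}")
        edges = tuple(float(e) for e in self.size_class_edges)
        object.__setattr__(self, "size_class_edges", edges)
        if len(edges) < 2:
            raise ConfigurationError(f"{self.name}: need at least 2 size-class edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigurationError(
                f"{self.name}: size_class_edges must be strictly increasing: {edges}"
            )
        c = dict(self.constants)
        object.__setattr__(self, "constants", c)
        if self.method == "power_law":
            if c.get("a", 0.0) <= 0 or c.get("b", 0.0) <= 0:
                raise ConfigurationError(f"{self.name}: power_law requires a>0 and b>0")
        elif self.method == "exponential":
            if c.get("coef", 0.0) <= 0 or c.get("rate", 0.0) <= 0:
                raise ConfigurationError(
                    f"{self.name}: exponential requires coef>0 and rate>0"
                )
        else:
            r = c.get("dry_wet_ratio", 0.0)
            if not (0.0 < r <= 1.0):
                raise ConfigurationError(
                    f"{self.name}: {self.method} requires dry_wet_ratio in (0, 1]"
                )
        if self.length_unit_for_formula not in ("um", "mm"):
            raise ConfigurationError(
                f"{self.name}: length_unit_for_formula must be 'um' or 'mm'"
            )
        if self.dw_output_unit not in ("ug", "mg"):
            raise ConfigurationError(f"{self.name}: dw_output_unit must be 'ug' or 'mg'")

    @property
    def n_classes(self) -> int:
        return len(self.size_class_edges) - 1


@dataclass(frozen=True)
class EnvironmentalRecord:
    """Per-cup environmental measurements; ``None`` marks a missing value."""

    chl_a: float | None = None
    afdm: float | None = None
    o2: float | None = None
    ph: float | None = None
    conductivity: float | None = None
    water_volume: float | None = None
    last_rain: float | None = None
    avg_daily_rain: float | None = None
    last_frost: float | None = None
    avg_daily_temperature: float | None = None

    def __post_init__(self) -> None:
        for name in _NONNEGATIVE_ENV:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"environmental variable {name} must be >= 0, got {v}")
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and not math.isfinite(float(v)):
                raise ValidationError(f"environmental variable {f.name} is not finite")

    def as_vector(self) -> np.ndarray:
        """Values in :data:`ENV_VARIABLES` order; missing becomes NaN."""
        return np.array(
            [np.nan if getattr(self, v) is None else float(getattr(self, v))
             for v in ENV_VARIABLES]
        )

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(v for v in ENV_VARIABLES if getattr(self, v) is None)


@dataclass(frozen=True)
class CupSample:
    """One cup at one sampling date.

    ``counts`` maps taxon name to the per-size-class integer count vector
    (individuals per cup); the vector length must equal the taxon's number
    of size classes.
    """

    site: str
    tree_id: str
    date: str
    counts: Mapping[str, np.ndarray]
    env: EnvironmentalRecord
    bottom_area: float = DEFAULT_BOTTOM_AREA_CM2

    def __post_init__(self) -> None:
        if self.bottom_area <= 0:
            raise ValidationError(f"{self.key}: bottom_area must be > 0")
        clean: dict[str, np.ndarray] = {}
        for taxon, vec in self.counts.items():
            arr = np.asarray(vec)
            if arr.ndim != 1:
                raise ValidationError(f"{self.key}/{taxon}: counts must be a 1-D vector")
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError(f"{self.key}/{taxon}: counts must be integers")
            arr = arr.astype(np.int64)
            if np.any(arr < 0):
                raise ValidationError(f"{self.key}/{taxon}: counts must be non-negative")
            clean[taxon] = arr
        object.__setattr__(self, "counts", clean)

    @property
    def key(self) -> tuple[str, str, str]:
        """Cup identity: (site, tree_id, date) — one cup per tree per date."""
        return (self.site, self.tree_id, self.date)

    def total_count(self, taxon: str | None = None) -> int:
        if taxon is not None:
            return int(self.counts.get(taxon, np.zeros(0, dtype=np.int64)).sum())
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def validate_against(self, specs: Mapping[str, TaxonSpec]) -> None:
        for taxon, vec in self.counts.items():
            if taxon not in specs:
                raise ConfigurationError(f"{self.key}: no TaxonSpec for taxon {taxon!r}")
            if len(vec) != specs[taxon].n_classes:
                raise ValidationError(
                    f"{self.key}/{taxon}: expected {specs[taxon].n_classes} size classes, "
                    f"got {len(vec)}"
                )


@dataclass(frozen=True)
class SurveyDesign:
    """Replicate structure of the cup survey."""

    sites: tuple[str, ...] = ("K-O", "K-Y", "O-O", "O-Y")
    trees_per_site: int = 15
    cups_per_tree: int = 5
    dates: tuple[str, ...] = (
        "2012-05", "2012-08", "2012-11", "2013-03", "2013-07",
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "dates", tuple(self.dates))
        if self.trees_per_site <= 0 or self.cups_per_tree <= 0:
            raise ValidationError("trees_per_site and cups_per_tree must be positive")
        if len(self.dates) > self.cups_per_tree:
            raise ValidationError(
                "one cup is removed per tree per date; need cups_per_tree >= #dates"
            )

    @property
    def n_cups(self) -> int:
        """Total cups deployed (5 per tree; one harvested per date)."""
        return len(self.sites) * self.trees_per_site * self.cups_per_tree

    @property
    def n_sampled(self) -> int:
        """Cups harvested over the whole survey (one per tree per date)."""
        return len(self.sites) * self.trees_per_site * len(self.dates)
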