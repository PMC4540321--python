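"""Delimited-table input/output and taxon configuration.

File dialect: comma-separated UTF-8 with a mandatory header row, "." as the
decimal separator, empty cell = missing. Counts are stored long-format, one
row per (cup, taxon, size class); environmental records one row per cup.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    ENV_VARIABLES,
    DEFAULT_BOTTOM_AREA_CM2,
    ConfigurationError,
    CupSample,
    EnvironmentalRecord,
    TaxonSpec,
    ValidationError,
)

__all__ = [
    "read_survey",
    "write_survey",
    "write_report",
    "load_taxa",
    "dump_taxa",
    "default_taxa",
]

log = logging.getLogger(__name__)

_KEY_COLS = ["site", "tree_id", "date"]


def _frange(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step))
    return [round(start + i * step, 6) for i in range(n + 1)]


def default_taxa() -> dict[str, TaxonSpec]:
    """Taxon configuration for the twelve tree-hole taxa.

    Size classes and dry-weight methods follow the field conventions for
    these groups: a volumetric formula for nematodes, a box-volume model for
    rotifers and tardigrades, taxon-specific length–weight power laws for
    most insect larvae, and an exponential model for *Culex*. Power-law
    constants other than *Myathropa*'s are representative values for the
    family and can be swapped in config; all constants live here, not in
    code. Width/height ratios give the transverse dimensions as a fraction
    of body length.
    """
    nem_const = {"dry_wet_ratio": 0.25, "width_ratio": 0.05}
    box_const = {"dry_wet_ratio": 0.25, "width_ratio": 0.33, "height_ratio": 0.33}

    def power(a: float, b: float) -> dict[str, float]:
        return {"a": a, "b": b}

    specs = [
        TaxonSpec("Nematoda", "meiofauna", "volumetric_nematode", nem_const,
                  _frange(0.0, 4.0, 0.25), length_unit_for_formula="um"),
        TaxonSpec("Bdelloidea", "meiofauna", "box_volume", box_const,
                  [0.0, 0.125, 0.25, 0.5], length_unit_for_formula="um"),
        TaxonSpec("Tardigrada", "meiofauna", "box_volume", box_const,
                  [0.125, 0.25, 0.5], length_unit_for_formula="um"),
        TaxonSpec("Dasyhelea", "macrofauna", "power_law", power(0.0025, 2.469),
                  _frange(0.0, 7.0, 0.5), dw_output_unit="mg"),
        TaxonSpec("Metriocnemus", "macrofauna", "power_law", power(0.0018, 2.617),
                  _frange(0.0, 15.0, 0.5), dw_output_unit="mg"),
        TaxonSpec("Muscidae", "macrofauna", "power_law", power(0.0064, 2.457),
                  [0.25] + _frange(0.5, 6.5, 0.5), dw_output_unit="mg"),
        TaxonSpec("Psychoda", "macrofauna", "power_law", power(0.0025, 2.469),
                  _frange(4.0, 5.5, 0.5), dw_output_unit="mg"),
        TaxonSpec("Cheilosia", "macrofauna", "power_law", power(0.0024, 3.0651),
                  [0.25] + _frange(0.5, 6.5, 0.5), dw_output_unit="mg"),
        TaxonSpec("Tabanidae", "macrofauna", "power_law", power(0.005, 2.591),
                  _frange(1.0, 6.5, 0.5), dw_output_unit="mg"),
        TaxonSpec("Scirtidae", "macrofauna", "power_law", power(0.0077, 2.910),
                  _frange(1.0, 23.0, 0.5), dw_output_unit="mg"),
        TaxonSpec("Culex", "macrofauna", "exponential", {"coef": 4.4e3, "rate": 0.8},
                  _frange(1.0, 10.5, 0.5), dw_output_unit="ug"),
        TaxonSpec("Myathropa", "macrofauna", "power_law", power(0.0024, 3.0651),
                  _frange(1.5, 22.0, 0.5), dw_output_unit="mg"),
    ]
    return {s.name: s for s in specs}


def load_taxa(path: str | Path) -> dict[str, TaxonSpec]:
    """Read a YAML taxon configuration (mapping name -> spec fields)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: taxa config must be a mapping")
    specs = {}
    for name, entry in raw.items():
        try:
            specs[name] = TaxonSpec(
                name=name,
                group=entry["group"],
                method=entry["method"],
                constants={k: float(v) for k, v in entry.get("constants", {}).items()},
                size_class_edges=tuple(entry["size_class_edges"]),
                length_unit_for_formula=entry.get("length_unit_for_formula", "mm"),
                dw_output_unit=entry.get("dw_output_unit", "ug"),
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: taxon {name!r} missing field {exc}") from exc
    return specs


def dump_taxa(specs: Mapping[str, TaxonSpec], path: str | Path) -> None:
    out = {
        s.name: {
            "group": s.group,
            "method": s.method,
            "constants": {k: float(v) for k, v in s.constants.items()},
            "size_class_edges": [float(e) for e in s.size_class_edges],
            "length_unit_for_formula": s.length_unit_for_formula,
            "dw_output_unit": s.dw_output_unit,
        }
        for s in specs.values()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)


def _env_from_row(row: pd.Series) -> EnvironmentalRecord:
    kwargs = {}
    for v in ENV_VARIABLES:
        val = row.get(v)
        kwargs[v] = None if val is None or pd.isna(val) else float(val)
    return EnvironmentalRecord(**kwargs)


def read_survey(
    counts_path: str | Path,
    env_path: str | Path,
    taxa: Mapping[str, TaxonSpec],
) -> list[CupSample]:
    """Read count and environment tables into validated :class:`CupSample`.

    The counts table has columns ``site, tree_id, date, taxon, size_class,
    count``; the environment table has the key columns plus the ten
    predictors (and optionally ``bottom_area``). Every cup key in the counts
    table must appear in the environment table; missing environmental cells
    are carried as flagged-missing values, never imputed. Cup order follows
    first appearance in the counts table.
    """
    counts = pd.read_csv(counts_path, dtype={"site": str, "tree_id": str, "date": str})
    env = pd.read_csv(env_path, dtype={"site": str, "tree_id": str, "date": str})

    for col in _KEY_COLS + ["taxon", "size_class", "count"]:
        if col not in counts.columns:
            raise ValidationError(f"{counts_path}: missing column {col!r}")
    for col in _KEY_COLS:
        if col not in env.columns:
            raise ValidationError(f"{env_path}: missing column {col!r}")

    dup = env.duplicated(subset=_KEY_COLS)
    if dup.any():
        key = tuple(env.loc[dup.idxmax(), _KEY_COLS])
        raise ValidationError(f"{env_path}: duplicate cup key {key}")

    env_by_key: dict[tuple[str, str, str], pd.Series] = {
        tuple(r[k] for k in _KEY_COLS): r for _, r in env.iterrows()
    }

    for i, row in counts.iterrows():
        taxon = row["taxon"]
        if taxon not in taxa:
            raise ConfigurationError(f"{counts_path} row {i}: unknown taxon {taxon!r}")
        c = row["count"]
        if pd.isna(c) or float(c) != int(c) or int(c) < 0:
            raise ValidationError(
                f"{counts_path} row {i}: count must be a non-negative integer, got {c!r}"
            )
        if pd.isna(row["size_class"]) or int(row["size_class"]) != row["size_class"]:
            raise ValidationError(f"{counts_path} row {i}: bad size_class {row['size_class']!r}")

    seen_rows: dict[tuple, set[int]] = {}
    cups: dict[tuple[str, str, str], dict[str, np.ndarray]] = {}
    order: list[tuple[str, str, str]] = []
    for i, row in counts.iterrows():
        key = tuple(row[k] for k in _KEY_COLS)
        taxon = row["taxon"]
        spec = taxa[taxon]
        sc = int(row["size_class"])
        if not (0 <= sc < spec.n_classes):
            raise ValidationError(
                f"{counts_path} row {i}: size_class {sc} out of range for {taxon} "
                f"(0..{spec.n_classes - 1})"
            )
        if sc in seen_rows.setdefault((key, taxon), set()):
            raise ValidationError(
                f"{counts_path} row {i}: duplicate (cup, taxon, size_class) entry"
            )
        seen_rows[(key, taxon)].add(sc)
        if key not in cups:
            if key not in env_by_key:
                raise ValidationError(
                    f"{counts_path} row {i}: cup {key} has no environment row"
                )
            cups[key] = {}
            order.append(key)
        cups[key].setdefault(taxon, np.zeros(spec.n_classes, dtype=np.int64))
        cups[key][taxon][sc] = int(row["count"])

    samples = []
    for key in order:
        erow = env_by_key[key]
        area = float(erow.get("bottom_area", DEFAULT_BOTTOM_AREA_CM2))
        if pd.isna(area):
            area = DEFAULT_BOTTOM_AREA_CM2
        sample = CupSample(
            site=key[0], tree_id=key[1], date=key[2],
            counts=cups[key], env=_env_from_row(erow), bottom_area=area,
        )
        sample.validate_against(taxa)
        if sample.env.missing:
            log.info("cup %s has missing env variables: %s", key, sample.env.missing)
        samples.append(sample)
    return samples


def write_survey(
    cups: Sequence[CupSample],
    counts_path: str | Path,
    env_path: str | Path,
) -> None:
    """Write cups back to the two-table format accepted by :func:`read_survey`."""
    crows = []
    erows = []
    for cup in cups:
        for taxon in sorted(cup.counts):
            for sc, n in enumerate(cup.counts[taxon]):
                crows.append(
                    dict(site=cup.site, tree_id=cup.tree_id, date=cup.date,
                         taxon=taxon, size_class=sc, count=int(n))
                )
        erow = dict(site=cup.site, tree_id=cup.tree_id, date=cup.date,
                    bottom_area=cup.bottom_area)
        for v in ENV_VARIABLES:
            erow[v] = getattr(cup.env, v)
        erows.append(erow)
    pd.DataFrame(crows).to_csv(counts_path, index=False)
    pd.DataFrame(erows).to_csv(env_path, index=False)


def write_report(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    float_format: str = "%.6g",
) -> dict[str, Path]:
    """Write a named set of result tables as CSV files under ``path``.

    Returns a manifest mapping table name to the written file. Column order
    is the DataFrame's own (deterministic); table names are written in
    sorted order. An empty table set yields an empty manifest and no files.
    """
    path = Path(path)
    manifest: dict[str, Path] = {}
    if not tables:
        return manifest
    path.mkdir(parents=True, exist_ok=True)
    for name in sorted(tables):
        out = path / f"{name}.csv"
        tables[name].to_csv(out, index=False, float_format=float_format)
        manifest[name] = out
    return manifest
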