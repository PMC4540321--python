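"""Dry-weight allometry and secondary production.

Size-class counts are converted to biomass with one of four length–weight
models, and annual secondary production is estimated from mean biomass,
maximal individual mass and mean annual temperature with the
Plante–Downing multiple regression for lentic invertebrate populations:

    log10 P = 0.06 + 0.79 log10 B − 0.16 log10 M_max + c_T · T

with P and B in g m⁻² (dry weight), M_max in mg and T in °C. The
temperature coefficient defaults to 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ConfigurationError, CupSample, TaxonSpec

__all__ = [
    "dw_volumetric_nematode",
    "dw_box_volume",
    "dw_power_law",
    "dw_exponential",
    "size_class_midpoint",
    "individual_dw_ug",
    "BiomassEstimate",
    "sample_biomass",
    "max_individual_dw_mg",
    "PowerLawFit",
    "fit_power_law",
    "ProductionEstimate",
    "annual_production",
    "community_production",
    "UG_PER_100CM2_TO_G_PER_M2",
]

#: 1 µg per 100 cm² = 100 µg m⁻² = 1e-4 g m⁻².
UG_PER_100CM2_TO_G_PER_M2 = 1e-4

DEFAULT_TEMP_COEFFICIENT = 0.05
DEFAULT_CARBON_FRACTION = 0.5  # g C per g dry weight


def _require_positive(**dims: float) -> None:
    for name, v in dims.items():
        if not (v > 0):
            raise ValueError(f"{name} must be > 0, got {v}")


def dw_volumetric_nematode(length_um: float, width_um: float,
                           dry_wet_ratio: float = 0.25) -> float:
    """Nematode dry weight (µg) from the volumetric formula.

    Wet weight (µg) = width² × length / 1.6e6 with dimensions in µm (the
    divisor embodies the specific gravity of 1.13 g cm⁻³); dry weight
    applies the dry/wet ratio.
    """
    _require_positive(length_um=length_um, width_um=width_um)
    return dry_wet_ratio * width_um ** 2 * length_um / 1.6e6


def dw_box_volume(length_um: float, width_um: float, height_um: float,
                  dry_wet_ratio: float = 0.25) -> float:
    """Rotifer/tardigrade dry weight (µg) from a 0.8·L·W·H box volume.

    The box volume in µm³ is converted at unit density (1e-6 µg per µm³)
    to wet weight, then scaled by the dry/wet ratio.
    """
    _require_positive(length_um=length_um, width_um=width_um, height_um=height_um)
    return dry_wet_ratio * 0.8 * length_um * width_um * height_um * 1e-6


def dw_power_law(length_mm: float, a: float, b: float) -> float:
    """Length–weight power law DW = a·Lᵇ (mg, length in mm)."""
    _require_positive(length_mm=length_mm, a=a)
    return a * length_mm ** b


def dw_exponential(length_mm: float, coef: float = 4.4e3, rate: float = 0.8) -> float:
    """Exponential length–weight model DW = coef·exp(rate·L) (length in mm)."""
    _require_positive(length_mm=length_mm)
    return coef * math.exp(rate * length_mm)


def size_class_midpoint(class_index: int, size_class_edges: Sequence[float]) -> float:
    """Representative length (arithmetic midpoint) of one size class.

    An open-ended first class ("<upper") is encoded with lower edge 0, so
    its midpoint is half the upper edge.
    """
    edges = list(size_class_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"size_class_edges must be strictly increasing: {edges}")
    if not (0 <= class_index < len(edges) - 1):
        raise IndexError(f"class_index {class_index} out of range 0..{len(edges) - 2}")
    return 0.5 * (edges[class_index] + edges[class_index + 1])


def individual_dw_ug(spec: TaxonSpec, class_index: int) -> float:
    """Per-individual dry weight (µg) at the class's representative length."""
    length_mm = size_class_midpoint(class_index, spec.size_class_edges)
    L = length_mm * 1000.0 if spec.length_unit_for_formula == "um" else length_mm
    c = spec.constants
    if spec.method == "volumetric_nematode":
        dw = dw_volumetric_nematode(L, c["width_ratio"] * L, c["dry_wet_ratio"])
    elif spec.method == "box_volume":
        dw = dw_box_volume(L, c["width_ratio"] * L, c["height_ratio"] * L,
                           c["dry_wet_ratio"])
    elif spec.method == "power_law":
        dw = dw_power_law(L, c["a"], c["b"])
    else:
        dw = dw_exponential(L, c["coef"], c["rate"])
    return dw * 1000.0 if spec.dw_output_unit == "mg" else dw


@dataclass(frozen=True)
class BiomassEstimate:
    """Per-taxon dry weight in one cup, with areal normalization."""

    taxon: str
    n_individuals: int
    dw_per_cup_ug: float
    dw_per_100cm2_ug: float


def sample_biomass(cup: CupSample,
                   specs: Mapping[str, TaxonSpec]) -> dict[str, BiomassEstimate]:
    """Dry-weight biomass per taxon for one cup.

    DW per cup is the sum over size classes of count × per-individual DW at
    the class midpoint; the areal value scales by 100/bottom_area.
    """
    out: dict[str, BiomassEstimate] = {}
    for taxon, counts in cup.counts.items():
        if taxon not in specs:
            raise ConfigurationError(f"{cup.key}: no TaxonSpec for {taxon!r}")
        spec = specs[taxon]
        dw = sum(
            int(n) * individual_dw_ug(spec, i) for i, n in enumerate(counts) if n
        )
        out[taxon] = BiomassEstimate(
            taxon=taxon,
            n_individuals=int(counts.sum()),
            dw_per_cup_ug=float(dw),
            dw_per_100cm2_ug=float(dw) * 100.0 / cup.bottom_area,
        )
    return out


def max_individual_dw_mg(cups: Sequence[CupSample], spec: TaxonSpec) -> float:
    """Maximal individual dry mass (mg) of a taxon across a dataset.

    Taken as the per-individual dry weight at the largest size class the
    taxon actually occupies in any cup; raises if the taxon never occurs.
    """
    top = -1
    for cup in cups:
        vec = cup.counts.get(spec.name)
        if vec is not None and vec.sum() > 0:
            top = max(top, int(np.flatnonzero(vec)[-1]))
    if top < 0:
        raise ValueError(f"taxon {spec.name!r} never occurs in the dataset")
    return individual_dw_ug(spec, top) / 1000.0


@dataclass(frozen=True)
class PowerLawFit:
    a: float
    b: float
    r_squared: float


def fit_power_law(lengths_mm: Sequence[float], dws_mg: Sequence[float]) -> PowerLawFit:
    """Fit DW = a·Lᵇ by ordinary least squares on log10–log10 axes.

    This is the standard way length–weight constants are obtained from
    measured specimens (dried larvae of known length).
    """
    L = np.asarray(lengths_mm, dtype=float)
    W = np.asarray(dws_mg, dtype=float)
    if L.shape != W.shape or L.ndim != 1:
        raise ValueError("lengths and dry weights must be equal-length 1-D sequences")
    if len(L) < 3:
        raise ValueError("need at least 3 specimens to fit a power law")
    if np.any(L <= 0) or np.any(W <= 0):
        raise ValueError("lengths and dry weights must all be positive")
    x, y = np.log10(L), np.log10(W)
    b, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return PowerLawFit(a=float(10.0 ** intercept), b=float(b), r_squared=r2)


@dataclass(frozen=True)
class ProductionEstimate:
    """Annual secondary production, dry weight and carbon."""

    p_dw_g_m2: float
    p_carbon_g_m2: float
    carbon_fraction: float


def annual_production(
    biomass_g_m2: float,
    m_max_mg: float,
    temperature_c: float,
    temp_coefficient: float = DEFAULT_TEMP_COEFFICIENT,
    carbon_fraction: float = DEFAULT_CARBON_FRACTION,
) -> ProductionEstimate:
    """Annual production (g m⁻² yr⁻¹) from the Plante–Downing regression.

    Zero biomass short-circuits to zero production; negative biomass is a
    domain error. ``m_max_mg`` is the maximal individual dry mass of the
    taxon in mg.
    """
    if biomass_g_m2 < 0:
        raise ValueError(f"biomass must be >= 0, got {biomass_g_m2}")
    if m_max_mg <= 0:
        raise ValueError(f"m_max_mg must be > 0, got {m_max_mg}")
    if biomass_g_m2 == 0:
        return ProductionEstimate(0.0, 0.0, carbon_fraction)
    log_p = (0.06 + 0.79 * math.log10(biomass_g_m2)
             - 0.16 * math.log10(m_max_mg) + temp_coefficient * temperature_c)
    p = 10.0 ** log_p
    return ProductionEstimate(p, carbon_fraction * p, carbon_fraction)


def community_production(
    inputs: pd.DataFrame,
    temperature_c: float,
    temp_coefficient: float = DEFAULT_TEMP_COEFFICIENT,
    carbon_fraction: float = DEFAULT_CARBON_FRACTION,
) -> pd.DataFrame:
    """Per-taxon and total annual production with percentage shares.

    ``inputs`` needs columns ``taxon``, ``group`` (meiofauna/macrofauna),
    ``biomass_g_m2`` and ``m_max_mg``. Returns per-taxon rows plus summary
    rows ``TOTAL_meiofauna``, ``TOTAL_macrofauna`` and ``TOTAL`` whose
    shares are relative to the community total (per-taxon shares sum to
    100% whenever total production is positive).
    """
    required = {"taxon", "group", "biomass_g_m2", "m_max_mg"}
    missing = required - set(inputs.columns)
    if missing:
        raise ValueError(f"inputs missing columns: {sorted(missing)}")
    rows = []
    for _, r in inputs.iterrows():
        est = annual_production(r["biomass_g_m2"], r["m_max_mg"], temperature_c,
                                temp_coefficient, carbon_fraction)
        rows.append(dict(taxon=r["taxon"], group=r["group"],
                         biomass_g_m2=float(r["biomass_g_m2"]),
                         m_max_mg=float(r["m_max_mg"]),
                         p_dw_g_m2=est.p_dw_g_m2, p_carbon_g_m2=est.p_carbon_g_m2))
    per_taxon = pd.DataFrame(rows)
    total = per_taxon["p_dw_g_m2"].sum()
    per_taxon["share_pct"] = (
        100.0 * per_taxon["p_dw_g_m2"] / total if total > 0 else 0.0
    )
    summaries = []
    for grp in ("meiofauna", "macrofauna"):
        sub = per_taxon[per_taxon["group"] == grp]
        summaries.append(dict(
            taxon=f"TOTAL_{grp}", group=grp,
            biomass_g_m2=sub["biomass_g_m2"].sum(), m_max_mg=np.nan,
            p_dw_g_m2=sub["p_dw_g_m2"].sum(),
            p_carbon_g_m2=sub["p_carbon_g_m2"].sum(),
            share_pct=sub["share_pct"].sum(),
        ))
    summaries.append(dict(
        taxon="TOTAL", group="all",
        biomass_g_m2=per_taxon["biomass_g_m2"].sum(), m_max_mg=np.nan,
        p_dw_g_m2=total, p_carbon_g_m2=per_taxon["p_carbon_g_m2"].sum(),
        share_pct=100.0 if total > 0 else 0.0,
    ))
    return pd.concat([per_taxon, pd.DataFrame(summaries)], ignore_index=True)
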