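"""Community partitioning, areal unit conversion and Kruskal–Wallis tests.

The metazoan community is split into meiofauna (rotifers, nematodes,
tardigrades) and macrofauna (insect larvae); the module computes their
abundance/biomass percentages, dominance ratios, per-taxon occupancy, and
nonparametric tests of a sampling-date effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .biomass import sample_biomass
from .types import CupSample, TaxonSpec, MEIOFAUNA, MACROFAUNA

__all__ = [
    "areal_convert",
    "CommunitySummary",
    "summarize",
    "ratio_larger_to_one",
    "KwResult",
    "kruskal_wallis",
]

# Quantity scale relative to the base unit (µg for mass, individuals for counts).
_QUANTITY = {
    "ug": ("mass", 1.0),
    "mg": ("mass", 1e3),
    "g": ("mass", 1e6),
    "ind": ("count", 1.0),
    "thousand_ind": ("count", 1e3),
    "million_ind": ("count", 1e6),
}
# Area in cm² represented by one unit of the denominator.
_AREA = {"cm2": 1.0, "100cm2": 100.0, "m2": 1e4}


def areal_convert(value: float, from_unit: str, to_unit: str,
                  cup_area_cm2: float = 71.0) -> float:
    """Convert an areal density between unit spellings.

    Units are written ``quantity/area``: quantity in ``ug, mg, g, ind,
    thousand_ind, million_ind``; area in ``cup, cm2, 100cm2, m2``. ``cup``
    uses ``cup_area_cm2`` (default: the 71 cm² cup bottom). Mass and count
    quantities cannot be interconverted. The conversion is exact power-of-10
    (and cup-area) arithmetic, hence invertible.

    >>> areal_convert(100, "ug/100cm2", "mg/m2")
    10.0
    """
    def parse(unit: str) -> tuple[str, float, float]:
        try:
            q, a = unit.split("/")
        except ValueError:
            raise ValueError(f"unit must be 'quantity/area': {unit!r}") from None
        if q not in _QUANTITY:
            raise ValueError(f"unknown quantity unit {q!r} in {unit!r}")
        if a == "cup":
            area = float(cup_area_cm2)
        elif a in _AREA:
            area = _AREA[a]
        else:
            raise ValueError(f"unknown area unit {a!r} in {unit!r}")
        dim, scale = _QUANTITY[q]
        return dim, scale, area

    dim_f, scale_f, area_f = parse(from_unit)
    dim_t, scale_t, area_t = parse(to_unit)
    if dim_f != dim_t:
        raise ValueError(f"cannot convert {dim_f} to {dim_t} ({from_unit} -> {to_unit})")
    # value × scale_f per area_f cm²  →  base units per cm²  →  target spelling
    return value * scale_f / area_f * area_t / scale_t


def ratio_larger_to_one(meio: float, macro: float) -> tuple[float | None, str | None]:
    """Dominance ratio in larger:1 form, with the dominant group's name.

    Returns ``(None, None)`` when either quantity is zero (ratio undefined).
    """
    if meio <= 0 or macro <= 0:
        return None, None
    if meio >= macro:
        return meio / macro, MEIOFAUNA
    return macro / meio, MACROFAUNA


@dataclass(frozen=True)
class CommunitySummary:
    """Meio/macro partition of one group of cups (a scope)."""

    scope: str
    n_cups: int
    meio_abundance: float | None = None   # mean ind per 100 cm²
    macro_abundance: float | None = None
    meio_abundance_sd: float | None = None
    macro_abundance_sd: float | None = None
    meio_biomass: float | None = None     # mean µg per 100 cm²
    macro_biomass: float | None = None
    meio_biomass_sd: float | None = None
    macro_biomass_sd: float | None = None
    meio_pct_abundance: float | None = None  # mean of per-cup percentages
    macro_pct_abundance: float | None = None
    meio_pct_abundance_sd: float | None = None
    ratio_abundance: float | None = None     # larger:1, from group means
    ratio_abundance_dominant: str | None = None
    ratio_biomass: float | None = None
    ratio_biomass_dominant: str | None = None
    occupancy: Mapping[str, float] = field(default_factory=dict)  # % cups present

    @property
    def empty(self) -> bool:
        return self.n_cups == 0


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def summarize(
    cups: Sequence[CupSample],
    specs: Mapping[str, TaxonSpec],
    by: str = "pooled",
) -> CommunitySummary | dict[tuple, CommunitySummary]:
    """Community summaries over cups.

    ``by`` is ``"pooled"`` (one summary), ``"site_date"`` (dict keyed by
    (site, date)) or ``"cup"`` (dict keyed by cup identity). Group means and
    SDs are over cups; dominance ratios are formed from the group means
    (documented basis); percentages are means of per-cup percentages over
    cups with at least one individual. An empty cup set yields a
    flagged-empty summary rather than an error.
    """
    if by == "pooled":
        return _summarize_group("pooled", list(cups), specs)
    if by == "site_date":
        groups: dict[tuple, list[CupSample]] = {}
        for cup in cups:
            groups.setdefault((cup.site, cup.date), []).append(cup)
        return {k: _summarize_group(f"{k[0]}×{k[1]}", v, specs)
                for k, v in groups.items()}
    if by == "cup":
        return {cup.key: _summarize_group(str(cup.key), [cup], specs) for cup in cups}
    raise ValueError(f"unknown grouping {by!r}")


def _summarize_group(scope: str, cups: list[CupSample],
                     specs: Mapping[str, TaxonSpec]) -> CommunitySummary:
    if not cups:
        return CommunitySummary(scope=scope, n_cups=0)
    meio_ab, macro_ab, meio_bm, macro_bm = [], [], [], []
    taxa = sorted({t for cup in cups for t in cup.counts})
    unknown = [t for t in taxa if t not in specs]
    if unknown:
        from .types import ConfigurationError
        raise ConfigurationError(f"no TaxonSpec for taxa: {unknown}")
    present = {t: 0 for t in taxa}
    for cup in cups:
        scale = 100.0 / cup.bottom_area
        ma = sum(int(v.sum()) for t, v in cup.counts.items()
                 if specs[t].group == MEIOFAUNA)
        xa = sum(int(v.sum()) for t, v in cup.counts.items()
                 if specs[t].group == MACROFAUNA)
        meio_ab.append(ma * scale)
        macro_ab.append(xa * scale)
        bm = sample_biomass(cup, specs)
        meio_bm.append(sum(e.dw_per_100cm2_ug for t, e in bm.items()
                           if specs[t].group == MEIOFAUNA))
        macro_bm.append(sum(e.dw_per_100cm2_ug for t, e in bm.items()
                            if specs[t].group == MACROFAUNA))
        for t in taxa:
            if cup.total_count(t) > 0:
                present[t] += 1

    meio_ab = np.array(meio_ab); macro_ab = np.array(macro_ab)
    meio_bm = np.array(meio_bm); macro_bm = np.array(macro_bm)
    total = meio_ab + macro_ab
    occupied = total > 0
    if occupied.any():
        pct = 100.0 * meio_ab[occupied] / total[occupied]
        meio_pct, meio_pct_sd = _mean_sd(pct)
        macro_pct = 100.0 - meio_pct
    else:
        meio_pct = macro_pct = meio_pct_sd = None

    m_ab, s_ab = _mean_sd(meio_ab)
    x_ab, xs_ab = _mean_sd(macro_ab)
    m_bm, s_bm = _mean_sd(meio_bm)
    x_bm, xs_bm = _mean_sd(macro_bm)
    r_ab, r_ab_dom = ratio_larger_to_one(m_ab, x_ab)
    r_bm, r_bm_dom = ratio_larger_to_one(m_bm, x_bm)
    return CommunitySummary(
        scope=scope, n_cups=len(cups),
        meio_abundance=m_ab, macro_abundance=x_ab,
        meio_abundance_sd=s_ab, macro_abundance_sd=xs_ab,
        meio_biomass=m_bm, macro_biomass=x_bm,
        meio_biomass_sd=s_bm, macro_biomass_sd=xs_bm,
        meio_pct_abundance=meio_pct, macro_pct_abundance=macro_pct,
        meio_pct_abundance_sd=meio_pct_sd,
        ratio_abundance=r_ab, ratio_abundance_dominant=r_ab_dom,
        ratio_biomass=r_bm, ratio_biomass_dominant=r_bm_dom,
        occupancy={t: 100.0 * present[t] / len(cups) for t in taxa},
    )


@dataclass(frozen=True)
class KwResult:
    """Kruskal–Wallis test result (tie-corrected H)."""

    h: float
    df: int
    p: float
    method: str  # "chi2" or "exact"


def _kw_h(values: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    """Tie-corrected Kruskal–Wallis H for values with integer group labels."""
    n = len(values)
    ranks = stats.rankdata(values)  # mid-ranks
    h = 0.0
    for g in range(n_groups):
        r = ranks[labels == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - float(np.sum(counts ** 3 - counts)) / (n ** 3 - n)
    if tie == 0.0:
        return 0.0  # all observations identical
    return h / tie


def _exact_kw_p(values: np.ndarray, sizes: Sequence[int], h_obs: float) -> float:
    """P(H >= h_obs) by exhaustive enumeration of group assignments.

    Enumerates every way of distributing the pooled observations over groups
    of the given sizes (the permutation null, exact under exchangeability).
    """
    n = len(values)
    idx = tuple(range(n))
    count = 0
    total = 0
    labels = np.empty(n, dtype=np.int64)

    def recurse(remaining: tuple[int, ...], g: int) -> None:
        nonlocal count, total
        if g == len(sizes) - 1:
            labels[list(remaining)] = g
            h = _kw_h(values, labels, len(sizes))
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for chosen in combinations(remaining, sizes[g]):
            labels[list(chosen)] = g
            rest = tuple(i for i in remaining if i not in chosen)
            recurse(rest, g + 1)

    recurse(idx, 0)
    return count / total


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   exact_threshold: int = 8) -> KwResult:
    """Kruskal–Wallis rank test with mid-rank ties and tie-corrected H.

    The p-value comes from the chi-square approximation with k−1 degrees of
    freedom, or from exact enumeration of all group assignments when the
    pooled sample size is at most ``exact_threshold``. All-identical data
    give H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must contain at least one observation")
    n = sum(len(a) for a in arrays)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    values = np.concatenate(arrays)
    labels = np.concatenate([np.full(len(a), i, dtype=np.int64)
                             for i, a in enumerate(arrays)])
    h = _kw_h(values, labels, len(arrays))
    df = len(arrays) - 1
    if np.ptp(values) == 0:
        return KwResult(h=0.0, df=df, p=1.0, method="degenerate")
    if n <= exact_threshold:
        p = _exact_kw_p(values, [len(a) for a in arrays], h)
        return KwResult(h=float(h), df=df, p=float(p), method="exact")
    p = float(stats.chi2.sf(h, df))
    return KwResult(h=float(h), df=df, p=max(p, np.finfo(float).tiny), method="chi2")
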