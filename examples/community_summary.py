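"""Meiofauna/macrofauna partition, occupancy and seasonal tests.

Summaries report mean areal abundance and biomass per group, the meio:macro
dominance ratio, and per-taxon occupancy (% of cups settled). A
Kruskal–Wallis test per taxon asks whether abundances differ across the
five sampling dates.
"""

import treeholes as th

survey = th.generate_survey(th.default_config(seed=1))
taxa = survey.truth.taxa

s = th.summarize(survey.cups, taxa)
print(f"{s.n_cups} cups — meiofauna {s.meio_pct_abundance:.1f}% "
      f"(± {s.meio_pct_abundance_sd:.1f} SD) of individuals")
print(f"abundance ratio {s.ratio_abundance:,.0f}:1 in favour of "
      f"{s.ratio_abundance_dominant}")
print(f"biomass ratio {s.ratio_biomass:,.1f}:1 in favour of "
      f"{s.ratio_biomass_dominant}")
print("occupancy (% of cups settled):")
for t, occ in sorted(s.occupancy.items(), key=lambda kv: -kv[1]):
    print(f"  {t:<14} {occ:5.1f}%")

print("\nsampling-date effect (Kruskal–Wallis on per-cup densities):")
for taxon in ("Bdelloidea", "Nematoda", "Dasyhelea"):
    groups: dict[str, list[float]] = {}
    for cup in survey.cups:
        groups.setdefault(cup.date, []).append(
            cup.total_count(taxon) * 100 / cup.bottom_area)
    res = th.kruskal_wallis(list(groups.values()))
    print(f"  {taxon:<12} H={res.h:6.1f} df={res.df} p={res.p:.4g} ({res.method})")
# small p → the date (season) shifts that taxon's abundance distribution
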