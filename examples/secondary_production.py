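"""Annual secondary production from mean biomass (Plante–Downing).

log10 P = 0.06 + 0.79·log10 B − 0.16·log10 M_max + 0.05·T, with B the mean
annual biomass (g m⁻² DW), M_max the maximal individual mass (mg, taken
from the largest occupied size class) and T the mean annual temperature.
Production is also expressed as carbon (default 0.5 g C per g DW).
"""

import numpy as np
import pandas as pd

import treeholes as th
from treeholes.biomass import UG_PER_100CM2_TO_G_PER_M2

T_MEAN_ANNUAL = 10.1  # °C

survey = th.generate_survey(th.default_config(seed=1))
taxa = survey.truth.taxa

# mean biomass per taxon over all cups, converted to g m⁻²
acc: dict[str, list[float]] = {t: [] for t in taxa}
for cup in survey.cups:
    for est in th.sample_biomass(cup, taxa).values():
        acc[est.taxon].append(est.dw_per_100cm2_ug)
inputs = pd.DataFrame([
    dict(taxon=t, group=taxa[t].group,
         biomass_g_m2=np.mean(acc[t]) * UG_PER_100CM2_TO_G_PER_M2,
         m_max_mg=th.max_individual_dw_mg(survey.cups, taxa[t]))
    for t in taxa if sum(acc[t]) > 0
])

table = th.community_production(inputs, T_MEAN_ANNUAL)
cols = ["taxon", "group", "biomass_g_m2", "p_dw_g_m2", "p_carbon_g_m2", "share_pct"]
print(table[cols].round(4).to_string(index=False))

tot = table.set_index("taxon")
meio = tot.loc["TOTAL_meiofauna", "p_carbon_g_m2"]
macro = tot.loc["TOTAL_macrofauna", "p_carbon_g_m2"]
ratio, dominant = th.ratio_larger_to_one(meio, macro)
print(f"\nannual production: meiofauna {meio:.3f}, macrofauna {macro:.3f} g C m⁻²"
      f" → ratio {ratio:.1f}:1 in favour of {dominant}")
print("share_pct is each taxon's percentage of total dry-weight production.")
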