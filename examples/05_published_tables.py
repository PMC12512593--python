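"""Gap arithmetic on the shipped published city summary tables.

The package ships the published population-weighted exposure summaries for
Aarhus and Paris as fixture CSVs.  This script recomputes the equity-gap
statistics from those tables: the income-quintile gap before and after
greening, and the widest baseline subgroup spread per city.
"""

import greenequity as ge

for city in ("aarhus", "paris"):
    table = ge.published_table(city)
    rep = ge.gaps(table)
    print(f"{city}:")
    print(f"  income gap (top vs bottom quintile): "
          f"{rep.income.baseline_gap:.2f} -> {rep.income.scenario_gap:.2f} ug/m3 "
          f"({rep.income.direction})")
    print(f"  widest baseline subgroup spread: {rep.max_baseline_range:.2f} ug/m3")
    print(f"  most / least benefited income group: "
          f"{rep.categories['income'].most_benefited} / {rep.categories['income'].least_benefited}")
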