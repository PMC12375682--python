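"""Suitable-area accounting on the published annual series for Akagera
National Park (2015-2023).

Run:  python examples/area_change_accounting.py
"""

from sdmpipe.experiments import akagera_area_summary

summ = akagera_area_summary()
print(summ.table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nmaximum annual share: {summ.max_percent:.2f}% of the park "
      f"({summ.total_km2:.0f} km2) in {summ.max_percent_year}, "
      f"i.e. {summ.rounded_max_percent()}% to the nearest whole percent")
# annual_change_km2 is the first difference of the suitable area; the
# rounded maximum share is the series' headline invasion-extent figure.
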