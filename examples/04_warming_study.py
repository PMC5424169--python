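"""A small eco-evolutionary warming study, end to end.

Generates a 12 x 12 alpine landscape, initializes locally adapted
populations in the niche-model presence mask, burns them in under a
frozen climate, then forces a severe warming trajectory (2010-2090,
constant afterwards) and prints the range and adaptation summaries.
"""

from evorange import recorders
from evorange.study import run_study

result = run_study(seed=1, n_replicates=1, severity="severe",
                   grid_shape=(12, 12), burn_in_years=150)
print("burn-in:", {k: round(v, 2) if isinstance(v, float) else v
                   for k, v in result.burnin_diagnostics.items()})

rec = result.records[0]
occ = recorders.occupancy_series(rec)
surv = recorders.adaptive_seedling_survival(rec)
ages = recorders.age_structure(rec)
print(f"\n{'year':>5} {'occupied':>9} {'SENM mask':>9} {'seedling surv':>14} "
      f"{'pre-adult freq':>15}")
for year in occ.index:
    senm = result.senm_occupancy.get(min(year, 2090), float("nan"))
    print(f"{year:>5} {occ.get(year, 0):>9} {senm:>9} "
          f"{surv.get(year, float('nan')):>14.3f} "
          f"{ages.loc[year, 'pre_adult']:>15.3f}")
print("\nReading: occupancy expands by colonization while the static mask")
print("contracts at once; seedling adaptive survival collapses under")
print("warming and rebounds after 2090 (evolutionary rescue), while")
print("occupied cells keep being lost for decades (extinction debt).")
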