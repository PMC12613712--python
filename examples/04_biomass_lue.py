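"""Total dry matter, fruit partitioning and light-use efficiency.

TDM per destructive sampling = standing organs + harvested-fruit and
trimmed-leaf ledgers.  LUE is the through-origin slope of
(TDM - initial dry weight) on cumulative intercepted PAR.
"""

from cucurgrow import (
    analyze_trial,
    generate_climate,
    generate_trial,
    packaged_scenarios,
)

climate = generate_climate(seed=42)
scens = packaged_scenarios()
a = analyze_trial(generate_trial(scens["s30"], climate))

tdm228 = a.records.loc[a.records["dat"] == 228, "tdm_area"].mean()
print("s30: TDM at 228 DAT = %.0f g/m2" % tdm228)
print("     LUE = %.2f g/MJ (95%% CI %.2f-%.2f)"
      % (a.lue.slope, a.lue.ci_low, a.lue.ci_high))
print("\nfruit fraction of new DM per term:")
for row in a.partition.itertuples():
    print(f"  term {row.term} ({row.start}-{row.end} DAT): {row.fraction:.2f} g/g")
print("cumulative fruit DM / TDM at 228 DAT: %.3f g/g"
      % a.cum_fraction["fraction"].iloc[-1])
print("\nA fraction near 0.5 means half of each interval's new dry matter")
print("went into fruit; the cumulative value is the season-long share.")
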