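"""National budget impact of changing molecular-diagnostic practice.

Loads the packaged Dutch model (old 2012 / current 2015 / future 2020
practice for stage-IV NSCLC and melanoma, peripheral vs specialised care)
and prints per-patient and population costs per frame plus the frame-to-
frame budget impacts.
"""

from panelcost import load_bia_inputs, round_half_away

inputs = load_bia_inputs("netherlands")

print("cost per patient (population) per frame:")
for timeframe in ("old_2012", "current_2015", "future_2020"):
    row = []
    for indication in ("nsclc", "melanoma"):
        pp = round_half_away(inputs.cost_per_patient(timeframe, indication))
        pop = round_half_away(inputs.population_cost(timeframe, indication))
        row.append(f"{indication}: EUR {pp} (EUR {pop:,})")
    print(f"  {timeframe:13s} " + " | ".join(row))

print("\nbudget impact (positive = cost increase):")
for a, b in (("old_2012", "current_2015"), ("current_2015", "future_2020")):
    for indication in ("nsclc", "melanoma"):
        impact = inputs.budget_impact(a, b, indication)
        print(f"  {indication:9s} {a} -> {b}: EUR {impact.per_patient_rounded:+d}"
              f"/patient, EUR {impact.population_rounded:+,d}/year")

print("\nThe 2015 cost rise is driven by the extra single-gene tests still")
print("needed beside the small panel; by 2020 WGS in specialised care and")
print("panel testing in peripheral care change the balance per indication.")
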