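"""One-way sensitivity of the future budget impact to prices and referral share.

Varies the small-panel price, the WGS price and the specialised-care share
by +/-20% — in the future (2020) frame only — and prints the tornado-ordered
outcome ranges for both indications.
"""

from panelcost import default_future_params, future_bia_model, load_bia_inputs, tornado

inputs = load_bia_inputs("netherlands")

for indication in ("nsclc", "melanoma"):
    base = inputs.budget_impact("current_2015", "future_2020", indication)
    print(f"{indication}: base budget impact EUR {base.population_rounded:+,d}/year")
    entries = tornado(
        future_bia_model(inputs, indication),
        default_future_params(inputs, indication, rel_range=0.2),
    )
    for e in entries:
        print(f"  {e.name:18s} [{e.outcome_at_low:+12,.0f} .. "
              f"{e.outcome_at_high:+12,.0f}]  width {e.width:10,.0f}")
    print()

print("Bars are sorted widest first: the panel price dominates the NSCLC")
print("impact, the WGS price the melanoma impact.")
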