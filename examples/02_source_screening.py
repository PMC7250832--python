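"""Screening every exchange metabolite as a candidate C / N / C+N source.

The candidate uptake is opened to -10 mmol/gDW/h while all remaining
minimal-medium nutrients are allowed up to -30, so only the tested
source can limit growth; for the carbon role the default carbon source
is removed, for nitrogen the ammonium is omitted.
"""

from gemflux import make_toy_model, screen_sources, toy_minimal_medium

model = make_toy_model()
medium = toy_minimal_medium(carbon="EX_hb3_e")

for role in ("C", "N", "CN"):
    print(f"\nrole = {role}")
    for res in screen_sources(model, medium, role=role):
        mark = "+" if res.grows else "-"
        extra = (f"  growth/C = {res.growth_per_carbon:.4f}"
                 if res.growth_per_carbon else "")
        print(f"  {mark} {res.exchange_id:<12} mu = {res.growth_rate:.4f}{extra}")

print("\n'+' = predicted growth. Note glucose fails: its exchange exists "
      "but no transporter is annotated, mirroring how a missing transport "
      "reaction shows up in a curated genome-scale model.")
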