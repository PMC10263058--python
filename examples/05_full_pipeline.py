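"""The full inference chain: generated study files -> community role model.

Generates the ten-genome synthetic community, runs annotation parsing, hit
filtering, pathway presence, etfAB analysis, substrate and role inference,
and prints the community report joining roles with abundance periods.
"""

import tempfile

from lactoferm import run_pipeline
from lactoferm.synthetic_data import default_scenario, generate

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate(default_scenario(seed=42), tmp)
    result = run_pipeline(bundle.outdir)

print("inferred roles and substrates:")
for genome, role in sorted(result.roles.items()):
    sub = result.substrates[genome]
    substrate = sub.substrate or "-"
    notes = f"  [{'; '.join(role.notes)}]" if role.notes else ""
    print(f"  {genome:8s} {','.join(sorted(role.roles)) or '(none)':55s} "
          f"substrate: {substrate}{notes}")

print("\ncommunity report (roles x abundance periods):")
print(result.report.to_string(index=False, float_format="%.1f"))

print("\nThe three chain elongators are separated by their substrates —")
print("lactose (carbohydrate route), lactic acid (LacT/ecLDH/lactate-EtfAB)")
print("and putatively ethanol (ADA+ADH only) — and each genome's abundance")
print("peaks in the operational period consistent with its role.")
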