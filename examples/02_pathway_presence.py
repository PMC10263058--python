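"""Pathway presence calling on a hand-built genome annotation set.

Annotates a toy genome with the Leloir-pathway enzymes plus β-galactosidase
and asks which lactose routes are complete.
"""

from lactoferm import GeneAnnotation, default_network
from lactoferm.pathway_presence import call_pathway, call_step

net = default_network()

ECS = ["3.2.1.23", "5.1.3.3", "2.7.1.6", "2.7.7.12", "5.1.3.2"]  # BGS + Leloir
genes = [
    GeneAnnotation("toy", "c1", 100 + 1200 * i, 1000 + 1200 * i, "+",
                   f"toy_{i:03d}", ec_numbers=frozenset({ec}))
    for i, ec in enumerate(ECS)
]

calls = {sid: call_step(genes, step, genome_id="toy") for sid, step in net.steps.items()}
for pid in ("leloir", "tagatose6p", "emp_glycolysis"):
    pc = call_pathway(calls, net.pathways[pid], "toy")
    missing = ",".join(pc.missing_steps) or "-"
    print(f"{pid:15s} {pc.status:13s} missing: {missing}")

print("\nThe Leloir route is complete, so this genome can catabolise the")
print("galactose moiety of lactose; the tagatose-6P alternative is absent.")
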