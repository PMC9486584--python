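"""Full pipeline: synthetic multi-omics cohort to ranked drug table.

Generates a two-condition dataset with three layers and perturbed
correlation blocks, runs correlation -> reduction -> multi-layer assembly ->
path integration -> differential network -> drug ranking, and traces the
top drug's score back to its targets.
"""

from dimona import FixtureSpec, explain_drug, generate_all, run_pipeline

spec = FixtureSpec(
    layers=(("mrna", 90), ("protein", 90), ("phosphosite", 90)),
    n_samples=40,
    n_blocks=9,
    perturbed_blocks=(0, 1, 2),
    n_drugs=20,
    frac_differential=0.4,
    seed=5,
)
omics, targets, sens, is_differential = generate_all(spec)

result = run_pipeline(omics, targets)
print(f"differential network: {result.differential.n_edges} edges "
      f"({result.condition_a} minus {result.condition_b})")

top = result.ranking.head(8).copy()
top["planted_differential"] = top["drug_id"].map(is_differential)
print("\ntop of the drug ranking (score = |mean differential| over "
      "target-incident edges):")
print(top.to_string(index=False))

best = top.iloc[0]["drug_id"]
record = explain_drug(
    result.differential,
    result.integrated[result.condition_a],
    result.integrated[result.condition_b],
    best,
    targets,
)
print(f"\nper-target trace for {best}:")
print(record["summary"].to_string(index=False))
print("-> drugs whose targets sit in perturbed correlation blocks should "
      "carry the 'planted_differential' flag and rank near the top.")
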