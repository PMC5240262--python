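"""Score a small drug cohort under the base-case scenario and rank it.

Loads the packaged illustrative six-drug cohort (synthetic values), computes
each drug's weighted aggregate score under equal criterion weights, and
prints the competition ranking. The weighted score lives on the same [1, 3]
scale as the individual criterion scores; the raw sum is its unweighted
counterpart on [9, 27].
"""

from importlib import resources

from orphanmcda import aggregate_score, builtin_scenarios, default_framework, rank_drugs
from orphanmcda.io import read_profiles

framework = default_framework()
with resources.as_file(
    resources.files("orphanmcda.data").joinpath("example_cohort_synthetic.csv")
) as path:
    profiles = read_profiles(path, framework)

base_case = builtin_scenarios()[0]
results = [aggregate_score(p, base_case) for p in profiles]
ranking = rank_drugs(results)

print(f"{base_case.name}: equal weights of 1/9 per criterion")
print(f"{'rank':>4}  {'drug':<10}  {'weighted':>8}  {'raw sum':>7}")
for rank, drug_id, score in ranking.entries:
    raw = next(r.raw_sum for r in results if r.drug_id == drug_id)
    print(f"{rank:>4}  {drug_id:<10}  {score:>8.3f}  {raw:>7}")
print("\nA weighted score of 3.0 would mean the top level on every criterion.")
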