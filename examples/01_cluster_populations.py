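"""Cluster predefined population samples with the Dirichlet-multinomial model.

Simulates a five-population polytomy with clear differentiation,
searches for the best partition, and prints its posterior support.
"""

import lineagesort as ls

spec = ls.polytomy_scenario(
    n_pops=5, n_per_pop=30, n_loci=80, theta=1.0, divergence_time=0.15
)
ds = ls.simulate_dataset(spec, seed=1)
counts = ls.allele_counts(ds)

result = ls.search_best_partition(counts, n_runs=3, seed=2)

print(f"populations: {ds.pop_labels}")
print(f"best partition: {result.best}")
print(f"log marginal likelihood: {result.log_ml:.2f} nats")
print(f"posterior probability:   {result.posterior_prob:.4f} ({result.pp_mode})")
# With F_ST well above 0.1, the search recovers all five populations as
# separate clusters and the posterior concentrates on that partition.
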