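# Demo pipeline: seeded synthetic survey (50 clusters x 6 households x 3
# adults) -> pattern table -> three separate fits + ICCs -> joint full and
# restricted fits -> 6-df cross-covariance LRT -> comparison table.
# Run:  jointlogit run --config examples/pipeline_demo.yaml
output_dir: demo_out
quad_nodes: 3
alpha: 0.05
seed: 7
simulate:
  n_clusters: 50
  households_per_cluster: 6
  individuals_per_household: 3
  beta:
    - [-1.8, 0.5]
    - [1.2, -0.4]
    - [0.2, 0.6]
  sigma_c:
    - [0.394, 0.2094, 0.2316]
    - [0.2094, 0.696, 0.3079]
    - [0.2316, 0.3079, 0.851]
  sigma_h:
    - [0.385, 0.1020, 0.0931]
    - [0.1020, 0.300, 0.0822]
    - [0.0931, 0.0822, 0.250]
  covariates:
    - {name: elec, kind: binary, level: household, prevalence: 0.3}
  missing_rate: 0.05
  seed: 7
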