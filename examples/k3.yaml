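# Fit the complete 3-node network to synthetic pulse data.
# Generate the dataset first:  ptlasso gen-data --fixture k3 --seed 1 --out examples/
network: k3_network.yaml
datasets: [k3.tsv]
parameter_space:
  bounds: [-12, 3]
  prior: {type: laplace, mu: -10, b: 1}
sampler:
  n_chains: 6
  n_mcmc: 25
  n_swaps: 1000
  burn_in_swaps: 200
  init_threshold: 1000
  seed: 1
reduction:
  c: 3.0
  mass_threshold: 0.95
output: k3_run
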