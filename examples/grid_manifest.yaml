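# Manifest for `ligandshell grid --config examples/grid_manifest.yaml --out out/`
# A reduced pilot: two compositions, one trial per initial morphology,
# short budget.  Scale proposals/trials up toward full_grid.py for
# production statistics.
x_values: [0.3, 0.5]
trials_per_composition: 3
proposals: 20000
snapshot_interval: 2000
keep_snapshots: 10
n_fragment_samples: 20000
n_janus_reference: 10
seed: 0
paper_mode: true
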