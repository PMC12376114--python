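"""The full study grid: 9 compositions x 18 trials x 3 initial morphologies.

This is the production configuration behind the composition-resolved SSR,
Janus-character and patch-size results.  It is an overnight-scale
computation (hundreds of millions of energy evaluations); run it on a
workstation, not as part of the test suite.  Reduce `proposals`,
`trials_per_composition` or `x_values` for a faster pilot.

Per composition the runner reports the mean +/- SD SSR over the final ten
snapshots of all trials, the Janus character against a 50-configuration
perfect-Janus reference, and box statistics of the number-weighted patch
sizes; everything lands as CSV under `out_root`.
"""

from ligandshell import ExperimentGrid, report, run_grid

grid = ExperimentGrid(
    x_values=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    trials_per_composition=18,       # 6 each: random, striped, janus
    proposals=2_000_000,             # budget per trial; plateau-check output
    snapshot_interval=10_000,
    keep_snapshots=10,               # final 10 configurations analysed
    n_fragment_samples=50_000,
    n_janus_reference=50,
    seed=0,
    out_root="scratch/full_grid",
)

if __name__ == "__main__":
    result = run_grid(grid, progress=True)
    tables = report(result)
    print(tables["ssr"])
    print(tables["janus_character"])
    print(tables["patches"].head(20))
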