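"""A short configurational-bias Monte Carlo equilibration.

Runs a reduced monolayer (x_PEG = 0.5 at full coverage on a small two-shell
test core) for 10,000 proposals and reports move acceptance, the energy
trend, and how the fragment-distribution SSR responds.  Production runs use
the full 2.8 nm core and much larger budgets (see full_grid.py).
"""

import numpy as np

from ligandshell import (CBMCEngine, MoveSet, ParameterSet, binomial_reference,
                         build_mackay_core, detect_equilibration, init_janus,
                         make_plan, sample_fragment_distribution, ssr,
                         surface_fraction, trim_outer_layers)

core = trim_outer_layers(build_mackay_core(2), 2)
params = ParameterSet.default()
plan = make_plan(0.5, core=core, paper_mode=False)
cfg = init_janus(plan, core, params, seed=3)

engine = CBMCEngine(cfg, MoveSet(), seed=4)
before = sample_fragment_distribution(cfg, 20_000, seed=5)
ssr_before = ssr(before, binomial_reference(surface_fraction(before))).ssr

record, trajectory = engine.run(10_000, snapshot_interval=2_000,
                                energy_log_interval=100)

after = sample_fragment_distribution(cfg, 20_000, seed=5)
ssr_after = ssr(after, binomial_reference(surface_fraction(after))).ssr

print(f"system: {plan.l_total} ligands on {len(core.anchor_sites)} sites")
for move in record.proposal_counts:
    print(f"  {move:12s} acceptance {record.acceptance_rate(move):6.3f} "
          f"({record.accept_counts[move]}/{record.proposal_counts[move]})")
e = np.array(record.energy_series)
print(f"energy: {e[0, 1]:.1f} -> {e[-1, 1]:.1f} kcal/mol "
      f"(bookkeeping drift at snapshots: {record.energy_check_max_abs:.1e})")
plateau = detect_equilibration(e, window=25)
print(f"plateau detected at logged step: {plateau}")
print(f"SSR: {ssr_before:.3f} (perfect Janus start) -> {ssr_after:.3f}")
print("A falling SSR means the two-faced start is relaxing toward the")
print("equilibrium degree of mixing at this temperature and composition.")
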