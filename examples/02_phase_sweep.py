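"""Small phase sweep: which structure evolves where in the (d_c, d_m) plane.

Repeats the simulation a few times per condition and tabulates the
frequencies of the emergent kinship structures.  Large d_c/d_m favours a
single endogamous clan; increasing d_m relative to d_c pushes toward
bride-exchange structures with more clans.  (Desk-scale: 5 trials and a
reduced system; increase n_trials/N for production figures.)
"""

from kinsim import ModelParams
from kinsim.experiments import cells_to_frame, run_phase_sweep

base = ModelParams(N_s=20, N_f=30, n_steps=300)
grid = [(5.0, 0.1), (0.3, 0.2), (0.5, 1.0)]
cells = run_phase_sweep(grid, base, n_trials=5, base_seed=0)
df = cells_to_frame(cells)
cols = ["d_c", "d_m", "modal", "count_clan_endogamy", "count_dual_organization",
        "count_generalized_exchange", "count_restricted_exchange", "count_other"]
print(df[cols].to_string(index=False))
# 'modal' is the structure a phase diagram would plot for each condition.
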