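"""Estimate cooperation/competition pressures from an ethnographic table.

Builds a synthetic cross-cultural table (150 societies, ten indicator
variables loading on latent d_c or d_m, noise, 10% missing cells),
z-scores the variables, averages them into per-society estimates
(dc_tilde, dm_tilde), and checks that societies labelled with
bride-exchange structures order by the estimated pressure ratio.
"""

from scipy.stats import pearsonr

from kinsim import (empirical_phase_table, estimate_dc_dm, make_sccs_table,
                    normalize_variables, spearman_pair_correlations)

table, latent = make_sccs_table(150, noise_sd=0.5, seed=0)
norm = normalize_variables(table)
est = estimate_dc_dm(norm)

ok = est["dc_tilde"].notna()
r = pearsonr(est.loc[ok, "dc_tilde"], latent.loc[ok, "d_c"]).statistic
print(f"recovery of latent d_c: Pearson r = {r:.3f} (n={ok.sum()})")

_, summary = empirical_phase_table(est, table["structure"])
print(summary.round(3).to_string(index=False))
# median_ratio = median dm_tilde/dc_tilde per structure: it should rise
# from dual organization through generalized to restricted exchange.

corr = spearman_pair_correlations(norm)
print("top structure-separating variables:")
print(corr.head(4).round(3).to_string(index=False))
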