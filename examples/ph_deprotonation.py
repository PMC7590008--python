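"""Fit the partial-deprotonation pH model to a (c, pH) titration table.

Above the solubility, aggregating peptides release a proton with
probability f, so pH = −log10[(c − c_s)·f] with concentrations in mol/L;
below c_s the solution stays at the solvent pH.
"""

import numpy as np

import itcdissolve as itc

truth = itc.PhModelParams(c_s_mM=2.0, f=0.4, pH_solvent=6.3)
rng = np.random.default_rng(8)
c = np.array([0.5, 1.0, 2.5, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0])
ph = itc.ph_model(c, truth) + 0.05 * rng.standard_normal(c.size)

fit, diag = itc.fit_ph_deprotonation(np.column_stack([c, ph]), pH_solvent=6.3)
print(f"c_s = {fit.c_s_mM:.2f} mM (truth 2.0), f = {fit.f:.2f} (truth 0.4), "
      f"points used: {diag['n_used']}")
print(f"model pH at c = 4.5 mM: {itc.ph_model(4.5, fit):.2f}")
# f < 1 means only a fraction of the aggregated peptides deprotonate --
# the aggregate behaves like an acid soap, not a fully ionised acid.
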