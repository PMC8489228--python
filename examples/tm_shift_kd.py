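"""Estimate Kd directly from the ligand dependence of the melting temperature.

Uses the same synthetic titration as the isothermal example, but skips the
isothermal step: assuming free ligand = total ligand, the observed melting
temperature satisfies Ku(Tm_obs) = 1 + Ltot/Kd, which links the Tm shift at
each concentration to the affinity.  Simpler than the isothermal route, at
the price of the free-ligand approximation; the two estimates typically
agree within a factor of two.
"""

import numpy as np

from thermoquant.isothermal import fit_tm_shift, fluorescence_fit
from thermoquant.preprocess import restrict_range
from thermoquant.synthetic import LigandSeriesScenario, gen_ligand_series

scenario = LigandSeriesScenario(seed=42)   # truth: Kd = 2 uM
mcs = restrict_range(gen_ligand_series(scenario), 303.15, 329.15)

ds = fluorescence_fit(mcs, mode="local", ptot_M=scenario.ptot_M)
i0 = int(np.argmin(ds.ligand_conc_M))
print(f"free-protein reference: Tm0 = {ds.tm_obs[i0]:.2f} K, "
      f"dHu = {ds.dH_obs[i0] / 1e3:.0f} kJ/mol")
print(f"largest shift: +{ds.tm_obs.max() - ds.tm_obs[i0]:.2f} K "
      f"at {ds.ligand_conc_M.max() * 1e6:.0f} uM ligand")

fit = fit_tm_shift(ds.ligand_conc_M, ds.tm_obs,
                   dHu=float(ds.dH_obs[i0]), tm0_K=float(ds.tm_obs[i0]))
kd, lo, hi = fit.derived["Kd_M"]
print(f"\nTm-shift fit:    Kd = {kd * 1e6:.2f} uM  "
      f"(95% CI {lo * 1e6:.2f} - {hi * 1e6:.2f} uM)")
print(f"generator truth: Kd = {scenario.kd_M * 1e6:.2f} uM")
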