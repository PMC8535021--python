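"""Reproduce the full synthetic study design and its statistical report.

18 providers each ventilate the manikin in a short (S1, ~30 s) and a long
(S4, ~90 s) scenario; each episode gets a duration-matched (±15%) newborn
episode. The report compares the four groups (MS/BS/ML/BL) with median/IQR
tables, panel random-effects tests, dynamical correlations and an
obstruction chi-square. Outputs land in ./venticomp_run/.
"""

import logging

from venticomp import RunConfig, run_full_study

logging.basicConfig(level=logging.INFO, format="%(message)s")

result = run_full_study(RunConfig(seed=1, n_bootstrap=1000,
                                  out_dir="venticomp_run"))

print("\nGroup sizes:", result.groups.sizes())
print("\nMedian (IQR) per group:")
t1 = result.table1.pivot_table(index=["group", "duration_class"],
                               columns="parameter", values="median")
print(t1.round(2).to_string())

print("\nDynamical correlation leak~eV_T per group:")
t2 = result.table2[result.table2.pair == "leak-ev_t"]
for _, row in t2.iterrows():
    print(f"  {row.group}: rho = {row.dyn_rho:+.2f} "
          f"(95% CI {row.ci_low:+.2f} to {row.ci_high:+.2f}), "
          f"p = {row.p_value:.3f}, Pearson r = {row.pearson_r:+.2f}")

o = result.obstruction
print(f"\nObstruction: {o['n_obstructed_manikin']}/{o['n_manikin']} manikin "
      f"vs {o['n_obstructed_baby']}/{o['n_baby']} baby sequences, "
      f"chi-square {o['chi_square']:.2f}, p = {o['p_value']:.2f}")
print("\nA strong negative leak~eV_T correlation in every group, comparable")
print("pressures/volumes with larger dispersion in the newborn groups, and")
print("no group difference in obstruction mirror what bedside comparisons")
print("of this manikin against real newborn ventilation report.")
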