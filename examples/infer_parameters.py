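"""Infer selection and co-segregation from observed summary statistics.

Runs a small ABC-SMC inference against the reported GBM39-KT targets
(C = 0.67, rho = 0.36).  Desk-scale settings (20,000-cell simulations,
200 particles) keep this a few minutes; the analysis-scale equivalent
uses 500,000-cell simulations.
"""

from ecdna import ABCConfig, ObservedStats, credible_interval, run_abc_smc

obs = ObservedStats.cell_line("GBM39-KT")
config = ABCConfig(n_particles=200, sim_cells=20_000, epsilon_target=0.05)

posterior = run_abc_smc(obs, config, seed=1, verbose=True)

print()
print(f"converged: {posterior.converged} "
      f"(achieved tolerance {posterior.achieved_tolerance:.3f}, "
      f"{posterior.n_simulations} simulations)")
print("posterior means:")
print(posterior.mean().round(3).to_string())
print("95% credible intervals:")
print(credible_interval(posterior).round(3).to_string())
print()
print("s_indiv is selection on cells carrying a single species, s_coselect")
print("the extra advantage of carrying both, gamma the co-segregation level")
print("(0 = independent mitotic segregation, 1 = fully coupled).")
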