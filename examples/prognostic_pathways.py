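"""Find prognostic pathways by an optimal-cutoff log-rank survival scan.

Simulates a tumor cohort in which one pathway's activation drives the death
hazard (hazard ratio 4 per activation standard deviation), scores every
patient by ssGSEA, scans every observed activation score as a stratification
cutoff and reports pathways whose best split separates survival at
p < 0.001.
"""

import cdp

cfg = cdp.SimulationConfig(
    n_genes=400, n_sets=6, set_size_range=(20, 35), n_cancers=1,
    n_case=150, n_control=5, planted_up={"SET_000": 2.0},
    hazard_ratio=4.0, censoring_rate=0.2, n_drugs=1, seed=3,
)
sets, cohorts, clinical, _ = cdp.simulate_study(cfg)
hits = cdp.prognostic_screen(cohorts, sets, clinical, p_threshold=0.001)

print("prognostic pathways (best log-rank p < 0.001):\n")
print(f"{'pathway':10s} {'cancer':10s} {'p':>10s} {'direction':>10s} {'split':>9s}")
for h in hits:
    print(f"{h.pathway:10s} {h.cancer:10s} {h.p:10.2e} {h.direction:>10s} "
          f"{h.n_high:4d}/{h.n_low}")
print(
    "\nSET_000 drives the hazard upward, so high activation predicts shorter"
    "\nsurvival: it is detected with direction 'adverse'. Unplanted pathways"
    "\nshould not reach p < 0.001."
)
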