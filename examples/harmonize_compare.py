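"""Apply all three correction methods and compare residual batch effects.

A kBET rejection rate near 0 and a mean |silhouette| near 0 mean the two
scanners' subjects are locally well mixed; values near 1 mean the batches
are cleanly separable.
"""

import radharmon as rh

features, _, truth = rh.generate_cohort(rh.SimulationConfig(seed=1))
ph1, ph2 = rh.generate_phantom_pair(truth)

corrected = {
    "uncorrected": features,
    "phantom": rh.phantom_correct(features, phantom_ref=ph2, phantom_other=ph1,
                                  reference_batch=2).corrected,
    "combat-global": rh.combat(features, mode="global").corrected,
    "combat-ref2": rh.combat(features, mode="reference",
                             reference_batch=2).corrected,
    "linear": rh.linear_batch_remove(features).corrected,
}

print(f"{'method':<14} {'kBET rate':>9} {'mean |s|':>9}")
for name, mat in corrected.items():
    kb = rh.kbet(mat, k=10, n_repeats=1000, seed=7)
    sil = rh.silhouette(mat)
    print(f"{name:<14} {kb.rejection_rate:>9.3f} {sil.mean_abs_s:>9.4f}")
print("\nphantom correction only undoes the multiplicative scanner component;"
      "\nthe statistical methods also remove the location shift, so their"
      "\ndiagnostics drop to near zero.")
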