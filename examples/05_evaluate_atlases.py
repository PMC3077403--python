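"""Why age-matched atlases matter: run the three evaluation experiments
(spatial normalisation, cross-age label consistency, prior-guided
neonatal segmentation) comparing the age-matched bundles against an
age-mismatched control on a held-out cohort."""

from infatlas.pipeline import run_comparative_experiments

res = run_comparative_experiments(seed=1)

print("Experiment 1 - spatial normalisation (mean Dice vs voted structure):")
print(f"  age-matched atlas : {res['exp1_matched']:.3f}")
print(f"  age-2 atlas       : {res['exp1_mismatched']:.3f}")
print("Experiment 2 - cross-age label consistency (mean Dice over labels):")
print(f"  age-matched atlases: {res['exp2_matched']:.3f}")
print(f"  fixed age-2 atlas  : {res['exp2_mismatched']:.3f}")
print(f"  per pair: " + ", ".join(f"{k}={v:.3f}"
                                  for k, v in res["exp2_pairs"].items()))
print("Experiment 3 - neonatal segmentation guided by warped TPMs:")
print(f"  age-0 TPMs: {res['exp3_matched']:.3f}")
print(f"  age-2 TPMs: {res['exp3_mismatched']:.3f}")
# Expected pattern: the age-matched atlas wins every experiment, and the
# 1-vs-2 pair shows the highest cross-age consistency because those two
# anatomies are most similar — using a mature atlas on neonates is
# particularly damaging for tissue priors (experiment 3).
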