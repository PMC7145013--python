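"""Eligibility, ICD-10 VTE classification, propensity scores and 1:1 matching.

Classification uses the 90-day post-surgery window: I26.x = pulmonary
embolism (PE), I80.1-I80.3/I80.8 = phlebitis and thrombophlebitis (PTP),
I82.x = other venous embolism and thrombosis (VET), and a deep-vein code
co-occurring with a PE code = DVT+PE.  Matching pairs every case with the
nearest-propensity control, without replacement.
"""

import vteburden as vb
from vteburden.params import CHRONIC_FLAGS
from vteburden.simulate import calibrate_probit_intercept

# single-episode classification
for diags in (["I26.9:10"], ["I26.0:91"], ["I80.2:5;I26.1:30"], ["I82.9:40"]):
    print(f"{diags[0]:<22s} -> {vb.classify_vte(diags[0])}")

# cohort-scale: boost prevalence to 2% so a 30k cohort yields ~600 cases
base = vb.CohortParams()
coefs = dict(base.vte_probit_coefs)
coefs["intercept"] = calibrate_probit_intercept(base, 0.02)
params = base.replace(n_episodes=30_000, seed=11, vte_probit_coefs=coefs)

cohort = vb.classify_cohort(vb.apply_eligibility(vb.generate_cohort(params).episodes))
prop = vb.estimate_propensity(cohort)
matched = vb.match_nearest_neighbor(
    prop.scores,
    cohort.loc[cohort["vte"] == 1, "episode_id"].to_numpy(),
    cohort.loc[cohort["vte"] == 0, "episode_id"].to_numpy(),
)
frame = vb.build_matched_frame(cohort, matched)
print(f"\nmatched pairs: {len(matched.pairs)} "
      f"(median |score difference| {matched.pairs['distance'].median():.2e})")

bal = vb.balance_table(frame, ["age_group", "sex", *CHRONIC_FLAGS])
print(f"covariates with |SMD| > 0.1 after matching: {int(bal['imbalanced'].sum())}"
      f" of {len(bal)}")
print("An |SMD| below 0.1 is the conventional threshold for adequate balance.")
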