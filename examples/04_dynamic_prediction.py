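"""Dynamic prediction of state occupancy for one child, updated as new data
arrive.

A child observed single-GADA-positive for 3 years gets a first forecast; two
years later, after an observed transition into the IA-2A-positive state, the
forecast is recomputed on the extended history.  P(state 4) is the predicted
probability of type 1 diabetes by each horizon; entering the IA-2A state
raises it sharply.
"""

import numpy as np

import isletprog as ip
from isletprog.datamodel import LongitudinalRecord, StateRecord
from isletprog.joint import predict_occupancy, update_prediction

cfg = ip.default_config(n_subjects=0)
fit = ip.truth_joint_fit(cfg)  # generating joint model as the fitted object

baseline = ip.BaselineCovariates(sex="male", age_at_gada=2.3, fdr=0, dq_group="DQ2/8")
rng = np.random.default_rng(5)
records = []
for t in np.arange(0, 3.01, 0.25):  # quarterly titers + HbA1c while single GADA
    for var in ("gada_z", "ia2a_z", "iaa_z", "znt8a_z", "hba1c"):
        mean = fit.longitudinal.mean_value(var, [t])[0]
        records.append(LongitudinalRecord(var, float(t), float(mean + rng.normal(0, 0.1))))

history = ip.SubjectHistory(
    baseline=baseline, records=records, state_path=[StateRecord(1, 0.0, 3.0, None)]
)
grid = np.array([3.0, 5.0, 7.0, 9.0, 11.0])
pred = predict_occupancy(fit, history, grid, n_draws=400, seed=5)
print("forecast at landmark s = 3y (still single GADA):")
print("   u    P(single)  P(multi-)  P(multi+IA2A)  P(T1D)")
for u, row in zip(pred.times, pred.occupancy):
    print(f"  {u:4.1f}   {row[0]:.3f}      {row[1]:.3f}      {row[2]:.3f}          {row[3]:.3f}")

# two years later: observed transition into the IA-2A-positive state
new_states = [StateRecord(1, 3.0, 3.6, 3), StateRecord(3, 3.6, 5.0, None)]
grid2 = np.array([5.0, 7.0, 9.0, 11.0])
upd = update_prediction(fit, history, [], new_states, grid2, n_draws=400, seed=5)
print("\nupdated forecast at s' = 5y (now multiple with IA-2A):")
print("   u    P(single)  P(multi-)  P(multi+IA2A)  P(T1D)")
for u, row in zip(upd.times, upd.occupancy):
    print(f"  {u:4.1f}   {row[0]:.3f}      {row[1]:.3f}      {row[2]:.3f}          {row[3]:.3f}")
print(f"\nimportance-sampling ESS: first {pred.ess:.0f}, updated {upd.ess:.0f} (of 400 draws)")
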