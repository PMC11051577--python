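"""Time-specific fit of one synthetic record.

A record is generated from known 'true' parameters (heart-rate gain raised
15%, CO2 threshold lowered 5%) with 3% multiplicative noise; the fit then
standardizes measurement-linked parameters, selects an identifiable base set
by sensitivity analysis, and minimizes the relative-error cost with bounded
CMA-ES starting from the nominal values.
"""

from dynfit import (
    CardioRespSurrogate, DriftSpec, OptimizerSettings, ParameterDrift, StudyDesign,
    fit_record, generate_longitudinal_study, make_bounds,
)
from dynfit.selection import select_parameters
from dynfit.standardization import standardize_record

model = CardioRespSurrogate()
spec = DriftSpec(drifts={
    "GHR": ParameterDrift(intercept=33.0 * 1.15),
    "Bc": ParameterDrift(intercept=36.0 * 0.95),
}, seed=0)
design = StudyDesign(times=(0.0,), at_vco2=(1.2,), activity=(3.0,), sleep=(7.0,), seed=0)
(record,), truth = generate_longitudinal_study(model, spec, design)

start = make_bounds(standardize_record(record, model.default_parameters()))
k = [0, record.n_levels // 2, record.n_levels - 1]
selection = select_parameters(
    model, start, [record.stimuli[i] for i in k], record.env,
    exp_data=record.observation_matrix(model.variable_names)[:, k],
)
print("base set:", selection.base_set)

result = fit_record(model, record, start, selection, OptimizerSettings(seed=0))
print(f"cost: {result.cf_initial.cf:.4f} -> {result.cf_final.cf:.4f}")
for name in ("GHR", "Bc"):
    true = truth.values["S1"][0][name]
    fitted = result.params.value(name)
    print(f"{name:>4}: true {true:8.3f}  fitted {fitted:8.3f}  "
          f"({abs(fitted - true) / true:.1%} off)")

print(
    "\nThe cost is the mean squared relative error over 10 variables x 8 "
    "stimulus levels; the two perturbed parameters are pulled back near their "
    "true values despite the observation noise."
)
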