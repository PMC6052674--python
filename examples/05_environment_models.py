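"""Environmental determinants of movement: mixed-effects models with
backward-stepwise term deletion.

Simulates a full study in which hourly log displacement responds only
to precipitation (negative) and time of day (negative), fits the
five-covariate random-intercept model, reduces it by backward deletion,
and reports marginal/conditional r2 and the rain-vs-dry contrast.
"""

import numpy as np
import pandas as pd

from terrapath import envstats, paths, synth

cfg = synth.SynthConfig(seed=5)
study = synth.simulate_study(cfg)

steps = paths.compute_steps_by_individual(study.gps)
steps = paths.exclude_overnight(steps)
t0 = pd.to_datetime(steps["t_start"])
steps["date"], steps["hour"] = t0.dt.date, t0.dt.hour
data = steps.merge(study.weather, on=["date", "hour"])
data["log_distance"] = np.log(data["step_length"])

terms = ["ambient_temp_c", "abs_humidity_gm3", "precipitation",
         "cloud_cover", "hour"]
kept, res = envstats.backward_stepwise(data, "log_distance", terms)
print(f"terms retained by backward deletion: {kept}")
print(res.fixed_effects.round(3).to_string(index=False))
print(f"LRT vs null: chi2_{res.lrt_df} = {res.lrt_stat:.1f}, p = {res.lrt_p:.2g}")
print(f"r2 marginal = {res.r2_marginal:.3f}, conditional = {res.r2_conditional:.3f}")

contrast = envstats.precip_contrast(
    data["step_length"].to_numpy(), data["precipitation"].to_numpy()
)
print(f"hourly distance: {contrast['mean_no_precip']:.1f} m dry vs "
      f"{contrast['mean_precip']:.1f} m in rain "
      f"(t_{contrast['df']} = {contrast['t']:.2f}, p = {contrast['p']:.3g})")
print()
print("The generator injects only precipitation and time-of-day effects;")
print("stepwise deletion recovers exactly those, with a small marginal r2")
print("and a larger conditional r2 - most variation in movement belongs")
print("to the individual and the residual, not the weather.")
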