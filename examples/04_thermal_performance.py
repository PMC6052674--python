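"""Fit a thermal performance curve (TPC) to activity-vs-body-temperature
data and measure the performance breadth.

Two generators are compared: one whose expected ODBA peaks at a known
optimum (thermal specialist) and one that is temperature-independent
(thermal generalist / thermoconformer).  Candidate curves are ranked by
small-sample-corrected AIC; breadth is the temperature interval where
the fitted curve stays above 80% of its maximum.
"""

from terrapath import accel, synth, thermal

for curve in ("gaussian", "flat"):
    rec = synth.simulate_tpc_records(8000, curve=curve, t_opt=21.0, seed=3)
    bins = accel.bin_by_temperature(rec)
    fit = thermal.fit_tpc(bins)
    b = thermal.performance_breadth(fit, level=0.8)
    span = bins["temp_bin"].max() - bins["temp_bin"].min()
    print(f"{curve:>8} generator: best model = {fit.name}")
    print(f"          t_opt = {b.t_opt:.1f} C, 80% breadth = "
          f"{b.lo:.1f}-{b.hi:.1f} C "
          f"({(b.hi - b.lo) / span:.0%} of the {span:.0f} C span)")

print()
print("A narrow breadth around the peak marks a thermal specialist; a")
print("breadth covering essentially the whole measured range - with the")
print("constant model winning the AICc comparison - is the generalist")
print("signature free-ranging box turtles show in the field.")
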