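"""A triplicate virtual thorough-QT-style trial with moxifloxacin.

Runs 3 studies x 20 subjects observed at six clock times, drug-free and
at the free Cmax of moxifloxacin (3.8 uM; IKr block 11.6% via the Hill
equation), then summarises the drug effect with both baseline
corrections.  The contrast between them is the point: a single pooled
baseline lets circadian heart-rate (and subject) variation leak into
the apparent drug effect, while each subject's own time-matched
baseline isolates the drug.
"""

from cardiocirc import (MOXIFLOXACIN_CHANNELS, SimulationSpec, TrialDesign,
                        delta_qtcf_individualized, delta_qtcf_single_baseline,
                        hill_inhibition_factor, run_virtual_trial,
                        surrogate_qt_engine)

ikr = MOXIFLOXACIN_CHANNELS[0]
print(f"moxifloxacin {ikr.concentration_um} uM vs IKr IC50 {ikr.ic50_um} uM "
      f"-> inhibition {hill_inhibition_factor(ikr):.4f}")

design = TrialDesign(seed=5)      # 3 x 20 subjects, hours 4..24
model = SimulationSpec(times=[0.0], seed=11)
obs = run_virtual_trial(design, surrogate_qt_engine(), MOXIFLOXACIN_CHANNELS,
                        model)
print(f"simulated {len(obs)} QT observations "
      f"({design.n_trials} trials x {design.n_per_trial} subjects x "
      f"{len(design.times_of_day)} times x 2 arms)\n")

single = delta_qtcf_single_baseline(obs)
indiv = delta_qtcf_individualized(obs)
print("hour   dQTcF (single-point)    dQTcF_i (individualised)")
for hour in single.index:
    s, i = single.loc[hour], indiv.loc[hour]
    print(f"{hour:4.0f}   {s['mean_ms']:6.2f} +/- {s['sd_ms']:5.2f} ms"
          f"      {i['mean_ms']:6.2f} +/- {i['sd_ms']:5.2f} ms")

print("\nThe individualised correction is flat across the day and tight")
print("(subject offsets cancel exactly); the single-point correction keeps")
print("the full between-subject spread and drifts with the clock.")
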