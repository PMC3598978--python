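"""Evaluate the reference circadian RR model for a few subjects.

Prints the expected RR interval over the day for a 30-year-old woman
and man, plus the 95% prediction band at selected hours.  RR is the
beat-to-beat interval in milliseconds (60000 / heart rate in bpm), so
longer RR = slower heart rate; the nocturnal RR lengthening is the
circadian signature the model captures.
"""

from cardiocirc import (DEFAULT_COEFFICIENTS, SubjectProfile, predict_rr,
                        prediction_band)

female = SubjectProfile("F-30", sex=0, age=30)
male = SubjectProfile("M-30", sex=1, age=30)

print("hour   RR female [ms]   RR male [ms]")
for hour in range(0, 24, 3):
    print(f"{hour:4d} {predict_rr(DEFAULT_COEFFICIENTS, female, hour):14.1f}"
          f" {predict_rr(DEFAULT_COEFFICIENTS, male, hour):14.1f}")

print("\n95% prediction band, female age 30:")
for hour in (0, 12):
    low, high = prediction_band(DEFAULT_COEFFICIENTS, female, hour, level=0.95)
    mid = predict_rr(DEFAULT_COEFFICIENTS, female, hour)
    print(f"  hour {hour:2d}: {low:6.1f} .. {mid:6.1f} .. {high:6.1f} ms")

print("\nThe band is the range expected to contain ~95% of single RR")
print("observations for such a subject at that time of day.")
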