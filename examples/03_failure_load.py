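"""Failure-load detection on a compression load-displacement curve.

The failure load is the first local maximum followed by a drop of strictly
more than 10% of the peak before the load recovers past it.  Dividing by the
minimum transverse cross-sectional area gives a size-adjusted strength.
"""

from marrowlab import detect_failure_load, generate_load_curve

curve = generate_load_curve(fl_true=2580.0, drop_fraction=0.2, seed=3)
result = detect_failure_load(curve, min_area=5.8)

print(f"failure load        : {result.failure_load:.0f} N")
print(f"observed drop       : {100 * result.drop_observed:.0f} % of the peak")
print(f"normalized strength : {result.normalized_failure_load:.0f} N/cm^2")

# A peak with only a 5% drop does not qualify as failure:
benign = generate_load_curve(fl_true=400.0, drop_fraction=0.05)
print(f"5% drop detected as failure: {detect_failure_load(benign).detected}")
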