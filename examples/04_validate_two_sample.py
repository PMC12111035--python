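"""External validation: two-sample F-test and pooled t-test on a matched
measured/predicted pair.

Builds a 50-sample pair with a small prediction bias and extra dispersion,
then prints the spreadsheet-style report block: if F stays below its
one-tailed critical value and |t| below the two-tailed critical value, the
predictions are statistically indistinguishable from the measurements in
variance and mean.
"""

from flourspec import make_validation_pair, two_sample_report

measured, predicted = make_validation_pair(
    n=50, bias=0.3, extra_sd=1.5, mean=29.0, sd=6.4, seed=8
)
report = two_sample_report(measured, predicted, alpha=0.05)
print(report.render_table())

f_ok = report.f_stat < report.f_critical_one_tailed
t_ok = abs(report.t_stat) < report.t_critical_two_tailed
print(f"variances homogeneous (F < critical): {f_ok}")
print(f"no significant mean bias (|t| < critical): {t_ok}")
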