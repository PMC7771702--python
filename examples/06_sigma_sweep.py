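"""Label-width experiment: how the Gaussian sigma affects accuracy.

Trains one network per label standard deviation (reference-frame px)
under identical seeds and schedules.  Narrow labels starve the network
of gradient signal and localisation collapses; moderately wide labels
train well.  Two sigmas take ~8 minutes on one CPU core.
"""

from skullmark import sigma_sweep

table = sigma_sweep(sigmas=(5.0, 20.0), seed=1)
print(table.round(2).to_string())
print()
m5 = table[5.0][["bregma_mean_error_px", "lambda_mean_error_px"]].mean()
m20 = table[20.0][["bregma_mean_error_px", "lambda_mean_error_px"]].mean()
print("mean error, sigma 5: %.1f crop px;  sigma 20: %.1f crop px" % (m5, m20))
# sigma=5 should be clearly worse than sigma=20 — the same direction the
# full-scale experiment shows when the label bump is too narrow.
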