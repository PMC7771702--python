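"""Train the heatmap-regression FCN at the tiny preset and evaluate it.

The tiny protocol is a CPU-scale replica of the full experiment: 64x64
net input, quarter-width network, 200 augmented training crops from 50
scenes, 30 epochs of Adam on pixel-wise MSE.  Takes a few minutes on
one CPU core.
"""

from skullmark.experiments import run_protocol

out = run_protocol(seed=1)

hist = out["history"]
print("epochs trained:", len(hist["train_loss"]),
      " best validation epoch:", hist["best_epoch"])
print("validation loss first/last: %.4f / %.4f"
      % (hist["val_loss"][0], hist["val_loss"][-1]))

s = out["summary"]
print("held-out mean error: bregma %.2f net px, lambda %.2f net px"
      % (s["bregma_mean_error_netpx"], s["lambda_mean_error_netpx"]))
print("held-out max error:  bregma %.2f net px, lambda %.2f net px"
      % (s["bregma_max_error_netpx"], s["lambda_max_error_netpx"]))
# Net pixels are crop pixels divided by the crop/net scale of 2.5; a
# mean of ~2 net px corresponds to ~5 px in the 160-px tiny crop, the
# scaled analogue of the ~10 px (of 640) error regime at full scale.
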