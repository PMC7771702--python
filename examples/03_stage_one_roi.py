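"""Stage one: detect the skull and extract the fixed-size crop.

The photograph is downsampled 4x, the rule-based baseline detector finds
the bright skull blob, and a 640x640 crop (downsampled to the 256x256
net input) is cut around it.  The returned CropWindow maps net-frame
coordinates back to full resolution exactly.
"""

from skullmark import (FULL, OtsuSkullDetector, detect_skull, downsample,
                       extract_net_input, generate_scene, to_full)
from skullmark.roi import bbox_iou

scene = generate_scene(preset=FULL, seed=3)
lowres = downsample(scene.image, FULL.downsample_factor)
print("lowres:", lowres.shape)  # (612, 816, 3)

detection = detect_skull(lowres, OtsuSkullDetector())
true_lowres = tuple(v / 4 for v in scene.bbox)
print("detected bbox:", [round(v, 1) for v in detection.bbox_lowres],
      "score", round(detection.score, 3))
print("IoU with true bbox:", round(bbox_iou(detection.bbox_lowres, true_lowres), 3))

net_image, window = extract_net_input(scene.image, detection)
print("net input:", net_image.shape, "crop origin:", window.origin,
      "scale:", window.scale)
print("net (0,0) maps to full", to_full((0, 0), window))
# A high IoU means the crop is centred on the skull, so both landmarks
# fall inside the window that stage two will see.
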