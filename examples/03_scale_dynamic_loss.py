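"""The scale-based dynamic box loss on worked examples.

Shows the IoU/localisation decomposition, the scale factor beta3, and
how the dynamic weights shift supervision toward centre localisation
for small ground-truth boxes.
"""

from dfsnet import Box, SDParams, bbox_loc_loss, box_iou, dynamic_weights, scale_factor, sdb_loss

bp, bgt = Box(0, 0, 10, 10), Box(5, 5, 15, 15)
s = SDParams(theta=1.0, gamma=0.0)

print(f"IoU(pred, gt)          = {box_iou(bp, bgt):.6f}   (= 25/175 = 1/7)")
print(f"centre/diagonal term   = {bbox_loc_loss(bp, bgt):.6f}   (= 50/450 = 1/9)")
print(f"L_SDB                  = {sdb_loss(bp, bgt, s):.6f}   (= 6/7 + 1/9, area 100 saturates beta3)")

print("\nbeta3 = min(area/81 * theta * delta, delta), theta=1:")
for area in (81.0, 40.0, 8.1):
    b3 = scale_factor(area, s)
    b1, b2 = dynamic_weights(b3, s.delta)
    print(f"  area {area:5.1f} px² -> beta3={b3:.3f}  beta1={b1:.2f}  beta2={b2:.2f}"
          f"   (beta1+beta2={b1+b2:.1f})")

print("\nSmaller targets push beta2 toward 1.5: centre localisation dominates")
print("exactly where the IoU signal is least reliable.")
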