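"""Model complexity accounting: parameters, MACs and streamlining savings.

Compares the streamlined single-head detector (3-conv neck block) with
the unstreamlined reference (5-conv blocks, three scale heads) at the
default width configuration, and recomputes the published reduction
percentages from the published parameter totals.
"""

from goatloc import (count_macs, count_parameters, percent_reduction,
                     published_reduction_table)
from goatloc.detector import DetectorConfig, custom_yolo_layer_specs

cfg = DetectorConfig()  # 416 px, stage widths (16, 32, 64, 128, 256)
slim = custom_yolo_layer_specs(cfg, streamlined=True)
full = custom_yolo_layer_specs(cfg, streamlined=False)
p_slim, p_full = count_parameters(slim), count_parameters(full)

print(f"streamlined Custom_YOLO:      {p_slim:>12,} params")
print(f"5-conv / 3-head reference:    {p_full:>12,} params")
print(f"reduction from streamlining:  {percent_reduction(p_slim, p_full):.2f}%")
print(f"MACs at {cfg.input_size} px:  {count_macs(slim, (cfg.input_size,) * 2):,}")
print("\npublished reduction table (recomputed from printed totals):")
for name, pct in published_reduction_table().items():
    print(f"  {name:<14s} {pct:.2f}%")
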