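"""Soma shape metrics: perimeter, area and the circularity index.

CI = 4πA/P² is 1.0 for a perfect circle and decreases for elongated or
irregular outlines — a compact, scale-free summary of soma roundness.
"""

import math

from spinemorph import circularity, generate_dataset, polygon_metrics, preset, summarize_soma

# analytic shapes
print(f"CI(circle, any radius)  = {circularity(2 * math.pi * 3, math.pi * 9):.6f}")
print(f"CI(unit square)         = {circularity(4.0, 1.0):.6f}  (π/4)")
p, a = polygon_metrics([(0, 0), (4, 0), (4, 1), (0, 1)])
print(f"CI(4×1 rectangle)       = {circularity(p, a):.6f}  (elongated → smaller)")

# synthetic soma traces, per strain and region
cfg = preset("null_twostrain")
cfg.seed = 7
summary = summarize_soma(generate_dataset(cfg))
print("\nSoma metrics per strain × region (mean ± SD over neurons):")
for _, row in summary[summary["metric"] == "circularity"].iterrows():
    print(f"  {row['strain']:9s} {row['region']:16s} CI = "
          f"{row['mean']:.3f} ± {row['sd']:.3f}  (n={row['n']})")
print("Values near 1 mean round somata; lower values mean irregular outlines.")
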