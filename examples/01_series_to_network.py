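"""Map a short series onto horizontal visibility graphs.

Builds the HVG and the limited penetrable variant (L = 1) of a ten-sample
series and prints their edge lists (1-based indices).  Every extra edge at
L = 1 tolerates exactly one blocking in-between sample.
"""

import numpy as np

from mlphvg import build_hvg, build_lphvg

series = np.array([0.8, 0.3, 0.9, 0.4, 0.1, 0.7, 0.2, 0.6, 0.5, 1.0])

hvg = build_hvg(series)
lphvg = build_lphvg(series, L=1)

print("series:", series.tolist())
print(f"HVG   (L=0): {hvg.n_edges} edges:",
      [(i + 1, j + 1) for i, j in hvg.sorted_edges()])
print(f"LPHVG (L=1): {lphvg.n_edges} edges:",
      [(i + 1, j + 1) for i, j in lphvg.sorted_edges()])
extra = sorted(lphvg.edges - hvg.edges)
print("edges gained by allowing one blocker:",
      [(i + 1, j + 1) for i, j in extra])
# The HVG links samples that can 'see' each other over strictly lower
# values; the penetrable variant adds longer-range links that one tall
# in-between sample would otherwise cut, making the mapping noise-tolerant.
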