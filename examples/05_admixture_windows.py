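"""Windowed fd admixture proportions over an introgressed region.

Simulates a chromosome where sites in 0.5-0.9 Mb share derived alleles
between P2 and P3 (the introgression signature) and scans overlapping
windows for D and fd.
"""

import numpy as np

from hybgen import admixture as adx
from hybgen import simulate as sim

freqs = sim.simulate_frequency_matrix(10_000, length_bp=2_000_000,
                                      introgressed_span=(500_000, 900_000),
                                      seed=5)
windows = adx.fd_windows(freqs.drop(columns="introgressed"),
                         window_bp=100_000, step_bp=20_000, min_sites=100)
inside = windows[(windows["start"] >= 500_000) & (windows["end"] <= 900_000)]
outside = windows[(windows["end"] <= 400_000) | (windows["start"] >= 1_000_000)]
print(f"{len(windows)} windows; fd defined in {windows['fd'].notna().sum()}")
print(f"mean fd inside the introgressed span:  {np.nanmean(inside['fd']):.3f}")
print(f"mean fd outside:                       {np.nanmean(outside['fd']):.3f}")
# High fd marks genomic regions exchanging alleles between species; genes
# resisting gene flow (e.g. barrier loci) sit in low-fd valleys.
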