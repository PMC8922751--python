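"""The N-adjusted kernel-to-PWM transformation on a worked example.

A trained first-layer kernel is a 5 x L weight matrix over the channels
A, T, C, G, N. The N (cryptic nucleotide) channel carries no sequence
preference, so its weight is treated as the bias floor: each nucleotide
weight is measured relative to it, clipped at zero, and the column is
normalized to probabilities. Columns where no nucleotide beats N become
uniform (0.25 each) — no preference. The N-effect rank (0 = smallest of
the five channels, 4 = largest) flags positions where the bias control
dominates.
"""

import numpy as np

from tssmotif.core import KernelMatrix
from tssmotif.interpret import n_adjusted_transform, n_effect_ranks

kernel = KernelMatrix(
    np.array(
        [
            # col0   col1   col2
            [0.50, 0.10, 1.00],  # A
            [0.30, 0.00, 0.00],  # T
            [-0.20, -0.30, 0.00],  # C
            [0.10, 0.05, 0.00],  # G
            [0.10, 0.20, 0.00],  # N
        ]
    )
)

pwm = n_adjusted_transform(kernel)
ranks = n_effect_ranks(kernel)

np.set_printoptions(precision=4, suppress=True)
print("kernel (rows A,T,C,G,N):")
print(kernel.matrix)
print()
print("N-adjusted PWM (rows A,T,C,G; columns sum to 1):")
print(pwm.matrix)
print()
print("N-effect rank per column (4 = N largest):", ranks)
print()
print("column 0: adjusted weights (0.4, 0.2, 0, 0) -> (2/3, 1/3, 0, 0)")
print("column 1: every nucleotide <= N -> uniform 0.25 (no preference)")
print("column 2: single dominant channel -> certain A")
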