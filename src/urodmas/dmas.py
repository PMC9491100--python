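"""The DNA methylation arctangent score (DMAS).

DMAS(i, j) = atan2(unmethyl(i, j), methyl(i, j)) for window i of sample j,
a value in [0, pi/2]: 0 for fully methylated *or uncovered* windows, pi/2
for fully unmethylated ones.  The score is scale-invariant in coverage and
strictly decreasing in the methylation rate at fixed coverage, so it can
replace the rate without special-casing zero-coverage windows.
"""

from __future__ import annotations

import numpy as np

from .types import CountMatrix, DMASMatrix, ValidationError


def compute_dmas(counts: CountMatrix) -> DMASMatrix:
    """Arctangent score per sample x window; atan2(0, 0) is pinned to 0."""
    values = np.arctan2(counts.unmethyl.astype(float), counts.methyl.astype(float))
    # numpy returns 0.0 for atan2(0, 0); keep that pinned regardless of platform.
    zero = (counts.unmethyl == 0) & (counts.methyl == 0)
    values[zero] = 0.0
    return DMASMatrix(list(counts.sample_ids), list(counts.window_ids), values)


def methylation_rate(counts: CountMatrix, floor: float = 1e-10) -> np.ndarray:
    """Conventional methylation rate methyl / max(floor, methyl + unmethyl).

    The floored dividend makes zero-coverage windows well-defined (rate 0);
    used only to relate DMAS to the rate, never by the classifier itself.
    """
    if floor <= 0:
        raise ValidationError(f"floor must be positive, got {floor}")
    total = (counts.methyl + counts.unmethyl).astype(float)
    return counts.methyl / np.maximum(floor, total)
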