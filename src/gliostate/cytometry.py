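"""Flow-cytometry summary computations: ratio channels and median gating.

Oxidation-sensitive dyes are summarized as per-event ratios of two
fluorescence channels (e.g. oxidized/reduced species); conditions are
compared by gating the test distribution at the median of a reference
condition and reporting the fraction of events above the gate (the
reference gated on itself sits at ~50% by construction). Inputs are
pre-gated live-event channel tables; FCS parsing and scatter/viability
gating are upstream concerns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def ratio_channel(numerator, denominator, floor: float = 1e-6) -> np.ndarray:
    """Per-event channel ratio with a floored denominator.

    ratio_i = num_i / max(den_i, floor); the floor keeps zero-denominator
    events finite.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError(f"channel length mismatch: {num.shape} vs {den.shape}")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    return num / np.maximum(den, floor)


def median_gate_fraction(reference_values, test_values) -> pd.Series:
    """Gate at the reference median; report test fractions above/below.

    "Above" is strict (> gate); events exactly at the gate count below, so
    fraction_above + fraction_at_or_below = 1 exactly.
    """
    ref = np.asarray(reference_values, dtype=float)
    test = np.asarray(test_values, dtype=float)
    if ref.size == 0:
        raise ValueError("reference condition is empty")
    if test.size == 0:
        raise ValueError("test condition is empty")
    gate = np.median(ref)
    above = float((test > gate).mean())
    return pd.Series(
        {"gate": float(gate), "fraction_above": above, "fraction_at_or_below": 1.0 - above}
    )
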