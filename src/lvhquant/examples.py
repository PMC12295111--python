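"""Worked-example inputs: a published per-sub-segment thickness table from
one hypertrophic-cardiomyopathy case, and reader-study confusion counts.

These are small printed datasets used as fixed inputs for demonstrating
the scorer and the classification metrics; they are not measurements made
by this package.
"""

from __future__ import annotations

#: mean wall thickness (mm) per AHA segment, three sub-segments each in
#: increasing angular order; segment 17 is the undivided apex.
EXAMPLE_HCM_SUBSEGMENT_RWT: dict[int, tuple[float, ...]] = {
    1: (21.23, 18.12, 14.78),
    2: (7.84, 7.63, 6.51),
    3: (6.57, 7.2, 6.22),
    4: (8.2, 10.44, 7.99),
    5: (9.32, 12.67, 8.71),
    6: (25.61, 26.08, 22.77),
    7: (12.44, 16.08, 22.08),
    8: (11.50, 10.34, 9.17),
    9: (13.21, 11.72, 11.13),
    10: (13.82, 13.40, 12.61),
    11: (12.47, 13.12, 14.55),
    12: (23.54, 21.91, 15.89),
    13: (14.56, 16.34, 21.61),
    14: (12.28, 13.49, 13.01),
    15: (9.13, 10.32, 10.75),
    16: (11.93, 16.61, 21.18),
    17: (5.31,),
}

#: reader-study binary confusion counts (tp, tn, fp, fn) over 1323
#: sub-segments: two readers, each assessed visually and with the
#: quantitative tool.
EXAMPLE_READER_CONFUSIONS: dict[str, tuple[int, int, int, int]] = {
    "reader1_visual": (827, 354, 77, 65),
    "reader1_quantitative": (847, 423, 32, 21),
    "reader2_visual": (881, 380, 35, 27),
    "reader2_quantitative": (910, 389, 16, 8),
}

#: study bookkeeping: cohort and split sizes the sub-segment counts follow
#: from (patients x regions).
COHORT_PATIENTS = 133
TEST_PATIENTS = 27


def example_rwt_values() -> list[float]:
    """The 49 thickness values flattened in segment order."""
    out: list[float] = []
    for seg in range(1, 18):
        out.extend(EXAMPLE_HCM_SUBSEGMENT_RWT[seg])
    return out
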