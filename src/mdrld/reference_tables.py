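"""Published detection-sensitivity reference values.

These are the reported per-100 exact and signal sensitivities of MDR for
one- and two-locus disease models embedded in pools of 40/60/80/95%
relative LD, used to exercise the cross-effect-size aggregation
utilities and as the comparison point for trend checks.  ``effect`` is a
per-allele odds ratio for the one-locus layouts and a broad-sense
heritability for the two-locus layouts.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["one_locus_reference", "two_locus_reference"]

# (scenario, ld_level, effect, exact, signal, signal_func_dropped)
_ONE_LOCUS = [
    ("edge_of_block", 0.40, 1.5, 86, 87, 4),
    ("edge_of_block", 0.40, 2.0, 96, 96, 7),
    ("edge_of_block", 0.40, 3.0, 94, 94, 10),
    ("edge_of_block", 0.60, 1.5, 85, 93, 71),
    ("edge_of_block", 0.60, 2.0, 97, 99, 67),
    ("edge_of_block", 0.60, 3.0, 96, 96, 49),
    ("edge_of_block", 0.80, 1.5, 23, 90, 90),
    ("edge_of_block", 0.80, 2.0, 22, 91, 91),
    ("edge_of_block", 0.80, 3.0, 28, 92, 92),
    ("edge_of_block", 0.95, 1.5, 14, 82, 84),
    ("edge_of_block", 0.95, 2.0, 25, 90, 90),
    ("edge_of_block", 0.95, 3.0, 24, 94, 95),
    ("middle_of_block", 0.40, 1.5, 76, 80, 14),
    ("middle_of_block", 0.40, 2.0, 92, 92, 10),
    ("middle_of_block", 0.40, 3.0, 95, 95, 5),
    ("middle_of_block", 0.60, 1.5, 58, 90, 92),
    ("middle_of_block", 0.60, 2.0, 75, 99, 99),
    ("middle_of_block", 0.60, 3.0, 73, 93, 94),
    ("middle_of_block", 0.80, 1.5, 54, 88, 87),
    ("middle_of_block", 0.80, 2.0, 72, 93, 96),
    ("middle_of_block", 0.80, 3.0, 84, 94, 93),
    ("middle_of_block", 0.95, 1.5, 0, 92, 92),
    ("middle_of_block", 0.95, 2.0, 0, 83, 83),
    ("middle_of_block", 0.95, 3.0, 0, 93, 93),
]

# (scenario, ld_level, effect, exact, signal,
#  signal_snp1_dropped, signal_snp2_dropped, signal_both_dropped)
_TWO_LOCUS = [
    ("one_in_one_out", 0.40, 0.05, 77, 81, 22, 44, 7),
    ("one_in_one_out", 0.40, 0.15, 100, 100, 3, 31, 1),
    ("one_in_one_out", 0.40, 0.25, 100, 100, 0, 23, 0),
    ("one_in_one_out", 0.60, 0.05, 83, 96, 91, 100, 97),
    ("one_in_one_out", 0.60, 0.15, 97, 100, 98, 100, 97),
    ("one_in_one_out", 0.60, 0.25, 99, 100, 100, 100, 100),
    ("one_in_one_out", 0.80, 0.05, 11, 65, 63, 60, 63),
    ("one_in_one_out", 0.80, 0.15, 77, 97, 99, 84, 86),
    ("one_in_one_out", 0.80, 0.25, 86, 98, 99, 83, 86),
    ("one_in_one_out", 0.95, 0.05, 0, 80, 63, 80, 63),
    ("one_in_one_out", 0.95, 0.15, 0, 95, 88, 95, 88),
    ("one_in_one_out", 0.95, 0.25, 0, 89, 87, 89, 87),
    ("two_separate_blocks", 0.40, 0.05, 91, 97, 8, 52, 1),
    ("two_separate_blocks", 0.40, 0.15, 100, 100, 3, 34, 1),
    ("two_separate_blocks", 0.40, 0.25, 100, 100, 2, 26, 0),
    ("two_separate_blocks", 0.60, 0.05, 88, 98, 100, 95, 96),
    ("two_separate_blocks", 0.60, 0.15, 91, 96, 100, 97, 100),
    ("two_separate_blocks", 0.60, 0.25, 94, 97, 100, 95, 99),
    ("two_separate_blocks", 0.80, 0.05, 6, 64, 67, 64, 67),
    ("two_separate_blocks", 0.80, 0.15, 36, 89, 92, 87, 92),
    ("two_separate_blocks", 0.80, 0.25, 49, 93, 96, 93, 96),
    ("two_separate_blocks", 0.95, 0.05, 19, 79, 79, 79, 79),
    ("two_separate_blocks", 0.95, 0.15, 23, 91, 91, 92, 92),
    ("two_separate_blocks", 0.95, 0.25, 28, 93, 93, 94, 94),
    ("two_same_block", 0.60, 0.05, 96, 96, 96, 97, 99),
    ("two_same_block", 0.60, 0.15, 97, 97, 98, 96, 100),
    ("two_same_block", 0.60, 0.25, 98, 98, 98, 96, 100),
    ("two_same_block", 0.80, 0.05, 78, 95, 95, 95, 93),
    ("two_same_block", 0.80, 0.15, 17, 72, 72, 72, 77),
    ("two_same_block", 0.80, 0.25, 54, 91, 91, 91, 93),
    ("two_same_block", 0.95, 0.05, 57, 91, 91, 91, 91),
    ("two_same_block", 0.95, 0.15, 29, 86, 86, 86, 86),
    ("two_same_block", 0.95, 0.25, 41, 94, 94, 94, 94),
]


def one_locus_reference() -> pd.DataFrame:
    """One-locus reference sensitivities (per 100 replicates)."""
    return pd.DataFrame(_ONE_LOCUS, columns=[
        "scenario", "ld_level", "effect", "exact", "signal",
        "signal_func_dropped"])


def two_locus_reference() -> pd.DataFrame:
    """Two-locus (purely epistatic) reference sensitivities."""
    return pd.DataFrame(_TWO_LOCUS, columns=[
        "scenario", "ld_level", "effect", "exact", "signal",
        "signal_snp1_dropped", "signal_snp2_dropped", "signal_both_dropped"])
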