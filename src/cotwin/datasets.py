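"""Small built-in example data.

``example_pair_counts`` reproduces the pair-classification structure of a
219-pair adult twin registry cohort (97 MZ / 122 DZ same-sex pairs,
binary mental-disorder status) used throughout the documentation:

==========  ===========  ====================  ===================
zygosity    discordant   concordant_affected   concordant_healthy
==========  ===========  ====================  ===================
MZ          28           22                    47
DZ          46           13                    63
==========  ===========  ====================  ===================

``metadata_from_pair_counts`` expands such a table into a minimal
individual-level metadata frame (two members per pair with the implied MD
flags), which the cohort-structure functions can consume directly.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["example_pair_counts", "metadata_from_pair_counts"]


def example_pair_counts() -> pd.DataFrame:
    """Pair counts (zygosity x class) of the 219-pair example cohort."""
    return pd.DataFrame(
        {"discordant": [28, 46], "concordant_affected": [22, 13],
         "concordant_healthy": [47, 63]},
        index=pd.Index(["MZ", "DZ"], name="zygosity"))


def metadata_from_pair_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Individual-level metadata implied by a zygosity x class count table.

    Each pair contributes two rows; discordant pairs get MD flags (1, 0),
    concordant-affected (1, 1), concordant-healthy (0, 0).
    """
    md_flags = {"discordant": (1, 0), "concordant_affected": (1, 1),
                "concordant_healthy": (0, 0)}
    rows = []
    pair_no = 0
    for zyg in counts.index:
        for cls, flags in md_flags.items():
            for _ in range(int(counts.loc[zyg, cls])):
                pair_no += 1
                pid = f"P{pair_no:04d}"
                for k, flag in enumerate(flags):
                    rows.append({"sample_id": f"{pid}_{k + 1}", "pair_id": pid,
                                 "zygosity": zyg, "md": flag})
    return pd.DataFrame(rows).set_index("sample_id")
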