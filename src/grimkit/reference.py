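"""Published summary tables of the reference CCl4 injection study.

These are inputs for desk-level reproduction: the severity-class counts of
the 24-mouse, 4-week repeated-i.p.-injection study (498 retained video
records) whose design the synthetic generator emulates. They allow the
contingency statistics to be recomputed without access to the raw data.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SEVERITY_COUNTS",
    "severity_counts_published",
]

#: Severity-class counts per (treatment, intervention): mild / moderate / severe.
SEVERITY_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("Oil", "bsl"): (11, 7, 0),
    ("Oil", "pre"): (93, 41, 2),
    ("Oil", "post"): (63, 59, 5),
    ("CCl4", "bsl"): (8, 12, 0),
    ("CCl4", "pre"): (49, 54, 3),
    ("CCl4", "post"): (9, 69, 13),
}


def severity_counts_published() -> pd.DataFrame:
    """The published severity table as interventions x classes per treatment."""
    idx = pd.MultiIndex.from_tuples(SEVERITY_COUNTS, names=["treatment", "intervention"])
    return pd.DataFrame(
        list(SEVERITY_COUNTS.values()),
        index=idx,
        columns=["mild", "moderate", "severe"],
    )
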