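"""Reference clinical cohort: the 10 drug-resistant-epilepsy patients whose
monthly seizure frequencies before and one year after VNS implantation
anchor the package's worked examples.

``labar_printed`` is the Labar index as reported clinically (two decimals).
For patient 10 the reported value (72.00) does not match the reported
seizure rates (33.00 -> 8.40 gives 74.55); the recomputed column is the
arithmetic truth and worked examples use patients 1-9 where both agree.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # id, sex, age, diagnosis, pre_rate, post_rate, labar_printed, mchugh
    (1, "M", 45, "focal", 11.80, 11.25, 4.66, "III"),
    (2, "F", 31, "LGS", 43.70, 47.40, -8.47, "III"),
    (3, "M", 48, "focal", 3.00, 0.43, 85.67, "I"),
    (4, "F", 61, "focal", 20.00, 0.10, 99.50, "I"),
    (5, "M", 42, "LGS", 4.00, 0.67, 83.25, "I"),
    (6, "M", 46, "focal", 0.13, 0.00, 100.00, "I"),
    (7, "F", 35, "focal", 0.33, 0.33, 0.00, "III"),
    (8, "F", 34, "focal", 10.00, 10.00, 0.00, "V"),
    (9, "M", 50, "LGS", 2.00, 2.00, 0.00, "III"),
    (10, "M", 27, "focal", 33.00, 8.40, 72.00, "II"),
]


def reference_cohort() -> pd.DataFrame:
    """The reference VNS cohort as a DataFrame (one row per patient)."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "id",
            "sex",
            "age",
            "diagnosis",
            "pre_rate",
            "post_rate",
            "labar_printed",
            "mchugh_class",
        ],
    )
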