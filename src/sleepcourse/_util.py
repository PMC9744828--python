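"""Small shared helpers."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

AGE_GROUP_LABELS = ("young", "middle", "older")


def assign_age_groups(
    ages,
    changepoints: Sequence[float] = (33.0, 53.0),
    labels: Sequence[str] = AGE_GROUP_LABELS,
) -> pd.Categorical:
    """Map ages to the three life-course phases delimited by two change points.

    A change point at age ``c`` puts ages ``<= c`` in the earlier group:
    with change points (33, 53) the groups are [19, 34), [34, 54), [54, inf).
    """
    c1, c2 = sorted(float(c) for c in changepoints)
    if len(labels) != 3:
        raise ValueError("exactly three group labels are required")
    ages = np.asarray(ages, dtype=float)
    idx = np.where(ages < c1 + 1, 0, np.where(ages < c2 + 1, 1, 2))
    return pd.Categorical.from_codes(idx, categories=list(labels), ordered=True)
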