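"""Two-sample Student's t-test and RT-qPCR relative-quantification arithmetic.

The classical pooled-variance test is the default (Welch's unequal-variance
form is available behind a flag); p-values are two-sided unless requested
otherwise. The qPCR normalization divides each sample's target quantity by
its reference-gene quantity and expresses the result as a fold change over
the mean ratio of a baseline group (e.g. wild-type dark controls), whose
mean fold is therefore exactly 1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError


def student_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
    alternative: str = "two-sided",
) -> tuple[float, float, float]:
    """Two-sample t-test; returns ``(t, df, p)``.

    Pooled-variance (classical Student) by default with
    ``df = n_a + n_b - 2``. Zero pooled variance with equal means gives
    ``t = 0, p = 1``; with unequal means the statistic is infinite and p is 0.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError(
            f"each group needs n >= 2 observations, got {a.size} and {b.size}"
        )
    if alternative not in ("two-sided", "less", "greater"):
        raise AnalysisError(f"unknown alternative {alternative!r}")
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    if welch:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / na + vb / nb
        if se2 == 0:
            return (0.0, float(na + nb - 2), 1.0) if diff == 0 else (np.inf * np.sign(diff), float(na + nb - 2), 0.0)
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        if sp2 == 0:
            if diff == 0:
                return 0.0, df, 1.0
            return float(np.sign(diff) * np.inf), df, 0.0
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if alternative == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif alternative == "greater":
        p = sps.t.sf(t, df)
    else:
        p = sps.t.cdf(t, df)
    return float(t), float(df), float(min(1.0, p))


REQUIRED_QPCR_COLUMNS = ("sample_id", "gene", "relative_quantity", "group")


def qpcr_normalize(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "RCK1",
    baseline_group: str = "WT dark",
) -> pd.DataFrame:
    """Reference-gene ratios expressed as fold change over a baseline group.

    ``table`` is tidy with columns ``sample_id, gene, relative_quantity,
    group`` (one row per sample x gene, quantities from the relative
    standard-curve method). Per sample: ``ratio = target / reference``;
    ``fold = ratio / mean(ratio over baseline_group)``. Samples without a
    reference record are skipped and listed in the ``skipped`` frame
    attribute. The baseline group's mean fold is exactly 1 by construction,
    and folds are invariant to any global rescaling of the quantities.
    """
    missing = [c for c in REQUIRED_QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise AnalysisError(f"qPCR table is missing column(s): {missing}")
    qty = pd.to_numeric(table["relative_quantity"], errors="raise")
    if (qty <= 0).any():
        raise AnalysisError("relative quantities must be positive")
    tgt = table[table["gene"] == target_gene].set_index("sample_id")
    ref = table[table["gene"] == reference_gene].set_index("sample_id")
    if tgt.empty:
        raise AnalysisError(f"no rows for target gene {target_gene!r}")
    skipped = sorted(set(tgt.index) - set(ref.index))
    common = [s for s in tgt.index if s in ref.index]
    ratios = pd.DataFrame(
        {
            "sample_id": common,
            "group": tgt.loc[common, "group"].to_numpy(),
            "ratio": (
                tgt.loc[common, "relative_quantity"].to_numpy(dtype=float)
                / ref.loc[common, "relative_quantity"].to_numpy(dtype=float)
            ),
        }
    )
    baseline = ratios[ratios["group"] == baseline_group]
    if baseline.empty:
        raise AnalysisError(f"baseline group {baseline_group!r} is empty for {target_gene!r}")
    ratios["fold"] = ratios["ratio"] / baseline["ratio"].mean()
    ratios.attrs["skipped"] = skipped
    ratios.attrs["target_gene"] = target_gene
    ratios.attrs["reference_gene"] = reference_gene
    ratios.attrs["baseline_group"] = baseline_group
    return ratios
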