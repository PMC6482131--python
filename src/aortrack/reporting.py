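"""Agreement statistics for method-evaluation workflows.

Bland-Altman analysis (mean difference, SD, 95% limits of agreement) and the
two-way mixed-effects, absolute-agreement, single-measure intraclass
correlation coefficient ICC(A,1) — the variant that matters when two
measurement methods must agree in absolute diameter, not merely rank
patients consistently. ``evaluate_agreement`` applies both per landmark to
two batches of diameter reports (observer vs observer, or pipeline vs a
manual-measurement CSV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .measurement import DiameterReport

ICC_VARIANT = "ICC(A,1)"


@dataclass
class AgreementResult:
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    icc: float | None
    n_pairs: int
    points: np.ndarray | None = None  # (n, 2): per-pair (mean, difference)

    def __post_init__(self):
        if self.n_pairs >= 3 and self.icc is not None and not (
            -1.0 < self.icc <= 1.0 + 1e-12
        ):
            raise ValueError(f"ICC out of range: {self.icc}")


def bland_altman(pairs) -> AgreementResult:
    """Mean/SD of paired differences (A - B) and 95% limits of agreement."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need at least 2 (A, B) measurement pairs")
    diff = arr[:, 0] - arr[:, 1]
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementResult(
        mean_difference=mean_diff,
        sd_difference=sd,
        loa_lower=mean_diff - 1.96 * sd,
        loa_upper=mean_diff + 1.96 * sd,
        icc=None,
        n_pairs=len(arr),
        points=np.stack([arr.mean(axis=1), diff], axis=1),
    )


def icc_two_way(pairs) -> float:
    """Two-way mixed-effects, absolute-agreement, single-measure ICC(A,1).

    Standard mean-squares decomposition for n subjects x k raters:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC is undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def evaluate_agreement(
    reports_a: list[DiameterReport],
    reports_b: list[DiameterReport],
    column: str = "baseline_mm",
) -> pd.DataFrame:
    """Per-landmark Bland-Altman + ICC between two batches of paired reports.

    The batches must have equal length and share the landmark vocabulary;
    report ``i`` of batch A is paired with report ``i`` of batch B. ICC is
    reported as NaN when fewer than 3 pairs are available; the ICC variant
    is recorded in every output row.
    """
    if len(reports_a) != len(reports_b):
        raise SchemaError(
            f"report batches differ in length ({len(reports_a)} vs {len(reports_b)})"
        )
    if not reports_a:
        raise SchemaError("empty report batches")

    def landmark_values(report, name):
        rows = report.rows
        sel = rows[rows["landmark"] == name]
        if len(sel) != 1:
            raise SchemaError(f"report is missing landmark {name!r}")
        return float(sel[column].iloc[0])

    names = list(reports_a[0].rows["landmark"])
    for rep in list(reports_a) + list(reports_b):
        if list(rep.rows["landmark"]) != names:
            raise SchemaError("reports do not share the same landmark set")

    records = []
    for name in names:
        a = np.asarray([landmark_values(r, name) for r in reports_a])
        b = np.asarray([landmark_values(r, name) for r in reports_b])
        ok = ~(np.isnan(a) | np.isnan(b))
        pairs = np.stack([a[ok], b[ok]], axis=1)
        if len(pairs) < 2:
            raise SchemaError(f"fewer than 2 valid pairs for landmark {name!r}")
        ba = bland_altman(pairs)
        try:
            icc = icc_two_way(pairs) if len(pairs) >= 3 else float("nan")
        except ValueError:
            icc = 1.0 if np.allclose(pairs[:, 0], pairs[:, 1]) else float("nan")
        records.append({
            "landmark": name,
            "n": ba.n_pairs,
            "mean_difference_mm": ba.mean_difference,
            "sd_difference_mm": ba.sd_difference,
            "loa_lower_mm": ba.loa_lower,
            "loa_upper_mm": ba.loa_upper,
            "icc": icc,
            "icc_variant": ICC_VARIANT,
        })
    return pd.DataFrame.from_records(records)
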