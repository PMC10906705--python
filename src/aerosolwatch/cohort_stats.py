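"""Cohort comparison machinery: exact tests for discrete demographics,
Welch t-tests for continuous ones, and burp-rate standardisation.

The two study arms are compared variable by variable: Fisher's exact
test (two-sided, minimum-likelihood rule) for discrete variables and a
Welch t-test for continuous ones, with burp counts standardised to
events per 20 minutes of procedure time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InferenceError, ValidationError

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "welch_t",
    "burp_rate",
    "cohort_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table; rows are study arms, columns categories."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency table entries must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("contingency table is empty")


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by the minimum-likelihood rule.

    With margins fixed, sums the hypergeometric probability of every
    table whose point probability does not exceed the observed table's
    (evaluated in log space with a small relative slack for ties).
    Degenerate margins (an all-zero row or column) carry no information;
    p = 1 is returned.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(support, n, c1, r1)
    log_obs = logp[a - lo]
    keep = logp <= log_obs + 1e-9  # slack absorbs floating-point ties
    p = float(np.exp(logp[keep]).sum())
    return min(p, 1.0)


def welch_t(group_a, group_b) -> float:
    """Two-sided Welch t-test p-value (Satterthwaite degrees of freedom)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InferenceError(f"each group needs >= 2 values, got {a.size} and {b.size}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else float(np.finfo(float).tiny)
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def burp_rate(annotations, duration_min: float) -> float:
    """Burp events standardised to a 20-minute procedure."""
    if duration_min <= 0:
        raise ValidationError(f"duration_min must be positive, got {duration_min}")
    n = sum(1 for a in annotations if a.label == "burp")
    return n * 20.0 / duration_min


def _arm_records(records, arm):
    return [r for r in records if r.arm == arm]


def cohort_table(records, arm_a: str = "EGD", arm_b: str = "Cytosponge") -> pd.DataFrame:
    """Arm-by-arm cohort summary with p-values.

    Continuous demographics (age, bmi), burp rate and duration are
    compared with Welch t-tests; smoking, sex and throat-spray use with
    Fisher's exact test.  Missing demographic fields are skipped.
    """
    ra, rb = _arm_records(records, arm_a), _arm_records(records, arm_b)
    if len(ra) < 2 or len(rb) < 2:
        raise InferenceError("each arm needs >= 2 procedures for a cohort table")
    rows = []

    def demo(recs, key):
        return np.array(
            [r.demographics[key] for r in recs if key in r.demographics], dtype=float
        )

    rows.append({"variable": "n", "value_a": len(ra), "value_b": len(rb), "p_value": np.nan})
    for key in ("age", "bmi"):
        va, vb = demo(ra, key), demo(rb, key)
        if va.size >= 2 and vb.size >= 2:
            rows.append(
                {
                    "variable": key,
                    "value_a": float(np.median(va)),
                    "value_b": float(np.median(vb)),
                    "p_value": welch_t(va, vb),
                }
            )

    def binary(recs, key, true_value):
        vals = [r.demographics.get(key) for r in recs if key in r.demographics]
        yes = sum(1 for v in vals if v == true_value)
        return yes, len(vals) - yes

    for key, true_value, label in (
        ("smoker", True, "smoking"),
        ("sex", "male", "sex_male"),
    ):
        ya, na = binary(ra, key, true_value)
        yb, nb = binary(rb, key, true_value)
        if ya + na and yb + nb:
            p = fisher_exact_2x2(ContingencyTable2x2(ya, na, yb, nb))
            rows.append({"variable": label, "value_a": ya, "value_b": yb, "p_value": p})

    sa = sum(1 for r in ra if r.used_throat_spray)
    sb = sum(1 for r in rb if r.used_throat_spray)
    p = fisher_exact_2x2(
        ContingencyTable2x2(sa, len(ra) - sa, sb, len(rb) - sb)
    )
    rows.append({"variable": "throat_spray", "value_a": sa, "value_b": sb, "p_value": p})

    for label, getter in (
        ("burp_rate_per_20min", lambda r: burp_rate(r.annotations, r.duration_min)),
        ("duration_min", lambda r: r.duration_min),
    ):
        va = np.array([getter(r) for r in ra])
        vb = np.array([getter(r) for r in rb])
        rows.append(
            {
                "variable": label,
                "value_a": float(va.mean()),
                "value_b": float(vb.mean()),
                "p_value": welch_t(va, vb),
            }
        )
    return pd.DataFrame(rows, columns=["variable", "value_a", "value_b", "p_value"])
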