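"""Cause-of-death misclassification arithmetic.

From suicide counts under the three nested definitions, estimates the
expected number of true suicides by applying literature-derived weights to
the deaths each narrowing step discards (default: 90% of undetermined-intent
and 80% of accidental-poisoning deaths are true suicides), then derives the
positive predictive value of the broad definition and the sensitivity of
the strict one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from ._util import round_half_away
from .errors import ValidationError

DEFAULT_W_UNDETERMINED = 0.90
DEFAULT_W_ACCIDENTAL = 0.80


@dataclass(frozen=True)
class AdjustmentInput:
    n_broad: int
    n_probable: int
    n_strict: int
    w_undetermined: float = DEFAULT_W_UNDETERMINED
    w_accidental: float = DEFAULT_W_ACCIDENTAL

    def __post_init__(self) -> None:
        if not self.n_strict <= self.n_probable <= self.n_broad:
            raise ValidationError(
                f"definition counts must nest: strict {self.n_strict} <= "
                f"probable {self.n_probable} <= broad {self.n_broad}"
            )
        for w in (self.w_undetermined, self.w_accidental):
            if not 0.0 <= w <= 1.0:
                raise ValidationError(f"weight {w} outside [0, 1]")


@dataclass(frozen=True)
class AdjustmentResult:
    input: AdjustmentInput
    n_undetermined: int
    n_accidental: int
    expected_undetermined: int
    expected_accidental: int
    expected_true: int
    ppv_broad_pct: float
    sens_strict_pct: float
    overestimation_pct: float
    underestimation_pct: float

    @property
    def ppv_broad_pct_rounded(self) -> int:
        return int(round_half_away(self.ppv_broad_pct))

    @property
    def sens_strict_pct_rounded(self) -> int:
        return int(round_half_away(self.sens_strict_pct))

    @property
    def overestimation_pct_rounded(self) -> int:
        return int(round_half_away(self.overestimation_pct))

    @property
    def underestimation_pct_rounded(self) -> int:
        return int(round_half_away(self.underestimation_pct))


def adjust(input: AdjustmentInput) -> AdjustmentResult:
    """Weighted-reclassification estimate of true suicides.

    expected_true = n_strict
                    + round(w_undetermined x (n_broad - n_probable))
                    + round(w_accidental x (n_probable - n_strict))

    with half-away-from-zero rounding of each weighted count.  PPV of the
    broad definition = expected_true / n_broad; sensitivity of the strict
    definition = n_strict / expected_true.  Overestimation uses the broad
    count as denominator; underestimation uses the expected-true count.
    """
    n_und = input.n_broad - input.n_probable
    n_acc = input.n_probable - input.n_strict
    exp_und = int(round_half_away(input.w_undetermined * n_und))
    exp_acc = int(round_half_away(input.w_accidental * n_acc))
    expected_true = input.n_strict + exp_und + exp_acc
    ppv = 100.0 * expected_true / input.n_broad if input.n_broad else 100.0
    sens = 100.0 * input.n_strict / expected_true if expected_true else 100.0
    over = 100.0 * (input.n_broad - expected_true) / input.n_broad if input.n_broad else 0.0
    under = 100.0 * (expected_true - input.n_strict) / expected_true if expected_true else 0.0
    return AdjustmentResult(
        input=input,
        n_undetermined=n_und,
        n_accidental=n_acc,
        expected_undetermined=exp_und,
        expected_accidental=exp_acc,
        expected_true=expected_true,
        ppv_broad_pct=ppv,
        sens_strict_pct=sens,
        overestimation_pct=over,
        underestimation_pct=under,
    )


def adjust_from_rates(rate_tables: Mapping[str, pd.DataFrame],
                      *,
                      w_undetermined: float = DEFAULT_W_UNDETERMINED,
                      w_accidental: float = DEFAULT_W_ACCIDENTAL,
                      ) -> dict[str, AdjustmentResult]:
    """Per-cohort adjustment from overall rows of broad/probable/strict
    rate tables computed on the same population."""
    needed = {"broad", "probable", "strict"}
    missing = needed - rate_tables.keys()
    if missing:
        raise ValidationError(f"missing rate tables for definitions: {sorted(missing)}")

    overall = {}
    for name in needed:
        tab = rate_tables[name]
        sub = tab[tab["stratum_variable"] == "overall"]
        overall[name] = dict(zip(sub["cohort"], sub["events"]))
    cohorts = set(overall["broad"])
    if any(set(overall[n]) != cohorts for n in needed):
        raise ValidationError("cohorts differ across definition rate tables")

    return {
        cohort: adjust(AdjustmentInput(
            n_broad=int(overall["broad"][cohort]),
            n_probable=int(overall["probable"][cohort]),
            n_strict=int(overall["strict"][cohort]),
            w_undetermined=w_undetermined,
            w_accidental=w_accidental,
        ))
        for cohort in sorted(cohorts)
    }


def adjustment_report(results: Mapping[str, AdjustmentResult]) -> pd.DataFrame:
    rows = []
    for cohort, r in sorted(results.items()):
        rows.append({
            "cohort": cohort,
            "n_broad": r.input.n_broad,
            "n_probable": r.input.n_probable,
            "n_strict": r.input.n_strict,
            "n_undetermined": r.n_undetermined,
            "n_accidental": r.n_accidental,
            "expected_undetermined": r.expected_undetermined,
            "expected_accidental": r.expected_accidental,
            "expected_true": r.expected_true,
            "ppv_broad_pct": r.ppv_broad_pct_rounded,
            "sens_strict_pct": r.sens_strict_pct_rounded,
            "overestimation_pct": r.overestimation_pct_rounded,
            "underestimation_pct": r.underestimation_pct_rounded,
        })
    return pd.DataFrame(rows)
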