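"""Y-tube olfactometer assay statistics.

Each stimulus is summarised by the count of juveniles that moved along
the tube out of the total tested, and compared against a control arm
(no stimulus) with Fisher's exact test on the 2x2 table

                 moved   not moved
    stimulus       a         b
    control        c         d

Only presence/absence of movement is analysed, not which arm of the Y
the animal chose.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class AssayRecord:
    stimulus: str
    moved: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError(f"assay {self.stimulus!r}: total must be >= 1")
        if not 0 <= self.moved <= self.total:
            raise ValueError(
                f"assay {self.stimulus!r}: moved={self.moved} outside [0, {self.total}]"
            )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts laid out as rows (stimulus, control) x columns (moved, not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")

    @classmethod
    def from_records(cls, stimulus: AssayRecord, control: AssayRecord):
        return cls(
            stimulus.moved, stimulus.total - stimulus.moved,
            control.moved, control.total - control.moved,
        )


def movement_proportion(record: AssayRecord) -> float:
    """Percentage of animals that moved; full precision (round for display)."""
    return 100.0 * record.moved / record.total


def fisher_exact_2x2(table: ContingencyTable2x2):
    """Fisher's exact test, two-sided by the point-probability rule.

    Returns (p_two_sided, odds_ratio).  The two-sided p sums the
    probabilities of every table with the same margins whose conditional
    (hypergeometric) probability does not exceed the observed table's.
    The odds ratio is the sample value a*d / (b*c): infinity when b*c = 0
    with a*d > 0, 0.0 when a*d = 0 with b*c > 0, and NaN when both
    diagonals vanish — never silently clamped.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    p = float(res.pvalue)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return p, odds


@dataclass(frozen=True)
class AssayTestResult:
    stimulus: str
    control: str
    table: ContingencyTable2x2
    percent_moved: float
    p_value: float
    odds_ratio: float
    alpha: float
    significant: bool


def assay_vs_control(
    stimulus: AssayRecord, control: AssayRecord, alpha: float = 0.05
) -> AssayTestResult:
    """Fisher test of one stimulus record against an explicit control.

    A control record must always be supplied — there is no default
    control movement rate.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    table = ContingencyTable2x2.from_records(stimulus, control)
    p, odds = fisher_exact_2x2(table)
    return AssayTestResult(
        stimulus=stimulus.stimulus, control=control.stimulus, table=table,
        percent_moved=movement_proportion(stimulus),
        p_value=p, odds_ratio=odds, alpha=alpha, significant=p < alpha,
    )
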