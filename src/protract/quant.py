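"""Western-blot normalization, group comparison, and qPCR relative expression.

Blot normalization follows the per-blot ratio convention: each lane's
test-antibody signal is divided by the blot-wide mean of that antibody,
then corrected by the identically normalized loading-control signal,

    ab_ratio_i = (Tab_i / mean Tab) / (Cab_i / mean Cab)
               = (Tab_i * mean Cab) / (mean Tab * Cab_i),

with means taken across all lanes of the same blot. The blot is the
normalization unit; blots are never pooled. For hypusination, total eIF5A
serves as the loading control of the hypusine signal, since hypusine is
carried exclusively by eIF5A.

Group comparisons use the Student (pooled-variance) unpaired t-test by
default; Welch's variant is available behind a flag. qPCR expression is
relative quantification 2^-dCT against a reference gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class BlotTable:
    """Lane-by-antibody fluorescence signals for one blot.

    ``signals`` maps antibody name -> per-lane values aligned with
    ``lanes``. All signals must be positive (background-subtracted
    upstream) and both the test and control antibody must be present for
    every lane.
    """

    lanes: tuple[str, ...]
    signals: Mapping[str, tuple[float, ...]]
    test_antibody: str
    control_antibody: str

    def __post_init__(self) -> None:
        if len(self.lanes) < 2:
            raise ValueError("a blot needs at least 2 lanes to define blot means")
        if len(set(self.lanes)) != len(self.lanes):
            raise ValueError("lane labels must be unique")
        for ab in (self.test_antibody, self.control_antibody):
            if ab not in self.signals:
                raise ValueError(f"antibody {ab!r} missing from signals")
            values = self.signals[ab]
            if len(values) != len(self.lanes):
                raise ValueError(
                    f"antibody {ab!r}: {len(values)} values for {len(self.lanes)} lanes"
                )
            for lane, v in zip(self.lanes, values):
                if not np.isfinite(v) or v <= 0:
                    raise ValueError(
                        f"non-positive signal for antibody {ab!r} in lane {lane!r}: {v}"
                    )

    def test_values(self) -> np.ndarray:
        return np.asarray(self.signals[self.test_antibody], dtype=float)

    def control_values(self) -> np.ndarray:
        return np.asarray(self.signals[self.control_antibody], dtype=float)


@dataclass(frozen=True)
class NormalizedRatio:
    """One lane's dimensionless ab-ratio."""

    lane: str
    ratio: float


@dataclass(frozen=True)
class ExpressionResult:
    """Relative expression of one sample: dCT and 2^-dCT."""

    sample: str
    delta_ct: float
    rel_expr: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rel_expr", 2.0 ** (-self.delta_ct))


def normalize_blot(table: BlotTable) -> list[NormalizedRatio]:
    """Per-lane ab-ratios for one blot.

    ratio_i = (Tab_i * mean(Cab)) / (mean(Tab) * Cab_i). Both channel
    means are computed over all lanes of this blot, so the ratios are
    invariant to rescaling either whole channel (exposure changes) and
    the test channel averages to 1 across the blot before the control
    correction.
    """
    tab = table.test_values()
    cab = table.control_values()
    ratios = (tab * cab.mean()) / (tab.mean() * cab)
    return [NormalizedRatio(lane, float(r)) for lane, r in zip(table.lanes, ratios)]


def hypusination_ratio(table: BlotTable) -> list[NormalizedRatio]:
    """Hypusination level per lane: hypusine normalized to total eIF5A.

    Identical arithmetic to :func:`normalize_blot` with the antibody roles
    fixed — the hypusine signal is the test antibody and total eIF5A its
    control.
    """
    return normalize_blot(table)


def unpaired_t_test(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; returns ``(t, p, df)``.

    Student's pooled-variance test by default; set ``welch=True`` for the
    unequal-variance variant. Degenerate inputs: if both groups are
    constant with equal means the result is ``(0, 1, df)``; constant
    groups with unequal means have no defined t statistic and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return 0.0, 1.0, df
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue), float(res.df)


def relative_expression(
    ct_target: float, ct_reference: float, sample: str = ""
) -> ExpressionResult:
    """Relative expression 2^-dCT with dCT = CT_target - CT_reference."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError(
            f"CT values must be finite, got target={ct_target}, reference={ct_reference}"
        )
    return ExpressionResult(sample=sample, delta_ct=float(ct_target - ct_reference))
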