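"""Cost-effectiveness metrics: CER, ICER, net monetary benefit, dominance.

The incremental cost-effectiveness ratio (ICER) is the cost difference
divided by the QALY difference between the comparator of interest and the
reference strategy. A comparator that is both cheaper and more effective is
*dominant*; following the source's reporting style, the signed (negative)
ratio is still reported alongside the label. Net monetary benefit at a
willingness-to-pay threshold w is ``w * effect - cost``; the strategy with
the higher NMB is cost-effective at that threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: per-capita GDP of China in 2021, ¥ (the WTP anchor used in the analysis)
GDP_PER_CAPITA_2021 = 80_976.0


def wtp_threshold(gdp_per_capita: float = GDP_PER_CAPITA_2021, multiplier: float = 3.0) -> float:
    """Willingness-to-pay threshold, ¥ per QALY (default 3x per-capita GDP)."""
    if gdp_per_capita <= 0 or multiplier <= 0:
        raise ValueError("wtp_threshold requires positive inputs")
    return gdp_per_capita * multiplier


def net_monetary_benefit(cost: float, effect: float, wtp: float) -> float:
    """``wtp * effect - cost`` (¥); higher is better at the given threshold."""
    return wtp * effect - cost


@dataclass
class CEResult:
    """Pairwise cost-effectiveness comparison.

    Deltas are comparator minus reference. ``icer`` is ``nan`` when the
    effect difference is zero (labelled ``undefined``); a dominant comparator
    (cheaper, more effective) keeps its signed negative ratio plus the label.
    """

    reference_name: str
    comparator_name: str
    reference: tuple[float, float]  # (cost ¥, effect QALY)
    comparator: tuple[float, float]
    delta_cost: float = field(init=False)
    delta_effect: float = field(init=False)
    icer: float = field(init=False)
    label: str = field(init=False, default="")

    def __post_init__(self) -> None:
        for value in (*self.reference, *self.comparator):
            if not math.isfinite(value):
                raise ValueError("costs and effects must be finite")
        self.delta_cost = self.comparator[0] - self.reference[0]
        self.delta_effect = self.comparator[1] - self.reference[1]
        if self.delta_effect == 0.0:
            self.icer = math.nan
            self.label = "undefined" if self.delta_cost != 0.0 else "equivalent"
        else:
            self.icer = self.delta_cost / self.delta_effect
            if self.delta_cost <= 0.0 and self.delta_effect > 0.0:
                self.label = "dominant"
            elif self.delta_cost >= 0.0 and self.delta_effect < 0.0:
                self.label = "dominated"

    def cer(self, which: str) -> float:
        """Average cost-effectiveness ratio (¥/QALY) of one strategy."""
        cost, effect = self._totals(which)
        return cost / effect if effect != 0.0 else math.nan

    def nmb(self, which: str, wtp: float) -> float:
        cost, effect = self._totals(which)
        return net_monetary_benefit(cost, effect, wtp)

    def comparator_cost_effective(self, wtp: float) -> bool:
        """Whether the comparator has the higher net monetary benefit at ``wtp``."""
        return self.nmb(self.comparator_name, wtp) > self.nmb(self.reference_name, wtp)

    def _totals(self, which: str) -> tuple[float, float]:
        if which == self.reference_name:
            return self.reference
        if which == self.comparator_name:
            return self.comparator
        raise KeyError(f"unknown strategy {which!r}")

    def to_rows(self) -> list[dict]:
        """Two report rows mirroring the published table layout.

        Currency rounds to integer ¥, QALYs to 0.1, ratio cells to integer
        ¥/QALY; internal arithmetic stays full precision.
        """
        ref_cost, ref_eff = self.reference
        comp_cost, comp_eff = self.comparator
        return [
            {
                "strategy": self.reference_name,
                "cost": round(ref_cost),
                "delta_cost": None,
                "effect": round(ref_eff, 1),
                "delta_effect": None,
                "cer": round(self.cer(self.reference_name)),
                "icer": None,
                "label": "",
            },
            {
                "strategy": self.comparator_name,
                "cost": round(comp_cost),
                "delta_cost": round(self.delta_cost),
                "effect": round(comp_eff, 1),
                "delta_effect": round(self.delta_effect, 1),
                "cer": round(self.cer(self.comparator_name)),
                "icer": None if math.isnan(self.icer) else round(self.icer),
                "label": self.label,
            },
        ]


def compute_icer(
    reference: tuple[float, float],
    comparator: tuple[float, float],
    reference_name: str = "ES",
    comparator_name: str = "AS",
) -> CEResult:
    """Incremental comparison of two (cost ¥, effect QALY) pairs."""
    return CEResult(
        reference_name=reference_name,
        comparator_name=comparator_name,
        reference=(float(reference[0]), float(reference[1])),
        comparator=(float(comparator[0]), float(comparator[1])),
    )
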