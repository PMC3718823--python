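"""Subjective value, discounting AUC, workload composite, amount effects.

An indifference amount divided by its base offer gives the relative
subjective value SV in [0, 1] -- the fraction of reward value surviving
the effort (or delay) cost.  A participant's SV curve over load levels (or
delays) is summarised atheoretically by the trapezoid area under the curve
on an x-axis normalized to unit width, so AUC = 1 means no discounting.

The NASA Task Load Index (NTLX) composite is the unweighted mean of the
per-scale trapezoid AUCs over the normalized level axis, kept in raw 0-21
rating units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SVCurve",
    "AucResult",
    "NTLX_SCALES",
    "DELAY_DAYS",
    "EFFORT_AUC_LEVELS",
    "subjective_value",
    "extra_payment",
    "discount_auc",
    "ntlx_composite",
    "amount_effect",
    "sv_table",
    "plot_sv_curves",
]

#: The six NASA-TLX workload scales (ratings 0-21).
NTLX_SCALES: tuple[str, ...] = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "failure",
    "effort",
    "frustration",
)

#: Calendar delays in days: 1 week, 6 months, 1, 3, 5, 10 years.
DELAY_DAYS: tuple[float, ...] = (7.0, 182.5, 365.0, 1095.0, 1825.0, 3650.0)

#: Load levels entering the effort-discounting AUC (common basis for both
#: age groups).
EFFORT_AUC_LEVELS: tuple[int, ...] = (2, 3, 4)


@dataclass(frozen=True)
class SVCurve:
    """Relative subjective values for one participant and base amount.

    ``points`` maps condition (load level N or delay in days) -> SV;
    conditions are kept sorted ascending.
    """

    participant_id: Hashable
    base_amount: float
    points: Mapping[Hashable, float]
    domain: str = "effort"  # "effort" | "delay"

    def __post_init__(self):
        object.__setattr__(
            self, "points", dict(sorted(dict(self.points).items()))
        )

    @property
    def conditions(self) -> tuple:
        return tuple(self.points)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(self.points.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "domain": self.domain,
                "base_amount": self.base_amount,
                "condition": list(self.conditions),
                "sv": list(self.values),
            }
        )


@dataclass(frozen=True)
class AucResult:
    """Discounting area under the curve for one participant/amount."""

    participant_id: Hashable
    base_amount: float
    auc: float
    conditions_used: tuple
    domain: str = "effort"


def subjective_value(indifference: float, base: float) -> float:
    """Relative subjective value: indifference amount / base amount.

    E.g. a $0.98 indifference point on a $2.00 base gives SV = 0.49.
    """
    if base <= 0:
        raise ValueError(f"base amount must be positive, got {base}")
    return indifference / base


def extra_payment(sv: float, base: float) -> float:
    """Premium demanded for the hard option: base * (1 - SV).

    A participant with SV = 0.49 on a $2.00 base requires an additional
    $1.02 to perform the harder task instead of the easiest one.
    """
    if not 0 <= sv <= 1:
        raise ValueError(f"sv must be in [0, 1], got {sv}")
    return base * (1.0 - sv)


def _normalized_x(x: np.ndarray) -> np.ndarray:
    span = x[-1] - x[0]
    if span <= 0:
        raise ValueError("x coordinates must be strictly increasing")
    return (x - x[0]) / span


def discount_auc(
    curve: SVCurve,
    x_spec: Mapping[Hashable, float] | None = None,
    conditions: Iterable[Hashable] | None = None,
) -> AucResult:
    """Trapezoid AUC of an SV curve over the normalized x-axis.

    The x-axis (load level for effort, days for delay) is rescaled to
    [0, 1] before integration, so a flat SV = 1 curve scores exactly 1 and
    the AUC is invariant to affine rescaling of the raw coordinates.

    Parameters
    ----------
    curve : SVCurve
    x_spec : mapping, optional
        condition -> raw x coordinate; defaults to the condition values
        themselves (levels 2-4 for effort, days for delay).
    conditions : iterable, optional
        Subset of conditions to use (default: effort curves restrict to
        levels 2-4 when available; delay curves use all points).
    """
    if conditions is None:
        if curve.domain == "effort":
            avail = [c for c in EFFORT_AUC_LEVELS if c in curve.points]
            conditions = avail if len(avail) >= 2 else list(curve.conditions)
        else:
            conditions = list(curve.conditions)
    else:
        conditions = list(conditions)
    if len(conditions) < 2:
        raise ValueError(
            f"need >= 2 SV points for an AUC, have {len(conditions)}"
        )
    missing = [c for c in conditions if c not in curve.points]
    if missing:
        raise ValueError(f"conditions missing from curve: {missing}")
    x = np.array(
        [float(x_spec[c]) if x_spec is not None else float(c) for c in conditions]
    )
    if np.any(np.diff(x) <= 0):
        raise ValueError("x coordinates must be strictly increasing")
    y = np.array([curve.points[c] for c in conditions], dtype=float)
    auc = float(np.trapezoid(y, _normalized_x(x)))
    return AucResult(
        participant_id=curve.participant_id,
        base_amount=curve.base_amount,
        auc=auc,
        conditions_used=tuple(conditions),
        domain=curve.domain,
    )


def ntlx_composite(
    scores: Mapping[str, Mapping[Hashable, float]],
    scales: Sequence[str] = NTLX_SCALES,
) -> float:
    """Workload composite: mean of per-scale trapezoid AUCs over levels.

    Each scale's ratings (0-21) are integrated over the normalized level
    axis and the per-scale AUCs are averaged without weighting, so the
    composite stays in rating units (constant ratings of r give exactly r).

    Raises a ``KeyError`` naming any scale that is missing -- no silent
    imputation.
    """
    missing = [s for s in scales if s not in scores]
    if missing:
        raise KeyError(f"missing NTLX scales: {missing}")
    aucs = []
    for scale in scales:
        pts = dict(sorted(scores[scale].items()))
        if len(pts) < 2:
            raise ValueError(f"scale {scale!r} needs >= 2 levels, has {len(pts)}")
        ratings = np.array(list(pts.values()), dtype=float)
        if np.any(ratings < 0) or np.any(ratings > 21):
            raise ValueError(f"scale {scale!r} has ratings outside [0, 21]")
        x = _normalized_x(np.array(list(pts), dtype=float))
        aucs.append(float(np.trapezoid(ratings, x)))
    return float(np.mean(aucs))


def amount_effect(
    curves: Iterable[tuple[SVCurve, SVCurve]] | pd.DataFrame,
) -> dict:
    """Paired amount-effect summary across two base amounts.

    Accepts pairs of SV curves per participant (small base first) or a
    tidy frame with columns (participant_id, base_amount, condition, sv).
    Reports per-amount mean AUC, the paired Wilcoxon signed-rank p, and
    per-condition mean discounted dollar values with their decrements
    (base - discounted value).  Participants lacking either amount are
    dropped with a warning.
    """
    if isinstance(curves, pd.DataFrame):
        curves = _pair_curves(curves)
    pairs = list(curves)
    if not pairs:
        raise ValueError("no curve pairs supplied")
    lo_amt = pairs[0][0].base_amount
    hi_amt = pairs[0][1].base_amount
    auc_lo = np.array([discount_auc(lo).auc for lo, _ in pairs])
    auc_hi = np.array([discount_auc(hi).auc for _, hi in pairs])
    diffs = auc_hi - auc_lo
    if np.allclose(diffs, 0):
        p = float("nan")  # signed-rank undefined on all-zero differences
    else:
        p = float(stats.wilcoxon(auc_hi, auc_lo).pvalue)

    per_condition = {}
    conds = sorted(set().union(*(set(lo.conditions) for lo, _ in pairs)))
    for c in conds:
        lo_vals = [lo.points[c] * lo.base_amount for lo, _ in pairs if c in lo.points]
        hi_vals = [hi.points[c] * hi.base_amount for _, hi in pairs if c in hi.points]
        per_condition[c] = {
            "mean_discounted_value": {
                lo_amt: float(np.mean(lo_vals)),
                hi_amt: float(np.mean(hi_vals)),
            },
            "decrement": {
                lo_amt: lo_amt - float(np.mean(lo_vals)),
                hi_amt: hi_amt - float(np.mean(hi_vals)),
            },
        }
    return {
        "mean_auc": {lo_amt: float(auc_lo.mean()), hi_amt: float(auc_hi.mean())},
        "mean_difference": float(diffs.mean()),
        "wilcoxon_p": p,
        "n_pairs": len(pairs),
        "per_condition": per_condition,
    }


def _pair_curves(df: pd.DataFrame) -> list[tuple[SVCurve, SVCurve]]:
    amounts = sorted(df["base_amount"].unique())
    if len(amounts) != 2:
        raise ValueError(f"expected exactly 2 base amounts, got {amounts}")
    domain = df["domain"].iloc[0] if "domain" in df else "effort"
    pairs = []
    for pid, grp in df.groupby("participant_id"):
        present = set(grp["base_amount"])
        if not set(amounts) <= present:
            warnings.warn(
                f"participant {pid!r} lacks one base amount; dropped from "
                "amount-effect pairing"
            )
            continue
        curves = []
        for a in amounts:
            sub = grp[grp["base_amount"] == a]
            curves.append(
                SVCurve(
                    participant_id=pid,
                    base_amount=a,
                    points=dict(zip(sub["condition"], sub["sv"])),
                    domain=domain,
                )
            )
        pairs.append(tuple(curves))
    return pairs


def sv_table(curves: Iterable[SVCurve]) -> pd.DataFrame:
    """Stack SV curves into the tidy long CSV schema."""
    frames = [c.to_frame() for c in curves]
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "domain", "base_amount", "condition", "sv"]
        )
    return pd.concat(frames, ignore_index=True)


def plot_sv_curves(curves: Iterable[SVCurve], ax=None, **plot_kw):
    """Basic SV-by-condition line plot (one line per curve)."""
    import matplotlib.pyplot as plt

    curves = list(curves)
    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        ax.plot(c.conditions, c.values, marker="o", **plot_kw)
    domain = curves[0].domain if curves else "effort"
    ax.set_xlabel("load level N" if domain == "effort" else "delay (days)")
    ax.set_ylabel("subjective value (fraction of base)")
    ax.set_ylim(-0.02, 1.02)
    return ax
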