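"""Reaction-time cleaning and attentional-bias indices for the dot-probe task.

Bias indices (all in milliseconds, computed from condition-mean RTs of
correct, outlier-cleaned trials):

    BI = meanRT(incongruent) - meanRT(congruent)     bias index
    OI = meanRT(neutral)     - meanRT(congruent)     orienting index
    DI = meanRT(incongruent) - meanRT(neutral)       disengagement index

so that BI = OI + DI holds exactly by construction. Positive BI indicates
vigilance toward the emotional face (faster when the probe replaces it).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["RTCleaningResult", "BiasIndices", "clean_rts", "bias_indices"]


@dataclass
class RTCleaningResult:
    """Filtered trial table plus removal bookkeeping."""

    trials: pd.DataFrame
    n_in: int
    n_removed_incorrect: int
    n_removed_outlier: int

    @property
    def n_kept(self) -> int:
        return len(self.trials)

    @property
    def empty(self) -> bool:
        """True when cleaning removed every trial (explicit signal, not a crash)."""
        return self.n_kept == 0


@dataclass
class BiasIndices:
    bi: float
    oi: float
    di: float
    n_used: dict[str, int]


def clean_rts(trials: pd.DataFrame, sd_multiplier: float = 2.5) -> RTCleaningResult:
    """Remove incorrect trials, then RT outliers beyond ±``sd_multiplier`` SD.

    The mean and SD are computed once, per subject, over the remaining
    correct trials (single pass — the criterion is not re-applied after
    removal). A zero SD (all RTs identical) excludes nothing. An input on
    which every trial is removed yields an empty ``RTCleaningResult``.
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    correct = trials[trials["correct"].astype(bool)]
    n_incorrect = len(trials) - len(correct)
    if len(correct) == 0:
        return RTCleaningResult(trials=correct.copy(), n_in=len(trials),
                                n_removed_incorrect=n_incorrect,
                                n_removed_outlier=0)
    mean = correct["rt"].mean()
    sd = correct["rt"].std(ddof=1) if len(correct) > 1 else 0.0
    if sd > 0:
        keep = (correct["rt"] - mean).abs() <= sd_multiplier * sd
    else:
        keep = pd.Series(True, index=correct.index)
    kept = correct[keep]
    return RTCleaningResult(
        trials=kept.copy(), n_in=len(trials),
        n_removed_incorrect=n_incorrect,
        n_removed_outlier=int((~keep).sum()))


def bias_indices(trials: pd.DataFrame) -> BiasIndices:
    """Compute BI, OI, DI from a cleaned trial table.

    Raises ``ValueError`` naming the first condition with no trials.
    """
    means: dict[str, float] = {}
    n_used: dict[str, int] = {}
    for cond in ("congruent", "incongruent", "neutral"):
        sub = trials[trials["condition"] == cond]
        if len(sub) == 0:
            raise ValueError(f"no trials in condition {cond!r}")
        means[cond] = float(sub["rt"].mean())
        n_used[cond] = len(sub)
    oi = means["neutral"] - means["congruent"]
    di = means["incongruent"] - means["neutral"]
    # BI computed as OI + DI so the additivity identity is exact in floating
    # point; algebraically identical to incongruent - congruent.
    return BiasIndices(bi=oi + di, oi=oi, di=di, n_used=n_used)
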