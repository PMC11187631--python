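"""Weighted consensus of the binary, multiclass and regression predictions.

Each model's label is encoded to a potency level (nonblocker 0, weak 1,
moderate/weak 2, strong 3; a binary "blocker" counts as level 3).  The
binary model carries weight 0.6; the multiclass and regression models carry
0.2 each when their blocker/nonblocker dichotomy agrees with the binary
call and 0.1 when it does not.  The weighted sum is thresholded at 2:

    score = 0.6 * L_bin + w_m * L_multi + w_r * L_reg
    call  = blocker  iff  score >= 2

so a lone binary "blocker" (score 1.8) is not enough — some support from
an auxiliary model is required.  Cohen's kappa quantifies pairwise model
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import cohen_kappa_score

REGRESSION_LABELS = ("strong", "moderate", "weak", "nonblocker")

DEFAULT_LEVELS = {
    "nonblocker": 0,
    "weak": 1,
    "moderate": 2,        # regression tier, same rung as multiclass moderate_weak
    "moderate_weak": 2,
    "strong": 3,
    "binary_blocker": 3,
}


@dataclass(frozen=True)
class ConsensusConfig:
    w_binary: float = 0.6
    w_agree: float = 0.2
    w_disagree: float = 0.1
    threshold: float = 2.0
    level_encoding: dict = field(default_factory=lambda: dict(DEFAULT_LEVELS))

    def __post_init__(self):
        if not (self.w_binary > self.w_agree > self.w_disagree > 0):
            raise ValueError("weights must satisfy w_binary > w_agree > w_disagree > 0")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class ConsensusResult:
    score: float
    call: str                      # blocker | nonblocker
    binary_label: str
    multiclass_label: str
    regression_label: str
    multiclass_agrees: bool
    regression_agrees: bool


def regression_to_label(pic50: float) -> str:
    """Map a predicted pIC50 to the four-level potency label.

    strong: pIC50 >= 6; moderate: [5, 6); weak: [4.5, 5); nonblocker: < 4.5.
    """
    if not np.isfinite(pic50):
        raise ValueError("pIC50 must be finite")
    if pic50 >= 6.0:
        return "strong"
    if pic50 >= 5.0:
        return "moderate"
    if pic50 >= 4.5:
        return "weak"
    return "nonblocker"


def _is_blocker(label: str) -> bool:
    """Collapse any label to the blocker/nonblocker dichotomy."""
    return label != "nonblocker"


def consensus_score(binary_label: str, multiclass_label: str,
                    regression_label: str,
                    config: ConsensusConfig | None = None) -> ConsensusResult:
    """Weighted consensus call from the three per-model labels.

    ``binary_label`` in {blocker, nonblocker}; ``multiclass_label`` in
    {strong, moderate_weak, nonblocker}; ``regression_label`` in
    {strong, moderate, weak, nonblocker} (see :func:`regression_to_label`).
    """
    cfg = config or ConsensusConfig()
    enc = cfg.level_encoding
    if binary_label == "blocker":
        l_bin = enc["binary_blocker"]
    elif binary_label == "nonblocker":
        l_bin = enc["nonblocker"]
    else:
        raise ValueError(f"unknown binary label {binary_label!r}")
    try:
        l_multi = enc[multiclass_label]
        l_reg = enc[regression_label]
    except KeyError as exc:
        raise ValueError(f"unknown label token {exc.args[0]!r}") from None

    bin_blocker = _is_blocker(binary_label)
    m_agrees = _is_blocker(multiclass_label) == bin_blocker
    r_agrees = _is_blocker(regression_label) == bin_blocker
    w_m = cfg.w_agree if m_agrees else cfg.w_disagree
    w_r = cfg.w_agree if r_agrees else cfg.w_disagree
    score = cfg.w_binary * l_bin + w_m * l_multi + w_r * l_reg
    # call = blocker iff score >= threshold; the slack absorbs float
    # round-off in the weighted sum (0.6*3 + 0.2 lands one ulp below 2)
    call = "blocker" if score >= cfg.threshold - 1e-9 else "nonblocker"
    return ConsensusResult(
        score=float(score), call=call,
        binary_label=binary_label, multiclass_label=multiclass_label,
        regression_label=regression_label,
        multiclass_agrees=m_agrees, regression_agrees=r_agrees,
    )


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two label assignments.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected
    agreement.  Raises when expected agreement is 1 (kappa undefined).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length label vectors of length >= 2")
    classes = np.unique(np.concatenate([a, b]))
    p_e = sum(
        np.mean(a == c) * np.mean(b == c) for c in classes
    )
    if p_e >= 1.0 - 1e-15:
        raise ValueError("expected agreement is 1: kappa undefined")
    return float(cohen_kappa_score(a, b))
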