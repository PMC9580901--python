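"""Meta-prediction: combine the SVM/RF/NN outputs for one protein.

Three rules are provided:

* **jury vote** — the majority class of the three classifiers;
* **consensus** — the posterior-weighted sum ``c = Σ p_i · class_i`` with
  ``class_i ∈ {−1, +1}`` and ``p_i`` the posterior of the predicted class;
  positive iff c > 0 (a tie at exactly 0 is conservatively negative);
* **red flag** — on a 2–1 split the minority class wins (it surfaces the
  dissenting opinion); unanimity returns the unanimous class.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ClassifierPrediction:
    """One classifier's verdict: kind, class in {-1, +1}, and the posterior
    probability of the *predicted* class (hence >= 0.5)."""

    kind: str  # "SVM" | "RF" | "NN"
    cls: int
    posterior: float

    def __post_init__(self) -> None:
        if self.cls not in (-1, 1):
            raise ValueError("class must be -1 or +1")
        if not 0.5 <= self.posterior <= 1.0 + 1e-12:
            raise ValueError("posterior of the predicted class must lie in [0.5, 1]")


@dataclass
class VotingResult:
    jury_class: int
    consensus_score: float
    consensus_class: int
    redflag_class: int


def _check_triple(preds: list[ClassifierPrediction]) -> list[ClassifierPrediction]:
    if len(preds) != 3:
        raise ValueError("exactly three classifier predictions required")
    kinds = sorted(p.kind for p in preds)
    if kinds != ["NN", "RF", "SVM"]:
        raise ValueError(f"need one prediction per kind (SVM, RF, NN); got {kinds}")
    return preds


def jury_vote(preds: list[ClassifierPrediction]) -> int:
    """Majority class of the three classifiers."""
    preds = _check_triple(preds)
    total = sum(p.cls for p in preds)
    return 1 if total > 0 else -1


def consensus(preds: list[ClassifierPrediction]) -> tuple[float, int]:
    """Posterior-weighted consensus score and its class."""
    preds = _check_triple(preds)
    c = sum(p.posterior * p.cls for p in preds)
    return c, (1 if c > 0 else -1)


def red_flag(preds: list[ClassifierPrediction]) -> int:
    """Minority class on a 2-1 split; the unanimous class otherwise."""
    preds = _check_triple(preds)
    total = sum(p.cls for p in preds)
    if total in (3, -3):
        return preds[0].cls
    return -1 if total > 0 else 1


def vote(preds: list[ClassifierPrediction]) -> VotingResult:
    """All three voting rules at once."""
    score, c_cls = consensus(preds)
    return VotingResult(
        jury_class=jury_vote(preds),
        consensus_score=score,
        consensus_class=c_cls,
        redflag_class=red_flag(preds),
    )
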