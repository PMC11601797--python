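"""Early-recognition metrics for virtual screening.

In a prospective screen only the top of the ranked list is ever
purchased or synthesized, so overall ROC-AUC is a poor guide.  This
module implements the four metrics that reward placing actives early:

- ``logauc_range`` — ROC area on a logarithmic FPR axis over a
  restricted range (default [0.001, 0.1]), normalized by the log-range
  so a perfect ranking scores 1 and a score-independent one about
  0.099/(2 ln 10) ≈ 0.0215;
- ``bedroc`` — Boltzmann-enhanced discrimination of ROC
  (Truchon & Bailey), exponentially weighted over active ranks;
- ``enrichment_factor`` — active fraction in the top-k selection over
  the library's active fraction;
- ``dcg_at_k`` — discounted cumulative gain with binary relevance.

All four are invariant to strictly monotone transformations of the
scores because they only consume the induced ranking (logAUC uses the
tie-grouped ROC curve, where tied scores form a single diagonal
segment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

LN10 = np.log(10.0)


@dataclass(frozen=True)
class MetricConfig:
    """Evaluation settings.

    Parameters
    ----------
    fpr_lo, fpr_hi
        False-positive-rate window for the logarithmic ROC area
        (defaults 0.001 and 0.1).
    alpha
        BEDROC early-recognition exponent (default 20.0, the community
        convention: ~80% of the score from the top 1/alpha of the list).
    k
        Selection-set size for the enrichment factor and DCG
        (default 100).
    """

    fpr_lo: float = 0.001
    fpr_hi: float = 0.1
    alpha: float = 20.0
    k: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.fpr_lo < self.fpr_hi <= 1:
            raise ValueError("need 0 < fpr_lo < fpr_hi <= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class MetricReport:
    """The four early-recognition metric values for one ranking."""

    logauc: float
    bedroc: float
    ef_k: float
    dcg_k: float

    def as_dict(self) -> dict[str, float]:
        return {"logauc": self.logauc, "bedroc": self.bedroc,
                "ef_k": self.ef_k, "dcg_k": self.dcg_k}


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D and equal length")
    if labels.size == 0:
        raise ValueError("empty input")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if np.isnan(scores).any():
        raise ValueError("NaN score")
    return labels.astype(int), scores


def _require_both_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("degenerate-labels: need at least one active "
                         "and one inactive")


def rank_by_score(labels, scores, tie_policy: str = "input_order"
                  ) -> np.ndarray:
    """Permutation of indices ordering compounds best-first.

    A stable descending sort; tied scores keep input order under the
    default policy (with a logged warning), or place actives last
    within the tie block under ``"average_pessimistic"`` for
    conservative audits.
    """
    labels, scores = _validate(labels, scores)
    if tie_policy not in ("input_order", "average_pessimistic"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    n = scores.size
    has_ties = np.unique(scores).size < n
    if has_ties and tie_policy == "input_order":
        warnings.warn("tied scores broken by input order")
    if tie_policy == "average_pessimistic":
        # within a tie block actives sink below inactives
        order = np.lexsort((np.arange(n), labels, -scores))
    else:
        order = np.lexsort((np.arange(n), -scores))
    return order


def _ranked_labels(labels, scores, tie_policy: str) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    return labels[rank_by_score(labels, scores, tie_policy)]


def logauc_range(labels, scores, config: MetricConfig | None = None) -> float:
    """ROC area on a log10 FPR axis over [fpr_lo, fpr_hi], normalized.

    The ROC curve is built with tie-grouped thresholds (tied scores form
    one straight segment, so a score-independent classifier yields the
    identity ROC).  TPR is linearly interpolated at the window
    boundaries and each linear-in-FPR segment is integrated against
    d(log10 FPR) in closed form:

        ∫ (a + b·f) dlog10 f = a·log10 f + b·f/ln 10.

    Normalization divides by log10(fpr_hi/fpr_lo) (= 2 for the default
    window), so a perfect ranking scores 1 and the identity ROC scores
    (fpr_hi − fpr_lo)/(ln 10 · log10(fpr_hi/fpr_lo)) ≈ 0.0215.
    """
    if config is None:
        config = MetricConfig()
    labels, scores = _validate(labels, scores)
    _require_both_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)

    lo, hi = config.fpr_lo, config.fpr_hi
    area = 0.0
    for (f0, t0), (f1, t1) in zip(zip(fpr, tpr), zip(fpr[1:], tpr[1:])):
        seg_lo, seg_hi = max(f0, lo), min(f1, hi)
        if seg_hi <= seg_lo:
            continue
        if f1 > f0:
            b = (t1 - t0) / (f1 - f0)
            a = t0 - b * f0
            area += (a * np.log10(seg_hi / seg_lo)
                     + b * (seg_hi - seg_lo) / LN10)
        # vertical segments (f1 == f0) have zero width on the FPR axis
    return float(area / np.log10(hi / lo))


def bedroc(labels, scores, config: MetricConfig | None = None,
           tie_policy: str = "input_order") -> float:
    """Truchon–Bailey BEDROC with exponent ``alpha`` over active ranks.

    With n compounds, m actives at ranks r_i (1-based, best first),
    Ra = m/n and α = ``config.alpha``:

        RIE    = (Σ_i exp(−α·r_i/n)) / (Ra·(1 − e^{−α})/(e^{α/n} − 1))
        BEDROC = RIE·Ra·sinh(α/2) / (cosh(α/2) − cosh(α/2 − α·Ra))
                 + 1 / (1 − e^{α(1−Ra)})

    Bounded in [0, 1]; 1 means all actives lead the list.
    """
    if config is None:
        config = MetricConfig()
    ranked = _ranked_labels(labels, scores, tie_policy)
    _require_both_classes(ranked)
    n = ranked.size
    m = int(ranked.sum())
    alpha = config.alpha
    ra = m / n
    ranks = np.flatnonzero(ranked == 1) + 1
    s = np.exp(-alpha * ranks / n).sum()
    rie = s / (ra * (1 - np.exp(-alpha)) / (np.exp(alpha / n) - 1))
    value = (rie * ra * np.sinh(alpha / 2)
             / (np.cosh(alpha / 2) - np.cosh(alpha / 2 - alpha * ra))
             + 1 / (1 - np.exp(alpha * (1 - ra))))
    return float(min(1.0, max(0.0, value)))


def enrichment_factor(labels, scores, config: MetricConfig | None = None,
                      tie_policy: str = "input_order") -> float:
    """EF_k: active fraction in the top k over the library fraction.

        EF_k = (actives in top k / k) / (n_actives / n)

    Requires n ≥ k and at least one active.
    """
    if config is None:
        config = MetricConfig()
    ranked = _ranked_labels(labels, scores, tie_policy)
    n = ranked.size
    m = int(ranked.sum())
    if m == 0:
        raise ValueError("degenerate-labels: no actives")
    if n < config.k:
        raise ValueError("list-shorter-than-k")
    hits = int(ranked[:config.k].sum())
    return float((hits / config.k) / (m / n))


def dcg_at_k(labels, scores, config: MetricConfig | None = None,
             tie_policy: str = "input_order") -> float:
    """DCG_k with binary relevance: Σ_{i≤k} rel_i / log2(i + 1).

    Rank 1 is undiscounted (log2 2 = 1); an active sliding down the
    selection set loses gain logarithmically.
    """
    if config is None:
        config = MetricConfig()
    ranked = _ranked_labels(labels, scores, tie_policy)
    if ranked.size < config.k:
        raise ValueError("list-shorter-than-k")
    top = ranked[:config.k]
    discounts = np.log2(np.arange(1, config.k + 1) + 1)
    return float((top / discounts).sum())


def evaluate_all(labels, scores, config: MetricConfig | None = None,
                 tie_policy: str = "input_order") -> MetricReport:
    """All four metrics on one identical ranking."""
    if config is None:
        config = MetricConfig()
    return MetricReport(
        logauc=logauc_range(labels, scores, config),
        bedroc=bedroc(labels, scores, config, tie_policy),
        ef_k=enrichment_factor(labels, scores, config, tie_policy),
        dcg_k=dcg_at_k(labels, scores, config, tie_policy),
    )


def roc_auc_debug(labels, scores) -> float:
    """Plain ROC-AUC, provided for debugging only.

    Deliberately not part of :func:`evaluate_all`: overall AUC rewards
    ranking quality among inactives nobody will ever test.
    """
    from sklearn.metrics import roc_auc_score
    labels, scores = _validate(labels, scores)
    _require_both_classes(labels)
    return float(roc_auc_score(labels, scores))
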