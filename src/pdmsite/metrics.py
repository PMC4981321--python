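"""Evaluation statistics: confusion metrics, BDT score, atom-type enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Confusion", "confusion_metrics", "mcc", "bdt_score", "atom_type_enrichment"]


@dataclass(frozen=True)
class Confusion:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, predicted, actual) -> "Confusion":
        p = np.asarray(predicted, bool)
        a = np.asarray(actual, bool)
        return cls(
            tp=int(np.sum(p & a)), tn=int(np.sum(~p & ~a)),
            fp=int(np.sum(p & ~a)), fn=int(np.sum(~p & a)),
        )

    def __add__(self, other: "Confusion") -> "Confusion":
        return Confusion(self.tp + other.tp, self.tn + other.tn,
                         self.fp + other.fp, self.fn + other.fn)


def mcc(c: Confusion) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom))


def confusion_metrics(c: Confusion) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity (x100), F-score, MCC.

    Accuracy through specificity are on the 0-100 percentage scale; the
    F-score is the harmonic mean of precision and sensitivity (same scale);
    MCC is in [-1, 1] with the zero-denominator convention MCC = 0.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion matrix: metrics undefined")
    acc = 100.0 * (c.tp + c.tn) / c.total
    pre = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    sen = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    spe = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    fsc = 2.0 * pre * sen / (pre + sen) if (pre + sen) else 0.0
    return {"Acc": acc, "Pre": pre, "Sen": sen, "Spe": spe,
            "Fsc": fsc, "MCC": mcc(c)}


def bdt_score(predicted_ca: np.ndarray, actual_ca: np.ndarray, d0: float = 5.0) -> float:
    """Binding-site distance test score between residue sets.

    ``S_ij = 1 / (1 + (d_ij / d0)^2)`` on C-alpha distances;
    ``BDT = sum_i max_j S_ij / max(Np, No)``, in (0, 1], reaching 1 only
    when every predicted residue coincides with a site residue and
    Np = No.
    """
    p = np.asarray(predicted_ca, float).reshape(-1, 3)
    a = np.asarray(actual_ca, float).reshape(-1, 3)
    if len(p) == 0 or len(a) == 0:
        raise ValueError("BDT requires non-empty predicted and actual residue sets")
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    d = np.linalg.norm(p[:, None, :] - a[None, :, :], axis=2)
    s = 1.0 / (1.0 + (d / d0) ** 2)
    return float(s.max(axis=1).sum() / max(len(p), len(a)))


def atom_type_enrichment(type_ids, confidences, confidence_floor: float = 0.10,
                         n_types: int = 30) -> np.ndarray:
    """Normalized per-type prevalence of confident atoms over a corpus.

    ``p_i = n_i / N_i`` with ``n_i`` the atoms of protein type ``i`` with
    confidence strictly above the floor and ``N_i`` all atoms of that type;
    the returned ``P_i = p_i / sum_j p_j`` sum to 1.  The uniform baseline
    is ``1 / n_types``.
    """
    type_ids = np.asarray(type_ids, int)
    confidences = np.asarray(confidences, float)
    p = np.zeros(n_types)
    import warnings

    for i in range(1, n_types + 1):
        sel = type_ids == i
        n_total = int(sel.sum())
        if n_total == 0:
            warnings.warn(f"no atoms of type {i} in corpus; p_{i} = 0", stacklevel=2)
            continue
        p[i - 1] = np.sum(confidences[sel] > confidence_floor) / n_total
    total = p.sum()
    return p / total if total > 0 else p
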