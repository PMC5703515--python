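"""Fast correlation-based filter (FCBF) feature selection.

Features are ranked by their symmetrical uncertainty (SU) with the target —
here the reference apnea-hypopnea index — and then pruned for redundancy:
scanning from the most relevant feature downwards, a lower-ranked feature j
is removed when its SU with a retained higher-ranked feature i is at least
as large as its SU with the target (SU_ij >= SU_j), i.e. when everything j
says about the target is already said by i.

SU is a normalization of the information gain IG(X, Y) = H(X) - H(X|Y):

    SU(X, Y) = 2 IG(X, Y) / (H(X) + H(Y))  in [0, 1],

with H the Shannon entropy. Entropies need discrete variables; continuous
features and the AHI target are discretized into equal-frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FCBFResult",
    "discretize",
    "entropy",
    "symmetrical_uncertainty",
    "fcbf_select",
]

DEFAULT_BINS = 4


@dataclass
class FCBFResult:
    su_with_target: dict[str, float]
    ranking: list[str]
    removed: dict[str, str]  # feature -> higher-ranked feature that removed it
    selected: list[str]
    n_input: int

    def to_dict(self) -> dict:
        return {
            "su_with_target": self.su_with_target,
            "ranking": self.ranking,
            "removed": self.removed,
            "selected": self.selected,
            "n_input": self.n_input,
        }


def discretize(values: np.ndarray, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency bin labels; stable under monotone transforms.

    Labels are assigned from the stable rank of each value, so bin counts
    are equal up to +-1 and ties keep their original order. A constant
    vector degrades to a single label.
    """
    values = np.asarray(values, float)
    n = len(values)
    if n == 0:
        raise ValueError("empty vector")
    if np.all(values == values[0]):
        return np.zeros(n, dtype=int)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def entropy(labels: np.ndarray) -> float:
    """Shannon entropy in bits of a discrete label vector."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty vector")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_entropy(x: np.ndarray, y: np.ndarray) -> float:
    pairs = x.astype(np.int64) * (y.max() + 1) + y
    return entropy(pairs)


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(X, Y) = 2 IG / (H(X) + H(Y)); both-constant input is defined as 0."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("label vectors must have equal length")
    hx, hy = entropy(x), entropy(y)
    if hx + hy == 0:
        return 0.0
    ig = hx + hy - _joint_entropy(x, y)
    return float(np.clip(2.0 * ig / (hx + hy), 0.0, 1.0))


def fcbf_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    n_bins: int = DEFAULT_BINS,
    delta: float = 0.0,
) -> FCBFResult:
    """Run FCBF on an (n_subjects, p) feature matrix against a continuous target.

    ``delta`` is the relevance threshold: features with SU(target) <= delta
    are dropped before the redundancy scan (default keeps everything with
    SU > 0). Ranking ties break by original column order.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with at least 2 subjects")
    if X.shape[0] != len(y):
        raise ValueError("feature matrix and target length mismatch")
    p = X.shape[1]
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("feature_names length mismatch")

    y_lab = discretize(y, n_bins)
    labs = [discretize(X[:, j], n_bins) for j in range(p)]
    su_t = {names[j]: symmetrical_uncertainty(labs[j], y_lab) for j in range(p)}

    # stable descending sort: ties keep original column order
    order = sorted(range(p), key=lambda j: (-su_t[names[j]], j))
    ranking = [names[j] for j in order]

    removed: dict[str, str] = {}
    alive = [j for j in order if su_t[names[j]] > delta]
    selected: list[int] = []
    while alive:
        i = alive.pop(0)
        selected.append(i)
        survivors = []
        for j in alive:
            su_ij = symmetrical_uncertainty(labs[i], labs[j])
            if su_ij >= su_t[names[j]]:
                removed[names[j]] = names[i]
            else:
                survivors.append(j)
        alive = survivors

    return FCBFResult(
        su_with_target=su_t,
        ranking=ranking,
        removed=removed,
        selected=[names[j] for j in selected],
        n_input=p,
    )
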