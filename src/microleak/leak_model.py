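"""The anastomotic-leak (AL) index and CART-based predictive-taxon selection.

The AL index is a genus-ratio score built from six genera whose relative
abundances discriminate leak from non-leak communities: three protective,
short-chain-fatty-acid-associated genera in the numerator (*Paramuribaculum*,
*Clostridium sensu stricto*, *Alistipes*) and three leak-associated,
mucin-degrading or abscess-associated genera in the denominator
(*Dubosiella*, *Bacteroides*, *Akkermansia*).  Lower values indicate a shift
toward the leak-associated assemblage; an index below the cutoff (0.45 by
default) predicts a leak, and a value at or above it predicts an intact
anastomosis.

CART models are grown by greedy binary splits maximizing information gain in
bits, with a randomized, outcome-stratified half split into training and
held-out prediction sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .tables_io import RelativeAbundanceTable, SampleMetadata
from .univariate_stats import ClassifierMetrics, classifier_metrics

__all__ = [
    "NUMERATOR_TAXA",
    "DENOMINATOR_TAXA",
    "ALIndexResult",
    "CartNode",
    "CartModel",
    "al_index",
    "evaluate_index",
    "entropy",
    "cart_train",
    "candidate_taxa",
]

# protective (absence-of-leak) genera over leak-associated genera
NUMERATOR_TAXA = ("Paramuribaculum", "Clostridium sensu stricto", "Alistipes")
DENOMINATOR_TAXA = ("Dubosiella", "Bacteroides", "Akkermansia")

_CANDIDATE_TAXA = (
    "Dubosiella",
    "Lachnospiraceae spp.",
    "Akkermansia",
    "Paramuribaculum",
    "Bacteroides",
    "Alistipes",
    "Clostridium sensu stricto",
    "Parasutterella",
)


@dataclass
class ALIndexResult:
    sample_id: str
    numerator: float
    denominator: float
    index: float              # NaN when numerator and denominator are both 0
    predicted: str            # "leak" / "no_leak" / "undefined"
    degenerate: bool = False


@dataclass
class CartNode:
    """One node of a binary classification tree.

    Internal nodes carry a (taxon, threshold) split — samples with abundance
    ≤ threshold go left — and its information gain in bits.  Leaves carry the
    majority class and the routed training class counts.
    """

    taxon_id: str | None = None
    threshold: float | None = None
    gain: float | None = None
    left: "CartNode | None" = None
    right: "CartNode | None" = None
    prediction: str | None = None
    class_counts: dict[str, int] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.taxon_id is None


@dataclass
class CartModel:
    root: CartNode
    feature_names: list[str]
    classes: list[str]
    seed: int | None
    n_train: int
    n_test: int

    def predict_one(self, row: dict[str, float]) -> str:
        node = self.root
        while not node.is_leaf:
            node = node.left if row.get(node.taxon_id, 0.0) <= node.threshold else node.right
        return node.prediction

    def predict(self, features: pd.DataFrame) -> list[str]:
        return [self.predict_one(features.loc[sid].to_dict()) for sid in features.index]

    def selected_taxa(self) -> list[str]:
        """Taxa appearing in internal nodes, in first-use (pre-order) order."""
        out: list[str] = []

        def walk(node: CartNode) -> None:
            if node.is_leaf:
                return
            if node.taxon_id not in out:
                out.append(node.taxon_id)
            walk(node.left)
            walk(node.right)

        walk(self.root)
        return out

    def to_json(self) -> str:
        def encode(node: CartNode) -> dict:
            if node.is_leaf:
                return {"prediction": node.prediction, "class_counts": node.class_counts}
            return {
                "taxon": node.taxon_id, "threshold": node.threshold,
                "gain": node.gain,
                "left": encode(node.left), "right": encode(node.right),
            }
        return json.dumps({
            "classes": self.classes, "features": self.feature_names,
            "seed": self.seed, "n_train": self.n_train, "n_test": self.n_test,
            "tree": encode(self.root),
        }, indent=2)


def candidate_taxa() -> list[str]:
    """The eight leak-associated candidate genera, in stable order."""
    return list(_CANDIDATE_TAXA)


def al_index(abundances: dict[str, float] | pd.Series, cutoff: float = 0.45,
             sample_id: str = "") -> ALIndexResult:
    """AL index of one sample from its genus percent abundances.

    index = (Paramuribaculum + Clostridium sensu stricto + Alistipes)
          / (Dubosiella + Bacteroides + Akkermansia);
    genera absent from ``abundances`` count as 0.  predicted = "leak" iff
    index < cutoff.  A zero denominator with positive numerator is the
    extreme no-leak configuration and is flagged degenerate; zero over zero
    is degenerate with an undefined prediction.
    """
    if isinstance(abundances, pd.Series):
        abundances = abundances.to_dict()
    vals = {t: float(abundances.get(t, 0.0)) for t in NUMERATOR_TAXA + DENOMINATOR_TAXA}
    neg = [t for t, v in vals.items() if v < 0]
    if neg:
        raise ValueError(f"negative abundances for {neg}")
    num = sum(vals[t] for t in NUMERATOR_TAXA)
    den = sum(vals[t] for t in DENOMINATOR_TAXA)
    if den == 0.0:
        if num == 0.0:
            return ALIndexResult(sample_id, num, den, float("nan"), "undefined", True)
        return ALIndexResult(sample_id, num, den, float("inf"), "no_leak", True)
    idx = num / den
    return ALIndexResult(sample_id, num, den, idx,
                         "no_leak" if idx >= cutoff else "leak")


def evaluate_index(rel: RelativeAbundanceTable,
                   metadata: Sequence[SampleMetadata],
                   cutoff: float = 0.45) -> tuple[ClassifierMetrics, pd.DataFrame, list[ALIndexResult]]:
    """Score every sample, compare predictions with leak outcomes.

    Returns the confusion-matrix metrics (leak = positive class), a
    per-group median [IQR] index table, and the per-sample results.  Every
    sample must have a known leak status.
    """
    meta = {m.sample_id: m for m in metadata}
    missing = [s for s in rel.sample_ids if s not in meta]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    unknown = [s for s in rel.sample_ids if meta[s].al_status == "unknown"]
    if unknown:
        raise ValueError(f"samples with unknown AL status: {unknown}")
    results = [al_index(rel.data.loc[sid], cutoff=cutoff, sample_id=sid)
               for sid in rel.sample_ids]
    tp = fp = tn = fn = 0
    for res in results:
        actual_leak = meta[res.sample_id].al_status == "yes"
        predicted_leak = res.predicted == "leak"
        if actual_leak and predicted_leak:
            tp += 1
        elif actual_leak:
            fn += 1
        elif predicted_leak:
            fp += 1
        else:
            tn += 1
    metrics = classifier_metrics(tp, fp, tn, fn)
    rows = []
    by_group: dict[str, list[float]] = {}
    for res in results:
        by_group.setdefault(meta[res.sample_id].group_label, []).append(res.index)
    for group, vals in by_group.items():
        finite = [v for v in vals if np.isfinite(v)]
        if not finite:
            continue
        rows.append({
            "group": group,
            "median_index": float(np.median(finite)),
            "iqr_low": float(np.percentile(finite, 25)),
            "iqr_high": float(np.percentile(finite, 75)),
            "n": len(finite),
        })
    table = pd.DataFrame(rows).set_index("group")
    return metrics, table, results


def entropy(class_counts: Sequence[float] | dict[str, float]) -> float:
    """Shannon entropy of a class distribution in bits."""
    if isinstance(class_counts, dict):
        counts = np.asarray(list(class_counts.values()), dtype=float)
    else:
        counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("class counts sum to zero")
    q = counts[counts > 0] / total
    return float(-(q * np.log2(q)).sum())


def _best_split(x: np.ndarray, y_codes: np.ndarray, n_classes: int):
    """Exhaustive best (feature, midpoint) split by information gain.

    Ties break toward the lower feature index, then the lower threshold.
    Returns (feature, threshold, gain) or None if no gain-positive split
    exists.
    """
    n = y_codes.size
    parent_counts = np.bincount(y_codes, minlength=n_classes)
    h_parent = entropy(parent_counts)
    best = None
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        sorted_y = y_codes[order]
        left_counts = np.zeros(n_classes)
        right_counts = parent_counts.astype(float).copy()
        for i in range(n - 1):
            left_counts[sorted_y[i]] += 1
            right_counts[sorted_y[i]] -= 1
            if sorted_vals[i] == sorted_vals[i + 1]:
                continue  # can't separate equal values
            thresh = (sorted_vals[i] + sorted_vals[i + 1]) / 2.0
            n_l = i + 1
            n_r = n - n_l
            h = (n_l / n) * entropy(left_counts) + (n_r / n) * entropy(right_counts)
            gain = h_parent - h
            if gain <= 1e-12:
                continue
            key = (-gain, j, thresh)
            if best is None or key < best[0]:
                best = (key, j, thresh, gain)
    if best is None:
        return None
    return best[1], best[2], best[3]


def _grow(x: np.ndarray, y_codes: np.ndarray, classes: list[str],
          feature_names: list[str], depth: int, max_depth: int,
          min_leaf: int) -> CartNode:
    counts = np.bincount(y_codes, minlength=len(classes))
    leaf = CartNode(
        prediction=classes[int(np.argmax(counts))],
        class_counts={c: int(k) for c, k in zip(classes, counts)},
    )
    if depth >= max_depth or np.count_nonzero(counts) < 2 or y_codes.size < 2 * min_leaf:
        return leaf
    split = _best_split(x, y_codes, len(classes))
    if split is None:
        return leaf
    j, thresh, gain = split
    mask = x[:, j] <= thresh
    if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
        return leaf
    node = CartNode(taxon_id=feature_names[j], threshold=float(thresh), gain=float(gain))
    node.left = _grow(x[mask], y_codes[mask], classes, feature_names,
                      depth + 1, max_depth, min_leaf)
    node.right = _grow(x[~mask], y_codes[~mask], classes, feature_names,
                       depth + 1, max_depth, min_leaf)
    return node


def cart_train(features: pd.DataFrame, labels: Sequence[str],
               seed: int | None = None, split_fraction: float = 0.5,
               max_depth: int = 3, min_leaf: int = 2,
               positive_class: str = "leak") -> tuple[CartModel, ClassifierMetrics | None, list[str]]:
    """Grow a CART on a randomized stratified half split; evaluate held out.

    ``features`` is a samples × taxa percent-abundance frame restricted to
    the candidate taxa; ``labels`` the leak outcome per sample.  The split is
    stratified by outcome so both halves see both classes whenever possible.
    Returns (model, held-out metrics, selected taxa); metrics are None when
    the held-out half lacks one of the classes.
    """
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != len(features):
        raise ValueError("labels must match features")
    classes = sorted(set(labels.tolist()))
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = int(round(idx.size * split_fraction))
        n_train = min(max(n_train, 1), idx.size)
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    train_idx.sort()
    test_idx.sort()
    x = features.to_numpy(dtype=float)
    code = {c: i for i, c in enumerate(classes)}
    y = np.array([code[l] for l in labels])
    root = _grow(x[train_idx], y[train_idx], classes, list(features.columns),
                 0, max_depth, min_leaf)
    model = CartModel(root=root, feature_names=list(features.columns),
                      classes=classes, seed=seed,
                      n_train=len(train_idx), n_test=len(test_idx))
    metrics = None
    if test_idx:
        preds = model.predict(features.iloc[test_idx])
        actual = labels[test_idx]
        pos = positive_class
        tp = sum(1 for p, a in zip(preds, actual) if p == pos and a == pos)
        fn = sum(1 for p, a in zip(preds, actual) if p != pos and a == pos)
        fp = sum(1 for p, a in zip(preds, actual) if p == pos and a != pos)
        tn = sum(1 for p, a in zip(preds, actual) if p != pos and a != pos)
        if tp + fn > 0 and tn + fp > 0:
            metrics = classifier_metrics(tp, fp, tn, fn)
    return model, metrics, model.selected_taxa()
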