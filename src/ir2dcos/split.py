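"""Partitioning samples into external-validation, training and test sets.

The protocol holds out a stratified random 10% of samples for external
validation first, then applies the Kennard–Stone algorithm to the
remaining model set, taking 70% of the total as training and the rest
(20%) as test.  Kennard–Stone is deterministic: it starts from the two
most distant samples and greedily adds the sample whose minimal distance
to the already-selected set is largest, so the training set always
covers the extremes of the data cloud.  Only the random holdout consumes
the seed.

Distances are Euclidean on the (normalized) 1-D spectra, computed before
any image conversion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import pairwise_distances

from .containers import LabeledSpectrumSet

__all__ = [
    "SplitAssignment",
    "holdout_external",
    "kennard_stone",
    "split_dataset",
    "KennardStoneSplitter",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitAssignment:
    """Per-sample membership in {train, test, external}."""

    sample_ids: list[str]
    membership: list[str]
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.membership):
            raise ValueError("sample_ids and membership lengths differ")
        bad = set(self.membership) - {"train", "test", "external"}
        if bad:
            raise ValueError(f"invalid membership values: {sorted(bad)}")

    def indices(self, which: str) -> np.ndarray:
        return np.array(
            [i for i, m in enumerate(self.membership) if m == which], dtype=int
        )

    def counts(self) -> dict[str, int]:
        return {w: int(len(self.indices(w))) for w in ("train", "test", "external")}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps({
            "sample_ids": self.sample_ids,
            "membership": self.membership,
            "ratios": list(self.ratios),
            "seed": self.seed,
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitAssignment":
        d = json.loads(Path(path).read_text())
        return cls(d["sample_ids"], d["membership"],
                   tuple(d["ratios"]), d["seed"])


def holdout_external(
    s: LabeledSpectrumSet, fraction: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random external-validation holdout.

    Per class, ``round(fraction * class_size)`` samples are drawn (at
    least one when the class has >= 2 samples).  A singleton class stays
    entirely in the model set, with a warning.  Returns (model indices,
    external indices), each sorted ascending.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    labels = np.asarray(s.labels)
    external: list[int] = []
    for lab in s.classes:
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            logger.warning("class %r has %d sample(s); kept in model set",
                           lab, idx.size)
            continue
        k = int(round(fraction * idx.size))
        k = max(k, 1)
        k = min(k, idx.size - 1)
        external.extend(rng.choice(idx, size=k, replace=False).tolist())
    external_idx = np.array(sorted(external), dtype=int)
    model_idx = np.setdiff1d(np.arange(s.n_samples), external_idx)
    return model_idx, external_idx


def kennard_stone(X: np.ndarray, k: int) -> list[int]:
    """Ordered Kennard–Stone selection of ``k`` rows of ``X``.

    The first two picks are the pair at maximal Euclidean distance; each
    subsequent pick maximizes the minimal distance to the selected set.
    Ties break toward the lowest row index (argmax convention).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    d = pairwise_distances(X, metric="euclidean")
    # initial pair: maximal distance, ties toward lowest flat index
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < k:
        masked = np.where(remaining, min_d, -np.inf)
        nxt = int(np.argmax(masked))
        selected.append(nxt)
        remaining[nxt] = False
        min_d = np.minimum(min_d, d[nxt])
    return selected


def split_dataset(
    s: LabeledSpectrumSet,
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
    per_class: bool = False,
    sample_ids: list[str] | None = None,
) -> SplitAssignment:
    """Full protocol: stratified external holdout, then Kennard–Stone.

    The external fraction is ``ratios[2]``; Kennard–Stone then selects
    ``floor(train_share * model_size)`` training samples from the model
    set, where ``train_share = ratios[0] / (ratios[0] + ratios[1])``
    (7/9 under the default 70/20/10).  The remainder of the model set is
    the test set.
    """
    r_train, r_test, r_ext = ratios
    if min(ratios) <= 0 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must be positive and sum to 1, got {ratios}")
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(s.n_samples)]
    model_idx, external_idx = holdout_external(s, fraction=r_ext, seed=seed)
    train_share = r_train / (r_train + r_test)

    def _ks_train(idx: np.ndarray) -> set[int]:
        n_train = int(np.floor(train_share * idx.size))
        n_train = max(min(n_train, idx.size), 2)
        sel = kennard_stone(s.spectra[idx], n_train)
        return {int(idx[i]) for i in sel}

    if per_class:
        labels = np.asarray(s.labels)
        train_set: set[int] = set()
        for lab in s.classes:
            cls_idx = model_idx[labels[model_idx] == lab]
            if cls_idx.size >= 2:
                train_set |= _ks_train(cls_idx)
            else:
                train_set |= set(cls_idx.tolist())
    else:
        train_set = _ks_train(model_idx)

    membership = []
    ext = set(external_idx.tolist())
    for i in range(s.n_samples):
        if i in ext:
            membership.append("external")
        elif i in train_set:
            membership.append("train")
        else:
            membership.append("test")
    return SplitAssignment(list(sample_ids), membership, ratios, seed)


class KennardStoneSplitter:
    """Model-selection-style wrapper: yields (train, test) index arrays.

    Mirrors the sklearn splitter protocol (``split`` / ``get_n_splits``)
    so it can stand in for a CV object in pipelines that accept one
    deterministic split.
    """

    def __init__(self, train_size: float = 0.78):
        if not 0.0 < train_size < 1.0:
            raise ValueError("train_size must be in (0, 1)")
        self.train_size = train_size

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return 1

    def split(self, X, y=None, groups=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        k = max(2, int(np.floor(self.train_size * n)))
        train = np.array(kennard_stone(X, k), dtype=int)
        test = np.setdiff1d(np.arange(n), train)
        yield train, test
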