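"""Stochastic model validation: mass train/test resampling diagnostics.

The compound ensemble (102 molecules in the reference data) is repeatedly
partitioned at a 2:1 ratio (68/34), a PLS model is fitted and validated on
each draw, and the population of (q2_cv, q2_test) pairs is filtered for
"best" models (q2_cv >= 0.6 and q2_test > 0 by default).  Counting how
often each molecule lands in the test set of a best model flags objects
the models systematically refuse to train on.  Deterministic alternatives
(activity-ranked systematic split, Kennard-Stone maximin) are provided for
single-split benchmarking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from naphqsar.pls import NipalsPLS, _as_xy, _loo_pred_multi, external_stats


def split_sizes(n: int, ratio: tuple[int, int] = (2, 1)) -> tuple[int, int]:
    """Training/test sizes at the given ratio (102 at 2:1 -> 68/34)."""
    if n < 3:
        raise ValueError("need at least 3 objects")
    n_train = int(round(n * ratio[0] / (ratio[0] + ratio[1])))
    n_train = min(max(n_train, 1), n - 1)
    return n_train, n - n_train


def random_split(
    ids: Sequence, seed: int, ratio: tuple[int, int] = (2, 1)
) -> tuple[list, list]:
    """Uniformly random train/test partition; deterministic per seed."""
    ids = list(ids)
    n_train, _ = split_sizes(len(ids), ratio)
    perm = np.random.default_rng(seed).permutation(len(ids))
    train = sorted(perm[:n_train])
    test = sorted(perm[n_train:])
    return [ids[i] for i in train], [ids[i] for i in test]


def ranked_split(
    ids: Sequence, activities: Sequence[float], ratio: tuple[int, int] = (2, 1)
) -> tuple[list, list]:
    """Systematic split on the activity ranking: every k-th object to test.

    With the default 2:1 ratio every 3rd compound of the activity-sorted
    list is held out, so the test set spans the full activity range.
    Ties in activity are resolved by a stable sort on id.
    """
    ids = list(ids)
    if len(activities) != len(ids):
        raise ValueError("ids and activities must align")
    k = (ratio[0] + ratio[1]) // ratio[1]
    order = sorted(range(len(ids)), key=lambda i: (activities[i], str(ids[i])))
    test_pos = set(order[k - 1 :: k][: split_sizes(len(ids), ratio)[1]])
    train = [ids[i] for i in order if i not in test_pos]
    test = [ids[i] for i in order if i in test_pos]
    return train, test


def kennard_stone_split(values: Sequence[float], n_train: int) -> tuple[list[int], list[int]]:
    """Classic maximin Kennard-Stone on 1-D values; returns index lists.

    Seeds with the two extremes, then repeatedly adds the candidate whose
    minimal distance to the chosen set is largest (ties -> lowest index).
    Chosen indices form the training set.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if not 2 <= n_train < n:
        raise ValueError("need 2 <= n_train < n")
    chosen = [int(np.argmin(v)), int(np.argmax(v))]
    if chosen[0] == chosen[1]:  # all values equal
        chosen = [0, 1]
    remaining = [i for i in range(n) if i not in chosen]
    while len(chosen) < n_train:
        dmin = np.array([min(abs(v[i] - v[c]) for c in chosen) for i in remaining])
        pick = remaining.pop(int(np.argmax(dmin)))
        chosen.append(pick)
    return sorted(chosen), sorted(remaining)


@dataclass(frozen=True)
class SplitPopulation:
    """Outcome of an SMV run: one row per resampling plus filter metadata."""

    samples: pd.DataFrame  # seed, n_components, q2_cv, sdep_cv, q2_test, sdep_test, test_ids
    ids: tuple
    q2_cv_min: float
    q2_test_min: float
    strict_gt: bool = False

    def filtered(self, q2_cv_min: float | None = None, q2_test_min: float | None = None) -> pd.DataFrame:
        """Subset of best models passing the thresholds."""
        cv_min = self.q2_cv_min if q2_cv_min is None else q2_cv_min
        t_min = self.q2_test_min if q2_test_min is None else q2_test_min
        if self.strict_gt:
            mask = self.samples.q2_cv > cv_min
        else:
            mask = self.samples.q2_cv >= cv_min
        return self.samples[mask & (self.samples.q2_test > t_min)]

    def test_frequency(self, **kwargs) -> pd.Series:
        """Per-molecule test-set membership count over the filtered samples."""
        counts = pd.Series(0, index=pd.Index(self.ids, name="id"))
        best = self.filtered(**kwargs)
        if best.empty:
            warnings.warn("no sample passed the best-model filter", stacklevel=2)
            return counts
        for test_ids in best.test_ids:
            counts[list(test_ids)] += 1
        return counts

    def to_csv(self, path: str | Path) -> None:
        df = self.samples.copy()
        df["test_ids"] = df["test_ids"].map(lambda t: " ".join(map(str, t)))
        df.to_csv(path, index=False)

    def frequency_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.test_frequency().to_dict(), indent=1))


def run_smv(
    X,
    y,
    n_samples: int = 10_000,
    a_max: int = 3,
    q2_cv_min: float = 0.6,
    q2_test_min: float = 0.0,
    base_seed: int = 0,
    ids: Sequence | None = None,
    ratio: tuple[int, int] = (2, 1),
    strict_gt: bool = False,
) -> SplitPopulation:
    """Repeated 2:1 resampling with per-sample PLS fitting and validation.

    For every draw the component count is re-selected on the training block
    by LOO (1..a_max), the model is refitted, and q2_cv/SDEP plus the
    strictly held-out q2_test/SDEP are recorded.  Identical ``base_seed``
    reproduces the population exactly.
    """
    X, y = _as_xy(X, y)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ids = tuple(range(len(y))) if ids is None else tuple(ids)
    if len(ids) != len(y):
        raise ValueError("ids must align with y")
    pos = {cid: i for i, cid in enumerate(ids)}
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_samples)
    denom_all = None
    records = []
    for seed in seeds:
        train_ids, test_ids = random_split(ids, int(seed), ratio)
        tr = np.array([pos[i] for i in train_ids])
        te = np.array([pos[i] for i in test_ids])
        Xtr, ytr = X[tr], y[tr]
        a_cap = min(a_max, len(ytr) - 2, X.shape[1])
        preds, _ = _loo_pred_multi(Xtr, ytr, a_cap, scale=False)
        denom_all = float(((ytr - ytr.mean()) ** 2).sum())
        q2s = 1.0 - ((ytr[:, None] - preds) ** 2).sum(axis=0) / denom_all
        a = int(np.argmax(q2s >= q2s.max() - 1e-12)) + 1
        pred_cv = preds[:, a - 1]
        q2_cv = float(q2s[a - 1])
        sdep_cv = float(np.sqrt(((pred_cv - ytr) ** 2).mean()))
        fit = NipalsPLS(n_components=a).fit(Xtr, ytr)
        ext = external_stats(fit, X[te], y[te])
        records.append(
            {
                "seed": int(seed),
                "n_components": a,
                "q2_cv": q2_cv,
                "sdep_cv": sdep_cv,
                "q2_test": ext.q2_test,
                "sdep_test": ext.sdep,
                "test_ids": tuple(test_ids),
            }
        )
    return SplitPopulation(
        samples=pd.DataFrame.from_records(records),
        ids=ids,
        q2_cv_min=q2_cv_min,
        q2_test_min=q2_test_min,
        strict_gt=strict_gt,
    )


def flag_frequent(population: SplitPopulation, count_threshold: int) -> list:
    """Molecule ids with test frequency >= threshold, descending by count."""
    counts = population.test_frequency()
    hits = counts[counts >= count_threshold]
    return hits.sort_values(ascending=False, kind="stable").index.tolist()
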