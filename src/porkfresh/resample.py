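"""Monte Carlo data augmentation and calibration/prediction splitting.

Augmentation draws whole paired rows (metabolites, quality and spectrum
jointly, so cross-block relationships survive) and adds Gaussian jitter
scaled to each variable's within-storage-day spread.  ``alpha=0`` reduces
to a pure bootstrap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["mc_augment", "split_cal_pred"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def mc_augment(
    frames: dict[str, pd.DataFrame],
    days: np.ndarray | pd.Series,
    n_target: int,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, pd.DataFrame], np.ndarray]:
    """Augment paired tables to exactly ``n_target`` rows.

    Each augmented row is one uniformly drawn base row (the same draw for
    every block, preserving pairing) plus independent Gaussian noise per
    variable with sd = ``alpha`` x that variable's within-day sample sd.

    Returns the augmented blocks (index ``aug0001``... with provenance
    columns left to the caller) and the drawn base-row positions.
    """
    if not frames:
        raise DomainError("no tables to augment")
    days = np.asarray(days)
    n_base = len(days)
    for name, df in frames.items():
        if len(df) != n_base:
            raise DomainError(
                f"block {name!r} has {len(df)} rows; expected {n_base}"
            )
    if n_base < 2:
        raise DomainError("need at least 2 base rows")
    if n_target < n_base:
        raise DomainError(
            f"n_target={n_target} below base row count {n_base}"
        )
    if alpha < 0:
        raise DomainError("alpha must be >= 0")
    if alpha > 0:
        _, counts = np.unique(days, return_counts=True)
        if counts.min() < 2:
            raise DomainError(
                "a storage day has a single base row; within-day sd "
                "undefined for alpha > 0"
            )

    rng = _rng(seed)
    base_idx = rng.integers(0, n_base, size=n_target)
    index = pd.Index(
        [f"aug{i:05d}" for i in range(n_target)], name="sample_id"
    )

    out: dict[str, pd.DataFrame] = {}
    for name, df in frames.items():
        values = df.to_numpy(float)[base_idx]
        if alpha > 0:
            day_sd = np.zeros((n_base, df.shape[1]))
            for d in np.unique(days):
                rows = days == d
                day_sd[rows] = df.to_numpy(float)[rows].std(axis=0, ddof=1)
            values = values + rng.normal(
                0.0, 1.0, values.shape
            ) * alpha * day_sd[base_idx]
        out[name] = pd.DataFrame(values, index=index, columns=df.columns)
    return out, base_idx


def split_cal_pred(
    index: pd.Index | np.ndarray | int,
    ratio: float = 0.7,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform shuffle, then split: calibration gets
    round(ratio x n) rows; the partition is disjoint and exhaustive.

    Accepts an index/array of ids (returned split accordingly) or a row
    count (returns integer positions).
    """
    if not (0 < ratio < 1):
        raise DomainError(f"ratio must be in (0, 1), got {ratio}")
    if isinstance(index, (int, np.integer)):
        items = np.arange(int(index))
    else:
        items = np.asarray(index)
    n = items.size
    if n < 2:
        raise DomainError("need at least 2 rows to split")
    rng = _rng(seed)
    perm = rng.permutation(n)
    n_cal = int(np.rint(ratio * n))
    return items[np.sort(perm[:n_cal])], items[np.sort(perm[n_cal:])]
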