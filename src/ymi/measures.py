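"""Per-fly behavioral statistics from raw turn sequences.

Each fly in a Y-maze produces an ordered sequence of binary left/right
choices.  Three summary statistics are computed per fly:

* **turn bias** p̂ — the fraction of choices that are right turns,
* **number of turns** n — the length of the sequence,
* **switchiness** S — the observed count of L↔R alternations divided by
  the count expected if the turns were i.i.d. Bernoulli draws at the
  fly's own bias:  S = A / [(n−1) · 2·p̂·(1−p̂)].

A fly whose turns follow the binomial null has expected switchiness 1
(exactly n/(n−1) in finite samples); streaky flies score below 1 and
over-alternating flies above 1.  Switchiness is undefined when the
normalizer vanishes (p̂ ∈ {0, 1} or n < 2) and is carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TurnSequence",
    "UndefinedMeasureError",
    "turn_bias",
    "alternation_count",
    "switchiness",
    "switchiness_from_stats",
    "compute_measures",
    "read_sequences",
    "write_sequences",
]

_LABEL_TO_BIT = {"L": 0, "R": 1, "l": 0, "r": 1, 0: 0, 1: 1, False: 0, True: 1}


class UndefinedMeasureError(ValueError):
    """A measure was requested for a sequence on which it is undefined."""


@dataclass(frozen=True)
class TurnSequence:
    """An individual fly's ordered binary choices.

    Parameters
    ----------
    turns
        Array of 0/1 codes, 1 meaning a right turn.
    times
        Optional strictly increasing event times in seconds, same length.
    """

    turns: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        turns = np.asarray(self.turns, dtype=np.uint8)
        if turns.ndim != 1:
            raise ValueError("turns must be one-dimensional")
        if turns.size and turns.max() > 1:
            raise ValueError("turn codes must be 0 (L) or 1 (R)")
        object.__setattr__(self, "turns", turns)
        if self.times is not None:
            times = np.asarray(self.times, dtype=float)
            if times.shape != turns.shape:
                raise ValueError("times must match turns in length")
            if times.size > 1 and not np.all(np.diff(times) > 0):
                raise ValueError("times must be strictly increasing")
            object.__setattr__(self, "times", times)

    @classmethod
    def from_labels(
        cls, labels: Iterable, times: Sequence[float] | None = None
    ) -> "TurnSequence":
        """Build from 'L'/'R' labels (a string like ``"LRLR"`` works)."""
        try:
            bits = [_LABEL_TO_BIT[c] for c in labels]
        except KeyError as exc:  # pragma: no cover - message path
            raise ValueError(f"unrecognized turn label: {exc.args[0]!r}") from exc
        return cls(np.array(bits, dtype=np.uint8), times)

    def __len__(self) -> int:
        return int(self.turns.size)

    def labels(self) -> str:
        return "".join("R" if b else "L" for b in self.turns)


def _as_sequence(seq) -> TurnSequence:
    if isinstance(seq, TurnSequence):
        return seq
    return TurnSequence.from_labels(seq)


def turn_bias(seq) -> float:
    """Fraction of right turns; raises on an empty sequence."""
    s = _as_sequence(seq)
    n = len(s)
    if n == 0:
        raise UndefinedMeasureError("turn bias is undefined for an empty sequence")
    return float(s.turns.sum()) / n


def alternation_count(seq) -> int:
    """Number of adjacent L↔R (or R↔L) transitions."""
    s = _as_sequence(seq)
    if len(s) == 0:
        raise UndefinedMeasureError("alternation count is undefined for an empty sequence")
    return int(np.count_nonzero(np.diff(s.turns)))


def switchiness_from_stats(alternations: float, n: float, p_hat: float) -> float:
    """Switchiness from pre-computed (A, n, p̂); NaN where undefined."""
    if n < 2 or p_hat <= 0.0 or p_hat >= 1.0:
        return float("nan")
    return alternations / ((n - 1) * 2.0 * p_hat * (1.0 - p_hat))


def switchiness(seq) -> float:
    """Binomial-normalized alternation statistic S; NaN where undefined.

    S = A / [(n−1)·2p̂(1−p̂)]: the observed alternation count over its
    expectation for an i.i.d. fly with the same bias.
    """
    s = _as_sequence(seq)
    n = len(s)
    if n == 0:
        raise UndefinedMeasureError("switchiness is undefined for an empty sequence")
    p_hat = turn_bias(s)
    if n < 2 or p_hat in (0.0, 1.0):
        return float("nan")
    return switchiness_from_stats(alternation_count(s), n, p_hat)


def _measures_from_padded(
    turns: np.ndarray, lengths: np.ndarray, min_turns: int = 0
) -> pd.DataFrame:
    """Vectorized measures for a padded 0/1 matrix (one row per fly).

    ``lengths[i]`` gives the valid prefix of row i; entries beyond it are
    ignored.  Shared by :func:`compute_measures` and the cohort generator.
    """
    turns = np.asarray(turns, dtype=np.uint8)
    lengths = np.asarray(lengths, dtype=np.int64)
    n_flies, width = turns.shape if turns.ndim == 2 else (len(lengths), 0)
    col = np.arange(width)
    mask = col[None, :] < lengths[:, None]
    r_counts = np.where(mask, turns, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p_hat = np.where(lengths > 0, r_counts / np.maximum(lengths, 1), np.nan)
    if width > 1:
        pair_mask = col[None, 1:] < lengths[:, None]
        alts = ((turns[:, 1:] != turns[:, :-1]) & pair_mask).sum(axis=1)
    else:
        alts = np.zeros(n_flies, dtype=np.int64)
    denom = (lengths - 1) * 2.0 * p_hat * (1.0 - p_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where((lengths >= 2) & (denom > 0), alts / denom, np.nan)
    out = pd.DataFrame(
        {
            "turn_bias": p_hat,
            "num_turns": lengths,
            "switchiness": s,
            "alternation_count": np.where(lengths > 0, alts, 0).astype(np.int64),
        }
    )
    if min_turns > 0:
        low = out["num_turns"] < min_turns
        out.loc[low, ["turn_bias", "switchiness"]] = np.nan
    return out


def compute_measures(seqs: Iterable, min_turns: int = 0) -> pd.DataFrame:
    """Apply the three measures element-wise over a collection of sequences.

    Returns a DataFrame with columns ``turn_bias``, ``num_turns``,
    ``switchiness`` and the auxiliary ``alternation_count``, one row per
    input sequence in order.  Undefined values propagate as NaN; flies with
    fewer than ``min_turns`` turns get NaN bias and switchiness (the filter
    is off by default, so all flies contribute to grand analyses).
    """
    parsed = [_as_sequence(s) for s in seqs]
    lengths = np.array([len(s) for s in parsed], dtype=np.int64)
    width = int(lengths.max()) if len(parsed) else 0
    padded = np.zeros((len(parsed), width), dtype=np.uint8)
    for i, s in enumerate(parsed):
        padded[i, : len(s)] = s.turns
    return _measures_from_padded(padded, lengths, min_turns=min_turns)


def write_sequences(seqs: Iterable, path, fly_ids: Sequence | None = None) -> str:
    """Write sequences as long-format CSV: flyID, turn ∈ {L,R}[, time]."""
    parsed = [_as_sequence(s) for s in seqs]
    if fly_ids is None:
        fly_ids = list(range(len(parsed)))
    frames = []
    has_times = any(s.times is not None for s in parsed)
    for fid, s in zip(fly_ids, parsed):
        d = {"flyID": fid, "turn": ["R" if b else "L" for b in s.turns]}
        if has_times:
            d["time"] = s.times if s.times is not None else np.full(len(s), np.nan)
        frames.append(pd.DataFrame(d))
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["flyID", "turn"])
    )
    df.to_csv(path, index=False)
    return str(path)


def read_sequences(path) -> dict:
    """Read long-format sequence CSV back to {flyID: TurnSequence}."""
    df = pd.read_csv(path)
    required = {"flyID", "turn"}
    if not required.issubset(df.columns):
        raise ValueError(f"sequence file must have columns {sorted(required)}")
    out = {}
    for fid, grp in df.groupby("flyID", sort=False):
        times = grp["time"].to_numpy() if "time" in grp else None
        if times is not None and np.isnan(times).all():
            times = None
        out[fid] = TurnSequence.from_labels(grp["turn"].tolist(), times)
    return out
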