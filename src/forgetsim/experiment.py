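"""Synthetic two-alternative forced-choice recognition experiments.

Emulates the statistical structure of a word-stream recognition protocol:
each participant watches a stream of 500 words (opaque integer tokens drawn
without replacement from a pool of 751) interrupted by 75 recognition
queries — 25 about the word two positions back, 25 about the word ten
positions back, and 25 about the first 25 presented words, each of those
queried exactly once at a random later point, with one query placed after
the final word.  The 2-/10-back queries are blocked: no other query falls
between the target's presentation and its query.

A query at position ``q`` occurs after ``q`` words have been presented;
its lag to a target presented at position ``s`` is ``q - s``, which is also
the number of words presented after the target — so an encoded word queried
at lag ``t`` faces exactly ``t`` potential interfering acquisitions, and
accuracies compose exactly with the theoretical retention curves through
the guessing relation ``p = (1 + R)/2``.

Encoding can be perfect or subject to fatigue (a linearly declining
probability of acquiring each word), and the fate of encoded words follows
a pluggable memory model: the valence-interference process, or the
``always_retained`` / ``never_retained`` degenerate references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "PerfectEncoding",
    "FatigueEncoding",
    "InterferenceMemory",
    "AlwaysRetained",
    "NeverRetained",
    "ProtocolConfig",
    "build_schedule",
    "generate_trials",
]

#: Condition labels in the order of their integer codes.
CONDITIONS = ("2-back", "10-back", "early")
_BACK_LAGS = {0: 2, 1: 10}


@dataclass(frozen=True)
class PerfectEncoding:
    """Every presented word is acquired."""

    kind: str = field(default="perfect", init=False)


@dataclass(frozen=True)
class FatigueEncoding:
    """Linearly declining acquisition probability along the stream.

    Word at position ``pos`` (1-based) is encoded with probability
    ``1 - gamma * pos / stream_length``; the default ``gamma = 0.3`` gives
    a gentle decline from ~1.0 to 0.7 — the simplest monotone model of the
    attention/fatigue drop seen in long streams.
    """

    gamma: float = 0.3
    kind: str = field(default="fatigue", init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True)
class InterferenceMemory:
    """Full-erasure valence interference with ``n_dims`` dimensions.

    Encoded words enter the interference process in presentation order with
    i.i.d. valence vectors; a word is retained at its query iff no encoded
    later word dominates it in all dimensions.  Words within short-term
    memory span (the 2-back condition) are protected: if encoded, they are
    recalled regardless of interference.
    """

    n_dims: int = 5
    kind: str = field(default="interference", init=False)

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")


@dataclass(frozen=True)
class AlwaysRetained:
    """Reference model: every encoded word stays in memory."""

    kind: str = field(default="always_retained", init=False)


@dataclass(frozen=True)
class NeverRetained:
    """Reference model: nothing is retained; every response is a guess."""

    kind: str = field(default="never_retained", init=False)


EncodingModel = Union[PerfectEncoding, FatigueEncoding]
MemoryModel = Union[InterferenceMemory, AlwaysRetained, NeverRetained]


@dataclass
class ProtocolConfig:
    """Configuration of a synthetic recognition cohort."""

    n_participants: int
    stream_length: int = 500
    n_2back: int = 25
    n_10back: int = 25
    n_early: int = 25
    pool_size: int = 751
    encoding: EncodingModel = field(default_factory=PerfectEncoding)
    memory: MemoryModel = field(default_factory=InterferenceMemory)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if min(self.n_2back, self.n_10back, self.n_early) < 0:
            raise ValueError("query counts must be non-negative")
        if self.n_early < 1:
            raise ValueError("the early condition anchors the lag curve; n_early >= 1")
        n_queries = self.n_2back + self.n_10back + self.n_early
        if self.pool_size < self.stream_length + n_queries:
            raise ValueError(
                f"pool_size {self.pool_size} cannot supply {self.stream_length} "
                f"stream words plus {n_queries} disjoint lures"
            )
        # blocked back-queries need room: gap lag+1 per back query, 1 per early
        base = self.n_early + 10
        min_span = 3 * self.n_2back + 11 * self.n_10back + self.n_early
        if self.stream_length - base < min_span:
            raise ValueError(
                f"stream of {self.stream_length} words cannot host "
                f"{n_queries} blocked queries after position {base}: "
                f"needs at least {base + min_span} words"
            )

    @property
    def n_queries(self) -> int:
        return self.n_2back + self.n_10back + self.n_early


def _schedule_arrays(config: ProtocolConfig, rng: np.random.Generator):
    """One participant's query schedule as (positions, targets, condition codes).

    Conditions are randomly intermixed.  Gaps between consecutive queries
    are at least ``lag + 1`` for back conditions (so no query intervenes
    between a back target's presentation and its query) and at least 1
    otherwise; leftover slack is spread multinomially over the gaps and the
    last query is pinned after the final word.  Random queries start after
    position ``n_early + 10`` so back targets never fall among the early
    words (each word is queried at most once).
    """
    codes = np.repeat(
        np.arange(3), [config.n_2back, config.n_10back, config.n_early]
    )
    codes = rng.permutation(codes)
    nq = codes.size
    min_gap = np.choose(codes, [3, 11, 1])
    base = config.n_early + 10
    slack = config.stream_length - base - int(min_gap.sum())
    extras = rng.multinomial(slack, np.full(nq, 1.0 / nq))
    positions = base + np.cumsum(min_gap + extras)
    targets = np.empty(nq, dtype=np.int64)
    for code, lag in _BACK_LAGS.items():
        targets[codes == code] = positions[codes == code] - lag
    targets[codes == 2] = rng.permutation(config.n_early) + 1
    return positions, targets, codes


def build_schedule(
    config: ProtocolConfig, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Build one participant's query schedule.

    Returns a frame with ``query_position`` (number of words presented
    before the query), ``target_position`` and ``condition``, ordered by
    query position; the final row sits after the last word of the stream.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    positions, targets, codes = _schedule_arrays(config, rng)
    return pd.DataFrame(
        {
            "query_position": positions,
            "target_position": targets,
            "condition": pd.Categorical.from_codes(codes, CONDITIONS),
        }
    )


def _participant_trials(config: ProtocolConfig, rng: np.random.Generator):
    positions, targets, codes = _schedule_arrays(config, rng)
    nq = codes.size
    L = config.stream_length

    if isinstance(config.encoding, FatigueEncoding):
        p_enc = 1.0 - config.encoding.gamma * np.arange(1, L + 1) / L
        encoded_stream = rng.random(L) < p_enc
    else:
        encoded_stream = np.ones(L, dtype=bool)
    encoded = encoded_stream[targets - 1]

    retained = np.zeros(nq, dtype=bool)
    memory = config.memory
    if isinstance(memory, AlwaysRetained):
        retained[:] = encoded
    elif isinstance(memory, InterferenceMemory):
        n = memory.n_dims
        v = rng.random((L, n))
        is_2back = codes == 0
        retained[is_2back] = encoded[is_2back]  # short-term-memory protection
        perfect = isinstance(config.encoding, PerfectEncoding)
        for i in np.nonzero(~is_2back & encoded)[0]:
            s, q = targets[i], positions[i]
            seg = v[s:q]  # words s+1 .. q, i.e. the `lag` followers
            if not perfect:
                seg = seg[encoded_stream[s:q]]
            dominated = (seg > v[s - 1]).all(axis=1).any() if seg.size else False
            retained[i] = not dominated
    # NeverRetained: leave all False

    guesses = rng.random(nq) < 0.5
    correct = retained | (~retained & guesses)
    return positions, targets, codes, encoded, retained, correct


def generate_trials(config: ProtocolConfig) -> pd.DataFrame:
    """Generate the full cohort's trial table.

    Each participant receives an independent schedule, word stream,
    encoding realisation and memory realisation, all driven by one
    generator seeded with ``config.seed`` (the table is a deterministic
    function of the config).  A response is correct with certainty when the
    target was encoded and retained, and by a fair guess between the two
    alternatives otherwise.
    """
    rng = np.random.default_rng(config.seed)
    nq = config.n_queries
    n_rows = config.n_participants * nq
    pid = np.empty(n_rows, dtype=np.int64)
    qpos = np.empty(n_rows, dtype=np.int64)
    tpos = np.empty(n_rows, dtype=np.int64)
    cond = np.empty(n_rows, dtype=np.int8)
    enc = np.empty(n_rows, dtype=bool)
    ret = np.empty(n_rows, dtype=bool)
    cor = np.empty(n_rows, dtype=bool)
    for p in range(config.n_participants):
        sl = slice(p * nq, (p + 1) * nq)
        positions, targets, codes, encoded, retained, correct = _participant_trials(
            config, rng
        )
        pid[sl] = p
        qpos[sl] = positions
        tpos[sl] = targets
        cond[sl] = codes
        enc[sl] = encoded
        ret[sl] = retained
        cor[sl] = correct
    return pd.DataFrame(
        {
            "participant_id": pid,
            "query_position": qpos,
            "target_position": tpos,
            "condition": pd.Categorical.from_codes(cond, CONDITIONS),
            "lag": qpos - tpos,
            "encoded": enc,
            "retained": ret,
            "correct": cor,
        }
    )
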