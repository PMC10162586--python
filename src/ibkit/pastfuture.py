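"""Past-future bottleneck preprocessing for single time series.

A single symbol sequence becomes paired (past, future) observations:
X is the window of ``past_len`` symbols ending at position t and Y the
window of ``future_len`` symbols starting at t+1 (adjacent and
non-overlapping; successive pairs slide by one step).  The windowed
pairs feed straight into :func:`ibkit.distributions.estimate_joint`, so
the bottleneck variable compresses the past while preserving predictive
information about the future.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence


class SequenceTooShortError(ValueError):
    """The sequence cannot host a single (past, future) window pair."""


@dataclass(frozen=True)
class WindowSpec:
    """Past and future window lengths, both at least one symbol."""

    past_len: int
    future_len: int

    def __post_init__(self) -> None:
        if self.past_len < 1:
            raise ValueError("past_len must be >= 1")
        if self.future_len < 1:
            raise ValueError("future_len must be >= 1")

    @property
    def min_sequence_length(self) -> int:
        return self.past_len + self.future_len


def windowed_pairs(sequence: Sequence[Hashable], spec: WindowSpec):
    """Sliding (past window, future window) pairs from one sequence.

    Emits exactly ``len(sequence) - past_len - future_len + 1`` pairs.
    Windows of length one are unwrapped to the bare symbol; longer
    windows become tuples, which downstream alphabets order
    lexicographically and treat as atomic symbols.
    """
    seq = list(sequence)
    n = len(seq)
    if n < spec.min_sequence_length:
        raise SequenceTooShortError(
            f"sequence of length {n} is too short: past_len={spec.past_len} "
            f"plus future_len={spec.future_len} needs at least "
            f"{spec.min_sequence_length} symbols"
        )

    def window(chunk):
        return chunk[0] if len(chunk) == 1 else tuple(chunk)

    x_obs = []
    y_obs = []
    for t in range(spec.past_len, n - spec.future_len + 1):
        x_obs.append(window(seq[t - spec.past_len : t]))
        y_obs.append(window(seq[t : t + spec.future_len]))
    return x_obs, y_obs
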