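"""Equal-probability symbolic encoding of MAV instances and word distances.

Each 100 ms instance is an 8-tuple of per-channel MAV values.  Per channel,
the value range is cut into ``n`` intervals so that every symbol is equally
probable on the training data (empirical quantiles at k/n); an instance then
becomes an 8-letter *word* over the alphabet A.. (internally integer ranks
0..n-1).  Two word distances are provided:

* ``lexical_distance``   -- sum over positions of |rank difference| (d_l),
  used for nearest-word imputation in the affinity classifier;
* ``modified_lexical_distance`` -- per position 0 if equal else
  |rank difference| - 1, used as the local cost of the banded DTW.  Adjacent
  symbols cost nothing, since two values either side of a quantile boundary
  may be arbitrarily close.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SaxCodebook",
    "fit_codebook",
    "encode",
    "lexical_distance",
    "modified_lexical_distance",
    "words_to_strings",
    "strings_to_words",
]

_N_CHANNELS = 8
_MAX_ALPHABET = 26  # rendered as letters A..Z


@dataclass(frozen=True)
class SaxCodebook:
    """Per-channel ordered breakpoints defining an n-symbol alphabet."""

    n: int
    breakpoints: np.ndarray  # (8, n-1), non-decreasing per channel

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if not (2 <= self.n <= _MAX_ALPHABET):
            raise ValueError(f"alphabet size must be in 2..{_MAX_ALPHABET}, got {self.n}")
        if bp.shape != (_N_CHANNELS, self.n - 1):
            raise ValueError(f"breakpoints must have shape (8, {self.n - 1}), got {bp.shape}")
        if np.any(np.diff(bp, axis=1) < 0):
            raise ValueError("breakpoints must be non-decreasing per channel")
        object.__setattr__(self, "breakpoints", bp)

    def to_dict(self) -> dict:
        return {"n": self.n, "breakpoints": self.breakpoints.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SaxCodebook":
        return cls(n=int(d["n"]), breakpoints=np.asarray(d["breakpoints"], dtype=float))


def fit_codebook(values: np.ndarray, n: int) -> SaxCodebook:
    """Fit per-channel equal-probability breakpoints on training instances.

    Parameters
    ----------
    values : (m, 8) array of training MAV values (one row per instance).
    n : alphabet size, 2..26.

    Breakpoints are type-1 empirical quantiles (inverse ECDF) at k/n,
    k = 1..n-1, so that on the training data each symbol is as close to
    probability 1/n as ties allow.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != _N_CHANNELS:
        raise ValueError(f"expected 8 channels, got {values.shape[1]}")
    if not 2 <= n <= _MAX_ALPHABET:
        raise ValueError(f"alphabet size must be in 2..{_MAX_ALPHABET}, got {n}")
    if values.shape[0] < n:
        raise ValueError(f"need at least {n} instances to fit {n} quantile bins, got {values.shape[0]}")
    q = np.arange(1, n) / n
    bp = np.quantile(values, q, axis=0, method="inverted_cdf").T  # (8, n-1)
    return SaxCodebook(n=n, breakpoints=bp)


def encode(values: np.ndarray, codebook: SaxCodebook) -> np.ndarray:
    """Encode MAV instances as words (integer ranks, shape (m, 8), int16).

    Per channel the rank is the number of breakpoints strictly below the
    value; values equal to a breakpoint fall to the lower interval.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != _N_CHANNELS:
        raise ValueError(f"expected 8 channels, got {values.shape[1]}")
    words = np.empty(values.shape, dtype=np.int16)
    for j in range(_N_CHANNELS):
        words[:, j] = np.searchsorted(codebook.breakpoints[j], values[:, j], side="left")
    return words


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=int).ravel()
    b = np.asarray(b, dtype=int).ravel()
    if a.shape != (_N_CHANNELS,) or b.shape != (_N_CHANNELS,):
        raise ValueError("words must have exactly 8 symbols")
    return a, b


def lexical_distance(a, b) -> int:
    """d_l: sum over the 8 positions of the absolute rank difference."""
    a, b = _check_pair(a, b)
    return int(np.abs(a - b).sum())


def modified_lexical_distance(a, b) -> int:
    """Per position 0 if symbols are equal, else |rank difference| - 1; summed.

    Example (5-symbol alphabet): D('AAAAAAAA', 'AACCBBEE') = 0+0+1+1+0+0+3+3 = 8.
    Adjacent symbols cost 0, so this is not a metric (identity of
    indiscernibles fails); it is symmetric and non-negative.
    """
    a, b = _check_pair(a, b)
    d = np.abs(a - b)
    return int((d - (d > 0)).sum())


def words_to_strings(words: np.ndarray) -> list[str]:
    """Render integer-rank words as letter strings ('A' = rank 0)."""
    words = np.atleast_2d(np.asarray(words, dtype=int))
    if np.any(words < 0) or np.any(words >= _MAX_ALPHABET):
        raise ValueError("ranks must be in 0..25 for letter rendering")
    return ["".join(chr(ord("A") + r) for r in row) for row in words]


def strings_to_words(strings) -> np.ndarray:
    """Parse letter strings back to integer-rank words (m, 8)."""
    out = np.empty((len(strings), _N_CHANNELS), dtype=np.int16)
    for i, s in enumerate(strings):
        if len(s) != _N_CHANNELS:
            raise ValueError(f"word {s!r} does not have 8 letters")
        for j, ch in enumerate(s):
            r = ord(ch.upper()) - ord("A")
            if not 0 <= r < _MAX_ALPHABET:
                raise ValueError(f"invalid symbol {ch!r} in word {s!r}")
            out[i, j] = r
    return out
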