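"""Symbolic aggregate approximation (SAX) of chromatographic traces.

An EIC is z-normalised and each point mapped to a letter via standard-normal
breakpoints, giving a compact symbolic shape. The MINDIST lower-bound distance
compares such sequences (e.g. a sample peak against the consensus reference
shape), and the zigzag detector flags alternating spike patterns that indicate
noise rather than chromatography. One letter is kept per raw data point — no
word compression — because peak bounds are edited at specific retention-time
indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .eic import EIC

_ALPHABET = "abcdefghijklmnopqrst"


@dataclass
class SAXSeq:
    letters: str
    alphabet_size: int
    breakpoints: np.ndarray   # (alphabet_size - 1,) standard-normal thresholds

    def __post_init__(self) -> None:
        alpha = set(_ALPHABET[: self.alphabet_size])
        if set(self.letters) - alpha:
            raise ValueError("letters outside the declared alphabet")

    @property
    def source_len(self) -> int:
        return len(self.letters)

    def indices(self) -> np.ndarray:
        return np.frombuffer(self.letters.encode("ascii"), dtype=np.uint8) - ord("a")


def sax_breakpoints(alphabet_size: int) -> np.ndarray:
    """Equiprobable standard-normal breakpoints for the given alphabet size."""
    return norm.ppf(np.arange(1, alphabet_size) / alphabet_size)


def encode_sax(intensities, alphabet_size: int = 7) -> SAXSeq:
    """Encode a trace as one SAX letter per point.

    Intensities are z-normalised; each value falls into the standard-normal
    bin whose letter it receives (bin i covers [bp[i-1], bp[i])). A constant
    trace has no shape and maps every point to the middle letter.
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) < 2:
        raise ValueError("SAX encoding needs at least 2 points")
    if not 2 <= alphabet_size <= 20:
        raise ValueError("alphabet size must be in [2, 20]")
    bp = sax_breakpoints(alphabet_size)
    sd = x.std()
    if sd == 0:
        idx = np.full(len(x), (alphabet_size - 1) // 2)
    else:
        z = (x - x.mean()) / sd
        idx = np.searchsorted(bp, z, side="right")
    letters = "".join(_ALPHABET[i] for i in idx)
    return SAXSeq(letters, alphabet_size, bp)


def _resample_indices(idx: np.ndarray, n: int) -> np.ndarray:
    """Linear index-resampling of a letter-index sequence to length n."""
    if len(idx) == n:
        return idx
    pos = np.linspace(0, len(idx) - 1, n)
    return idx[np.round(pos).astype(int)]


def mindist(seq_a: SAXSeq, seq_b: SAXSeq) -> float:
    """SAX lower-bound distance between two letter sequences.

    Uses the standard breakpoint lookup table: letters at distance <= 1
    contribute nothing, otherwise the gap between their nearest breakpoints.
    Sequences of unequal length are index-resampled to the longer one. With
    one letter per point the word length equals the series length, so no
    compression scaling applies and the value lower-bounds the Euclidean
    distance of the z-normalised traces.
    """
    if seq_a.alphabet_size != seq_b.alphabet_size:
        raise ValueError("MINDIST requires equal alphabet sizes")
    bp = seq_a.breakpoints
    ia, ib = seq_a.indices(), seq_b.indices()
    n = max(len(ia), len(ib))
    ia, ib = _resample_indices(ia, n), _resample_indices(ib, n)
    hi = np.maximum(ia, ib)
    lo = np.minimum(ia, ib)
    gap = hi - lo > 1
    cell = np.zeros(n)
    cell[gap] = bp[hi[gap] - 1] - bp[lo[gap]]
    return float(np.sqrt(np.sum(cell ** 2)))


def zero_out_bounds(seq: SAXSeq, indices) -> SAXSeq:
    """Set the letters at peak start/end/split indices to the lowest letter."""
    letters = list(seq.letters)
    for i in indices:
        if not 0 <= i < len(letters):
            raise IndexError(f"index {i} outside SAX sequence of {len(letters)}")
        letters[i] = "a"
    return replace(seq, letters="".join(letters))


def zigzag_fraction(eic: EIC, baseline: float, noise: float,
                    min_run: int = 4) -> float:
    """Fraction of the trace covered by alternating high/near-baseline spikes.

    A point is an alternation candidate when it sits above baseline + 3*noise
    while both neighbours sit at or below baseline + noise, or the mirror
    case. Maximal runs of consecutive candidates spanning at least ``min_run``
    points (candidates plus their two bracketing neighbours) are flagged; the
    returned value is flagged points / total points.
    """
    y = np.asarray(eic.intensity, dtype=float)
    n = len(y)
    if n < 3:
        return 0.0
    hi_thr = baseline + 3.0 * noise
    lo_thr = baseline + noise
    high = y > hi_thr
    low = y <= lo_thr
    cand = np.zeros(n, dtype=bool)
    mid = slice(1, n - 1)
    cand[mid] = (high[mid] & low[:-2] & low[2:]) | (low[mid] & high[:-2] & high[2:])
    flagged = np.zeros(n, dtype=bool)
    i = 1
    while i < n - 1:
        if cand[i]:
            j = i
            while j < n - 1 and cand[j]:
                j += 1
            if (j - i) + 2 >= min_run:
                flagged[i - 1:j + 1] = True
            i = j
        else:
            i += 1
    return float(flagged.sum()) / n
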