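"""Gapped dinucleotide counting and frequency profiles.

For a sequence ``s`` of length ``n`` and a separation distance ``d``
(``d = 1`` means adjacent, i.e. X and Y are separated by ``d - 1``
nucleotides), every position ``i`` in ``[1, n - d]`` contributes one
ordered pair ``(s[i], s[i + d])``.  The 16 pair counts therefore sum to
``n - d``, and dividing by ``n - d`` gives a frequency vector on the
simplex.  Stacking the vectors for ``d = 1..d0`` yields the ``d0 x 16``
frequency matrix; its row-major flattening is the ``16 * d0``-dimensional
frequency vector used by the cosine distance.

The depth is capped at ``floor(n / 4)`` by default so that the X-window
``[1, n - d]`` and the Y-window ``[d + 1, n]`` overlap on at least half
of the sequence (``(n - 2d) / n >= 50%``); pass ``enforce_bound=False``
to explore deeper separations up to ``n - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from dinuprof.sequence_io import DnaSequence

#: The fixed ordered alphabet of the 16 ordered dinucleotides.  Every
#: 16-vector, matrix column block and flattened vector uses this order,
#: so serialized artifacts are reproducible byte for byte.
OMEGA: tuple[str, ...] = (
    "AT", "AA", "AC", "AG",
    "TT", "TA", "TC", "TG",
    "GT", "GA", "GC", "GG",
    "CT", "CA", "CC", "CG",
)

PAIR_INDEX: dict[str, int] = {pair: i for i, pair in enumerate(OMEGA)}

# Nucleotide -> code such that code(X) * 4 + code(Y) indexes a 4x4 table
# remapped onto the OMEGA order below.
_NUC_CODE = {"A": 0, "T": 1, "G": 2, "C": 3}
_CODE_TO_OMEGA = np.empty(16, dtype=np.intp)
for _x, _cx in _NUC_CODE.items():
    for _y, _cy in _NUC_CODE.items():
        _CODE_TO_OMEGA[_cx * 4 + _cy] = PAIR_INDEX[_x + _y]


def _encode(residues: str) -> np.ndarray:
    """Map residues to integer codes; non-ACGT becomes -1 (masked later)."""
    table = np.full(128, -1, dtype=np.int8)
    for nuc, code in _NUC_CODE.items():
        table[ord(nuc)] = code
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return table[arr]


@dataclass(frozen=True)
class GapPairCounts:
    """Counts of the 16 ordered pairs at one separation distance."""

    d: int
    counts: np.ndarray  # 16 non-negative ints in OMEGA order
    n: int
    n_pairs: int  # pairs actually counted: n - d, minus skipped ambiguous

    def __getitem__(self, pair: str) -> int:
        return int(self.counts[PAIR_INDEX[pair]])


@dataclass(frozen=True)
class GapFrequencyVector:
    """The 16 pair frequencies at one separation distance (sums to 1)."""

    d: int
    freqs: np.ndarray

    def __getitem__(self, pair: str) -> float:
        return float(self.freqs[PAIR_INDEX[pair]])


@dataclass(frozen=True)
class FrequencyMatrix:
    """The ``d0 x 16`` stack of frequency vectors for ``d = 1..d0``."""

    label: str
    values: np.ndarray  # shape (d0, 16), row d-1 is the distance-d vector
    d0: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, d: int) -> GapFrequencyVector:
        if not 1 <= d <= self.d0:
            raise ValueError(f"d={d} outside 1..{self.d0}")
        return GapFrequencyVector(d=d, freqs=self.values[d - 1])


def max_valid_distance(n: int) -> int:
    """Largest separation distance for a length-``n`` sequence: floor(n/4).

    This keeps the overlap between the X- and Y-windows at >= 50% of the
    sequence, so most positions are seen as both pair start and pair end.
    """
    if n < 4:
        raise ValueError(f"sequence length {n} < 4: no valid distance exists")
    return n // 4


def _check_d(seq: DnaSequence, d: int) -> None:
    if d < 1:
        raise ValueError(f"separation distance d={d} must be >= 1")
    if d >= seq.n:
        raise ValueError(
            f"separation distance d={d} >= sequence length {seq.n} "
            f"(record {seq.id!r}): no pairs exist"
        )


def count_pairs(seq: DnaSequence, d: int) -> GapPairCounts:
    """Count ordered pairs ``(s[i], s[i+d])`` over all ``i in [1, n-d]``.

    Occurrences overlap freely: one position may serve as the X of one
    pair and the Y of another.  Pairs touching a non-ACGT residue are
    skipped (only possible for sequences read in permissive mode), and
    ``n_pairs`` records how many pairs were retained.
    """
    _check_d(seq, d)
    codes = _encode(seq.residues)
    x, y = codes[:-d], codes[d:]
    valid = (x >= 0) & (y >= 0)
    pair_codes = _CODE_TO_OMEGA[(x[valid] * 4 + y[valid]).astype(np.intp)]
    counts = np.bincount(pair_codes, minlength=16).astype(np.int64)
    return GapPairCounts(d=d, counts=counts, n=seq.n, n_pairs=int(valid.sum()))


def frequency_vector(seq: DnaSequence, d: int) -> GapFrequencyVector:
    """Pair frequencies at separation ``d``: counts divided by ``n - d``.

    In permissive mode the denominator is the number of retained pairs,
    so the frequencies always sum to 1.
    """
    pc = count_pairs(seq, d)
    if pc.n_pairs == 0:
        raise ValueError(
            f"record {seq.id!r}: no unambiguous pairs at distance {d}"
        )
    return GapFrequencyVector(d=d, freqs=pc.counts / pc.n_pairs)


def frequency_matrix(
    seq: DnaSequence, d0: int, *, enforce_bound: bool = True
) -> FrequencyMatrix:
    """Stack the frequency vectors for ``d = 1..d0`` into a matrix.

    ``d0`` must not exceed ``floor(n / 4)`` unless ``enforce_bound`` is
    False, in which case any ``d0 <= n - 1`` is accepted with a warning
    (the window overlap drops below 50% and the deeper rows are noisy).
    """
    if d0 < 1:
        raise ValueError(f"depth d0={d0} must be >= 1")
    bound = max_valid_distance(seq.n)
    if d0 > bound:
        if enforce_bound:
            raise ValueError(
                f"depth d0={d0} exceeds floor(n/4)={bound} for record "
                f"{seq.id!r} (n={seq.n}); pass enforce_bound=False to override"
            )
        if d0 >= seq.n:
            raise ValueError(f"depth d0={d0} >= sequence length {seq.n}")
        warnings.warn(
            f"depth d0={d0} exceeds floor(n/4)={bound} for record "
            f"{seq.id!r}: the X/Y window overlap (n-2d)/n falls below 50%",
            stacklevel=2,
        )
    rows = np.empty((d0, 16), dtype=np.float64)
    for d in range(1, d0 + 1):
        rows[d - 1] = frequency_vector(seq, d).freqs
    return FrequencyMatrix(label=seq.id, values=rows, d0=d0)


def flatten(fm: FrequencyMatrix) -> np.ndarray:
    """Row-major flattening (d = 1 block first): the ``16*d0``-vector."""
    return fm.values.reshape(-1).copy()
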