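"""Distance measures between dinucleotide frequency profiles.

Two measures are provided.  ``d1`` is the city-block (Manhattan)
distance between two ``d0 x 16`` frequency matrices: the sum of absolute
cell-wise differences.  ``d2`` is the cosine distance between the
flattened ``16 * d0`` frequency vectors: one minus the cosine of the
included angle, which lies in [0, 1] because all entries are
non-negative.  A set of sequences shares one common depth
``d0 = min over the set of floor(n / 4)``, so all profiles have equal
shape; longer sequences still contribute all their pairs at each
``d <= d0`` (no truncation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from dinuprof.profile import FrequencyMatrix, flatten, frequency_matrix, max_valid_distance
from dinuprof.sequence_io import SequenceSet

METRICS = ("d1", "d2")


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, zero-diagonal matrix of pairwise distances."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric_name: str  # "d1" or "d2"
    d0: int

    def __post_init__(self) -> None:
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("labels and matrix shape disagree")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.labels), columns=list(self.labels)
        )

    def write(
        self,
        path: Union[str, Path],
        *,
        fmt: str = "tsv",
        precision: int = 4,
        upper: bool = False,
    ) -> None:
        """Write the matrix as TSV, CSV or square PHYLIP.

        ``upper`` blanks the strict lower triangle (TSV/CSV only), the
        layout used in printed distance tables.  ``precision`` affects
        formatting only, never the stored values.
        """
        path = Path(path)
        if fmt == "phylip":
            with open(path, "w") as fh:
                fh.write(f"{len(self.labels)}\n")
                for label, row in zip(self.labels, self.values):
                    cells = " ".join(f"{v:.{precision}f}" for v in row)
                    fh.write(f"{label:<10s} {cells}\n")
            return
        if fmt not in ("tsv", "csv"):
            raise ValueError(f"unknown format {fmt!r}")
        sep = "\t" if fmt == "tsv" else ","
        with open(path, "w") as fh:
            fh.write("Species" + sep + sep.join(self.labels) + "\n")
            for i, label in enumerate(self.labels):
                cells = [
                    "" if upper and j < i else f"{self.values[i, j]:.{precision}f}"
                    for j in range(len(self.labels))
                ]
                fh.write(label + sep + sep.join(cells) + "\n")


def common_depth(seqs: SequenceSet) -> int:
    """The shared profile depth: min over the set of floor(n / 4)."""
    return min(max_valid_distance(rec.n) for rec in seqs)


def city_block(fa: FrequencyMatrix, fb: FrequencyMatrix) -> float:
    """City-block distance d1: sum of |Fij(s) - Fij(h)| over all cells.

    Accumulation runs row-major (d = 1..d0, then the 16 pair columns) so
    repeated runs are bit-identical.
    """
    if fa.shape != fb.shape:
        raise ValueError(f"shape mismatch: {fa.shape} vs {fb.shape}")
    diff = np.abs(fa.values - fb.values)
    return float(sum(diff.reshape(-1)))


def cosine_distance(va: np.ndarray, vb: np.ndarray) -> float:
    """Cosine distance d2: one minus the cosine of the included angle.

    For frequency vectors (all entries >= 0) the result lies in [0, 1]:
    0 for parallel vectors, 1 for disjoint support.
    """
    va = np.asarray(va, dtype=np.float64).reshape(-1)
    vb = np.asarray(vb, dtype=np.float64).reshape(-1)
    if va.shape != vb.shape:
        raise ValueError(f"length mismatch: {va.shape[0]} vs {vb.shape[0]}")
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    return 1.0 - float(va @ vb) / (na * nb)


def profiles_for_set(
    seqs: SequenceSet, d0: Optional[int] = None, *, enforce_bound: bool = True
) -> tuple[list[FrequencyMatrix], int]:
    """Profile every record at the shared depth (common depth if None)."""
    if d0 is None:
        d0 = common_depth(seqs)
    return [
        frequency_matrix(rec, d0, enforce_bound=enforce_bound) for rec in seqs
    ], d0


def pairwise_matrix(
    seqs: SequenceSet,
    metric: str = "d1",
    d0: Optional[int] = None,
    *,
    enforce_bound: bool = True,
) -> DistanceMatrix:
    """Full symmetric pairwise distance matrix in input record order."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    mats, d0 = profiles_for_set(seqs, d0, enforce_bound=enforce_bound)
    k = len(mats)
    values = np.zeros((k, k), dtype=np.float64)
    if metric == "d1":
        for i in range(k):
            for j in range(i + 1, k):
                values[i, j] = values[j, i] = city_block(mats[i], mats[j])
    else:
        vecs = [flatten(m) for m in mats]
        for i in range(k):
            for j in range(i + 1, k):
                values[i, j] = values[j, i] = cosine_distance(vecs[i], vecs[j])
    return DistanceMatrix(
        labels=seqs.labels, values=values, metric_name=metric, d0=d0
    )
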