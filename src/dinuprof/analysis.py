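"""Downstream summaries: relative-similarity tables and PCA projection.

The relative-similarity table rescales one row of a distance matrix by
a reference pair's distance, so that the reference pair maps to exactly
1 and other species are read as "how many times farther from the
reference species than the reference partner".

The PCA projects the flattened frequency vectors (one per species,
``16 * d0`` entries on a common scale) onto their top principal
components.  Mean-centred covariance PCA via SVD is used — no
per-feature standardisation, since all features are frequencies on one
scale — and each component's sign is fixed so its largest-magnitude
loading is positive, making plots reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from dinuprof.distance import DistanceMatrix, pairwise_matrix, profiles_for_set
from dinuprof.profile import flatten
from dinuprof.sequence_io import SequenceSet, builtin_beta_globin


@dataclass(frozen=True)
class RelativeSimilarityTable:
    """Distances from a reference species, rescaled so one pair equals 1."""

    reference: str
    partner: str
    metric_name: str
    rows: tuple[tuple[str, float, float], ...]  # (label, raw, relative)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows), columns=["species", "raw", "relative"]
        )


@dataclass(frozen=True)
class PcaProjection:
    """Coordinates on the top-k principal components plus variance shares."""

    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n_species, k)
    explained: np.ndarray    # variance fraction per retained component
    n_components: int

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(
            self.coordinates, index=list(self.labels), columns=cols
        )


def relative_similarity(
    dm: DistanceMatrix, reference: str, partner: str
) -> RelativeSimilarityTable:
    """Rescale the reference species' distances by the reference pair.

    Every species other than the reference gets
    ``relative = dm[reference, x] / dm[reference, partner]``; the
    partner therefore maps to exactly 1.
    """
    for label in (reference, partner):
        if label not in dm.labels:
            raise KeyError(f"label {label!r} not in distance matrix")
    ref_dist = dm[reference, partner]
    if ref_dist == 0.0:
        raise ValueError(
            f"reference pair ({reference}, {partner}) has zero distance; "
            "cannot normalise"
        )
    rows = []
    for label in dm.labels:
        if label == reference:
            continue
        raw = dm[reference, label]
        rows.append((label, raw, raw / ref_dist))
    return RelativeSimilarityTable(
        reference=reference,
        partner=partner,
        metric_name=dm.metric_name,
        rows=tuple(rows),
    )


def pca_project(
    vectors: Sequence[np.ndarray],
    labels: Sequence[str],
    k: int = 2,
) -> PcaProjection:
    """Project one frequency vector per species onto the top-k components.

    Vectors are mean-centred and decomposed by SVD; ``explained`` holds
    each retained component's fraction of the total variance.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 equal-length vectors")
    if len(labels) != X.shape[0]:
        raise ValueError("one label per vector required")
    max_k = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= k <= max_k:
        raise ValueError(f"k={k} outside 1..{max_k}")
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("total variance is zero: all vectors identical")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    # Deterministic sign: largest-magnitude loading of each component > 0.
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    return PcaProjection(
        labels=tuple(labels),
        coordinates=coords,
        explained=pca.explained_variance_ratio_.copy(),
        n_components=k,
    )


def reproduce_all(
    out_dir: Union[str, Path],
    seqs: Optional[SequenceSet] = None,
    *,
    precision: int = 4,
    plots: bool = False,
) -> dict[str, Path]:
    """Run the full benchmark pipeline and write its tables.

    Computes both pairwise distance matrices at the common depth, the
    human-referenced relative-similarity table (human-gorilla pair = 1)
    and the 2-component PCA of the flattened vectors, writing one TSV
    per artifact into ``out_dir``.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seqs is None:
        seqs = builtin_beta_globin()
    written: dict[str, Path] = {}

    dms = {m: pairwise_matrix(seqs, m) for m in ("d1", "d2")}
    for metric, fname in (("d1", "table3_d1.tsv"), ("d2", "table4_d2.tsv")):
        path = out_dir / fname
        dms[metric].write(path, fmt="tsv", precision=precision, upper=True)
        written[fname] = path

    rel_frames = []
    for metric in ("d1", "d2"):
        rel = relative_similarity(dms[metric], "Human", "Gorilla")
        df = rel.to_dataframe().rename(
            columns={"raw": f"{metric}_raw", "relative": f"{metric}_relative"}
        )
        rel_frames.append(df.set_index("species"))
    rel_df = rel_frames[0].join(rel_frames[1])
    path = out_dir / "fig1_relative.tsv"
    rel_df.to_csv(path, sep="\t", float_format=f"%.{precision}f")
    written["fig1_relative.tsv"] = path

    mats, _d0 = profiles_for_set(seqs)
    proj = pca_project([flatten(m) for m in mats], seqs.labels, k=2)
    path = out_dir / "fig2_pca_coords.tsv"
    proj.to_dataframe().to_csv(path, sep="\t", float_format=f"%.{precision}f")
    written["fig2_pca_coords.tsv"] = path
    path = out_dir / "fig2_pca_explained.tsv"
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(proj.n_components)],
            "explained_fraction": proj.explained,
        }
    ).to_csv(path, sep="\t", index=False, float_format=f"%.{precision}f")
    written["fig2_pca_explained.tsv"] = path

    if plots:
        written.update(_write_plots(out_dir, rel_df, proj))
    return written


def _write_plots(out_dir: Path, rel_df: pd.DataFrame, proj: PcaProjection):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    fig, ax = plt.subplots(figsize=(7, 4))
    for col in ("d1_relative", "d2_relative"):
        ax.plot(rel_df.index, rel_df[col], marker="o", label=col[:2])
    ax.set_ylabel("distance relative to Human-Gorilla")
    ax.legend()
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    path = out_dir / "fig1_relative.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written["fig1_relative.png"] = path

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(proj.coordinates[:, 0], proj.coordinates[:, 1])
    for label, (x, y) in zip(proj.labels, proj.coordinates):
        ax.annotate(label, (x, y), fontsize=8)
    ax.set_xlabel(f"PC1 ({proj.explained[0]:.0%})")
    ax.set_ylabel(f"PC2 ({proj.explained[1]:.0%})")
    fig.tight_layout()
    path = out_dir / "fig2_pca.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written["fig2_pca.png"] = path
    return written
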