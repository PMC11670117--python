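"""Clustering of protein abundance profiles across differentiation.

Protein abundances measured over a differentiation time course (e.g.
days 0–12 of stem-cell-to-neuron conversion) are row z-scored so that
clustering groups proteins by the *shape* of their trajectory rather than
by absolute abundance, then partitioned with centroid-based (k-means)
clustering. Clusters are relabelled by descending size with contiguous
ids starting at 1, so the labelling is stable and reproducible.

The number of clusters is a user choice; ``TimecourseModel.elbow`` emits
the within-cluster dispersion across a range of k as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)


def zscore(m: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, list[str]]:
    """Row z-score a protein × timepoint matrix (sample sd, n−1 by default).

    Each returned row has mean 0 and sd 1. Constant rows (sd 0) cannot be
    z-scored; they are dropped and their ids returned (and logged).
    Already z-scored input is unchanged (idempotent).
    """
    x = m.astype(float)
    sd = x.std(axis=1, ddof=ddof)
    constant = list(x.index[(sd == 0) | sd.isna()])
    if constant:
        log.warning("dropping %d constant row(s) before z-scoring", len(constant))
        x = x.drop(index=constant)
        sd = sd.drop(index=constant)
    z = x.sub(x.mean(axis=1), axis=0).div(sd, axis=0)
    return z, constant


@dataclass
class ClusterResults:
    """A centroid-based partition of z-scored trajectories.

    ``assignment`` maps protein id → cluster id (contiguous from 1,
    ordered by descending cluster size); ``centroids`` is cluster ×
    timepoint in z units; ``dispersion`` is the total within-cluster sum
    of squared distances.
    """

    assignment: pd.Series
    centroids: pd.DataFrame
    dispersion: float
    k: int
    seed: int

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster_id])

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def summary(self) -> str:
        lines = [
            "Time-course clustering results",
            "=" * 40,
            f"k = {self.k}, seed = {self.seed}",
            f"proteins assigned: {len(self.assignment)}",
            f"within-cluster dispersion: {self.dispersion:.3f}",
            "cluster sizes: "
            + ", ".join(f"{c}: {n}" for c, n in self.sizes().items()),
        ]
        return "\n".join(lines)


class TimecourseModel:
    """Trajectory-shape clustering model for a time-course matrix.

    Parameters
    ----------
    data : DataFrame
        Protein × timepoint abundances (linear or log scale); rows are
        z-scored internally. At least 3 timepoints are required and
        all-missing rows are rejected.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[1] < 3:
            raise ValueError("need at least 3 timepoints")
        if data.isna().all(axis=1).any():
            raise ValueError("all-missing rows in time-course matrix")
        self.data = data
        self.z, self.dropped = zscore(data)

    def fit(self, k: int = 6, seed: int = 0, n_restarts: int = 10) -> ClusterResults:
        """Best-of-``n_restarts`` k-means partition of the z-scored rows.

        Deterministic for a fixed seed; clusters relabelled by descending
        size (ties broken by original k-means label for stability).
        """
        n = len(self.z)
        if k < 2:
            raise ValueError("k must be at least 2")
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} clusterable proteins")
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        raw = km.fit_predict(self.z.to_numpy())

        # relabel by descending cluster size, ids contiguous from 1
        sizes = pd.Series(raw).value_counts()
        order = sorted(range(k), key=lambda c: (-sizes.get(c, 0), c))
        relabel = {old: new + 1 for new, old in enumerate(order)}
        labels = np.array([relabel[c] for c in raw])

        centroids = pd.DataFrame(
            km.cluster_centers_[order],
            index=pd.Index(range(1, k + 1), name="cluster"),
            columns=self.z.columns,
        )
        return ClusterResults(
            assignment=pd.Series(labels, index=self.z.index, name="cluster"),
            centroids=centroids,
            dispersion=float(km.inertia_),
            k=k,
            seed=seed,
        )

    def elbow(self, ks=range(2, 11), seed: int = 0, n_restarts: int = 10) -> pd.Series:
        """Within-cluster dispersion for each candidate k (elbow diagnostic)."""
        out = {}
        for k in ks:
            if k > len(self.z):
                break
            out[k] = self.fit(k=k, seed=seed, n_restarts=n_restarts).dispersion
        return pd.Series(out, name="dispersion").rename_axis("k")
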