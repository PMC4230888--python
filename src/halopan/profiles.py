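"""Phylogenetic profiling: cluster families by presence/absence pattern.

Families with correlated phylogenetic distributions often act in the
same process, so unannotated families clustering with a functionally
coherent annotated group inherit that function as a testable
hypothesis (annotation transfer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .pangenome import PresenceAbsenceMatrix


@dataclass
class ProfileClustering:
    family_ids: list[str]
    distances: np.ndarray        # condensed form (scipy convention)
    dendrogram: np.ndarray       # scipy linkage matrix
    flat_clusters: dict[str, int]

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for fid in self.family_ids:  # deterministic family-ID order
            out.setdefault(self.flat_clusters[fid], []).append(fid)
        return out

    def square_distances(self) -> pd.DataFrame:
        return pd.DataFrame(
            squareform(self.distances), index=self.family_ids, columns=self.family_ids
        )


def profile_distances(
    matrix: PresenceAbsenceMatrix,
    family_subset: list[str] | None = None,
    binarize: bool = True,
) -> tuple[list[str], np.ndarray]:
    """Euclidean distances between family profiles.

    d(f, g) = sqrt(sum over species of (b_f - b_g)^2) on binarized
    presence vectors (``binarize=False`` uses copy numbers). Returns
    (family_ids, condensed distance vector).
    """
    data = matrix.binary() if binarize else matrix.counts
    fids = sorted(family_subset) if family_subset is not None else list(data.index)
    if len(fids) < 2:
        raise ValueError("need at least two families")
    sub = data.loc[fids].to_numpy(float)
    return fids, pdist(sub, metric="euclidean")


def cluster_profiles(
    family_ids: list[str],
    distances: np.ndarray,
    method: str = "average",
    cut_height: float | None = None,
    n_clusters: int | None = None,
) -> ProfileClustering:
    """Agglomerative clustering of the profile distance matrix.

    Cut either at *cut_height* or into *n_clusters* flat clusters
    (exactly one must be given). Ties break deterministically because
    families enter in sorted-ID order.
    """
    if (cut_height is None) == (n_clusters is None):
        raise ValueError("give exactly one of cut_height / n_clusters")
    Z = linkage(distances, method=method)
    if cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    else:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return ProfileClustering(
        family_ids=list(family_ids),
        distances=distances,
        dendrogram=Z,
        flat_clusters=dict(zip(family_ids, (int(x) for x in labels))),
    )


def propose_annotations(
    clustering: ProfileClustering,
    categories: dict[str, str],
    majority_fraction: float = 0.8,
) -> list[dict]:
    """Annotation-transfer hypotheses for unannotated families.

    *categories* maps annotated family_id -> functional category
    (families absent from the map are unannotated). For every cluster
    in which at least *majority_fraction* of the annotated members
    share one category, each unannotated member is proposed to carry
    that category, with the supporting members listed.
    """
    proposals: list[dict] = []
    for cluster_id, members in sorted(clustering.cluster_members().items()):
        annotated = [f for f in members if f in categories]
        unannotated = [f for f in members if f not in categories]
        if not annotated or not unannotated:
            continue
        tally: dict[str, list[str]] = {}
        for f in annotated:
            tally.setdefault(categories[f], []).append(f)
        category, supporters = max(tally.items(), key=lambda kv: (len(kv[1]), kv[0]))
        if len(supporters) / len(annotated) >= majority_fraction:
            for f in unannotated:
                proposals.append(
                    {
                        "family_id": f,
                        "proposed_category": category,
                        "cluster": cluster_id,
                        "supporters": sorted(supporters),
                        "n_annotated_in_cluster": len(annotated),
                    }
                )
    return proposals
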