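"""Expression-profile clustering and oxygen-phase regulation calls.

Profiles are grouped by agglomerative clustering under the correlation
distance 1 - Pearson r (so shape, not level, drives grouping). Each
cluster's mean profile is then contrasted between low-oxygen (anaerobic)
and high-oxygen timepoints: a cluster more expressed under low oxygen is
called positively regulated by the oxygen-sensing factor (FNR-activated),
one more expressed under high oxygen negatively regulated, and small
contrasts are called flat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

LOW_O2 = "anaerobic"
HIGH_O2 = "microaerobic"

FLAT_LABEL = 0  # constant profiles get their own dedicated cluster label

DEFAULT_FLAT_TOLERANCE = 0.5  # dlog2 RPKM


@dataclass
class ClusterAssignment:
    labels: pd.Series  # item_id -> cluster label; 0 is the flat cluster
    n_clusters: int
    linkage_method: str

    @property
    def item_ids(self) -> list[str]:
        return list(self.labels.index)

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass(frozen=True)
class RegulationCall:
    cluster: int
    sign: str  # positive | negative | flat
    contrast: float  # mean(low-O2) - mean(high-O2), dlog2 RPKM


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int | None = None,
    cut_height: float | None = None,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering of items x timepoints profiles with distance
    1 - Pearson. Exactly one of ``k`` or ``cut_height`` must be given.
    Deterministic given the input; labels are renumbered 1..n in order of
    first appearance by item order. Constant (zero-variance) profiles cannot
    be placed under a correlation distance and go to a dedicated flat
    cluster, label 0 (logged)."""
    if (k is None) == (cut_height is None):
        raise ValueError("give exactly one of k or cut_height")
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 items")
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")

    variances = profiles.var(axis=1)
    flat_items = list(profiles.index[variances == 0])
    if flat_items:
        logger.warning("%d constant profiles placed in the flat cluster (0)",
                       len(flat_items))
    active = profiles.drop(index=flat_items)
    labels = pd.Series(FLAT_LABEL, index=profiles.index, dtype=int)
    if len(active) == 0:
        return ClusterAssignment(labels, 0, linkage_method)
    if k is not None and k > len(active):
        raise ValueError(f"k={k} exceeds the {len(active)} clusterable items")

    if len(active) == 1:
        raw = np.array([1])
    else:
        dist = pdist(active.to_numpy(dtype=float), metric="correlation")
        Z = linkage(dist, method=linkage_method)
        if k is not None:
            raw = fcluster(Z, t=k, criterion="maxclust")
        else:
            raw = fcluster(Z, t=cut_height, criterion="distance")
    # canonical labels: order of first appearance in item order
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels.loc[active.index] = [remap[lab] for lab in raw]
    return ClusterAssignment(labels, len(remap), linkage_method)


def cluster_means(
    profiles: pd.DataFrame, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Mean profile per cluster (index: cluster label, incl. flat if present)."""
    return profiles.groupby(assignment.labels).mean()


def classify_regulation_sign(
    cluster_mean_profiles: pd.DataFrame,
    phase_labels: list[str],
    tolerance: float = DEFAULT_FLAT_TOLERANCE,
) -> list[RegulationCall]:
    """Call each cluster positive / negative / flat from the phase contrast
    mean(low-O2 timepoints) - mean(high-O2 timepoints) of its mean profile.
    ``phase_labels`` gives one of {anaerobic, microaerobic} per timepoint."""
    phases = np.asarray(phase_labels)
    if phases.size != cluster_mean_profiles.shape[1]:
        raise ValueError("one phase label per timepoint required")
    low = phases == LOW_O2
    high = phases == HIGH_O2
    if not low.any() or not high.any():
        raise ValueError("both oxygen phases must be represented among timepoints")
    calls = []
    for label, row in cluster_mean_profiles.iterrows():
        vals = row.to_numpy(dtype=float)
        contrast = float(vals[low].mean() - vals[high].mean())
        if contrast >= tolerance:
            sign = "positive"
        elif contrast <= -tolerance:
            sign = "negative"
        else:
            sign = "flat"
        calls.append(RegulationCall(cluster=int(label), sign=sign, contrast=contrast))
    return calls


def write_clusters(
    assignment: ClusterAssignment,
    calls: list[RegulationCall],
    path,
) -> None:
    sign_of = {c.cluster: c.sign for c in calls}
    pd.DataFrame(
        {
            "item_id": assignment.item_ids,
            "cluster": assignment.labels.values,
            "sign": [sign_of.get(int(l), "flat") for l in assignment.labels.values],
        }
    ).to_csv(path, sep="\t", index=False)
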