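"""Entropy-based filtering of enzyme clusters.

Each cluster S_V is scored by the Shannon entropy of its members' KEGG group
identifiers,

    H(S_V) = - sum_i p_i log p_i

where p_i is the fraction of S_V carrying group ID i.  Low entropy means the
cluster is functionally uniform; clusters with entropy no larger than the
threshold (default 0.5, boundary inclusive) are retained.

The natural logarithm is the default: at threshold 0.5 it admits a 90/10
two-group split (H ~ 0.325) but rejects a 50/50 split (H = ln 2 ~ 0.693).
Base 2 is selectable for sensitivity analysis.  Members lacking a group ID
carry no consistency evidence and are excluded from the fractions; a cluster
with no annotated member at all gets NaN ("unannotated") and always fails
the filter.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .alignment import EnzymeCluster
from .network import MetabolicNetwork, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntropyParams:
    threshold: float = 0.5
    log_base: str = "natural"  # "natural" or "base2"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValidationError("threshold must be >= 0")
        if self.log_base not in ("natural", "base2"):
            raise ValidationError(f"unknown log_base {self.log_base!r}")


def cluster_entropy(
    cluster: EnzymeCluster,
    networks: Mapping[str, MetabolicNetwork],
    log_base: str = "natural",
) -> float:
    """Shannon entropy of the cluster's group-ID composition.

    Returns 0.0 when all annotated members share one group ID and NaN when no
    member carries a group ID (the "unannotated" sentinel, which fails every
    threshold).
    """
    counts: Counter[str] = Counter()
    for org, node in cluster.members:
        net = networks.get(org)
        if net is None or node not in net.nodes:
            raise ValidationError(f"cluster member ({org},{node}) unresolvable")
        gid = net.nodes[node].group_id
        if gid is not None:
            counts[gid] += 1
    total = sum(counts.values())
    if total == 0:
        logger.warning(
            "cluster %d has no annotated member; entropy undefined",
            cluster.cluster_id,
        )
        return math.nan
    log = math.log if log_base == "natural" else math.log2
    return -sum(
        (c / total) * log(c / total) for c in counts.values() if c > 0
    )


def filter_clusters(
    clusters: Sequence[EnzymeCluster],
    networks: Mapping[str, MetabolicNetwork],
    params: EntropyParams = EntropyParams(),
) -> list[EnzymeCluster]:
    """Retain clusters whose entropy is no larger than the threshold.

    Input order is preserved; each retained cluster comes back with its
    ``entropy`` field set.  NaN entropies (unannotated clusters) never pass.
    """
    kept: list[EnzymeCluster] = []
    for cl in clusters:
        h = cluster_entropy(cl, networks, params.log_base)
        if not math.isnan(h) and h <= params.threshold:
            cl.entropy = h
            kept.append(cl)
    return kept
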