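"""End-to-end pipeline: align -> cluster -> filter -> distance -> tree.

Every stage writes its intermediate to the output directory so that runs can
be resumed and inspected; a manifest records parameters and library versions.
Given fixed inputs and parameters the whole run is deterministic, down to
byte-identical output files.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .alignment import (
    ClusterParams,
    EnzymeCluster,
    build_alignment_graph,
    spectral_star_clusters,
)
from .distance import (
    DistanceMatrix,
    distance_matrix,
    write_distance_tsv,
    write_phylip,
)
from .filtering import EntropyParams, filter_clusters
from .network import (
    MetabolicNetwork,
    NodePairScores,
    read_clusters,
    read_scores,
    write_clusters,
    write_scores,
)
from .similarity import AlignParams, pairwise_scores
from .trees import neighbor_joining, upgma, write_newick

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    align: AlignParams = field(default_factory=AlignParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    distance_form: str = "one-minus-jaccard"
    tree_method: str = "nj"  # "nj" or "upgma"
    resume: bool = False


@dataclass
class PipelineResult:
    scores: dict[tuple[str, str], NodePairScores]
    clusters: list[EnzymeCluster]
    filtered: list[EnzymeCluster]
    dm: DistanceMatrix
    tree: object


def _stage(name: str, outputs: list[Path], resume: bool) -> bool:
    """True when the stage must run (some output missing or resume off)."""
    if resume and all(p.exists() for p in outputs):
        logger.info("stage %s: outputs exist, skipped (--resume)", name)
        return False
    return True


def run_pipeline(
    networks: Mapping[str, MetabolicNetwork],
    prior: NodePairScores,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    orgs = sorted(networks)
    t0 = time.perf_counter()

    # align: pairwise converged similarities
    scores: dict[tuple[str, str], NodePairScores] = {}
    for oa, ob in itertools.combinations(orgs, 2):
        path = outdir / f"scores_{oa}_{ob}.tsv"
        if _stage(f"align[{oa},{ob}]", [path], config.resume):
            r = pairwise_scores(networks[oa], networks[ob], prior, config.align)
            write_scores(r, path)
        else:
            r = read_scores(path)
        scores[(oa, ob)] = r
    logger.info("align done in %.2fs", time.perf_counter() - t0)

    # cluster
    clusters_path = outdir / "clusters.tsv"
    if _stage("cluster", [clusters_path], config.resume):
        graph = build_alignment_graph(
            scores.values(), networks, config.cluster.min_weight
        )
        clusters = spectral_star_clusters(graph, config.cluster)
        write_clusters([c.members for c in clusters], clusters_path)
    else:
        clusters = clusters_from_file(clusters_path)

    # filter
    filtered_path = outdir / "clusters_filtered.tsv"
    if _stage("filter", [filtered_path], config.resume):
        filtered = filter_clusters(clusters, networks, config.entropy)
        write_clusters(
            [c.members for c in filtered],
            filtered_path,
            entropies={i: c.entropy for i, c in enumerate(filtered)},
        )
    else:
        filtered = clusters_from_file(filtered_path)

    # distance
    dm = distance_matrix(filtered, orgs, config.distance_form)
    if _stage("dist", [outdir / "dist.tsv", outdir / "dist.phylip"], config.resume):
        write_distance_tsv(dm, outdir / "dist.tsv")
        write_phylip(dm, outdir / "dist.phylip")

    # tree
    build = neighbor_joining if config.tree_method == "nj" else upgma
    tree = build(dm)
    if _stage("tree", [outdir / "tree.nwk"], config.resume):
        write_newick(tree, outdir / "tree.nwk")

    manifest = {
        "netphylo_version": __version__,
        "organisms": orgs,
        "align": asdict(config.align),
        "cluster": asdict(config.cluster),
        "entropy": asdict(config.entropy),
        "distance_form": config.distance_form,
        "tree_method": config.tree_method,
        "n_clusters": len(clusters),
        "n_filtered": len(filtered),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("pipeline done in %.2fs", time.perf_counter() - t0)
    return PipelineResult(scores, clusters, filtered, dm, tree)


def clusters_from_file(path: str | Path) -> list[EnzymeCluster]:
    """Load a clusters.tsv file into numbered EnzymeCluster objects."""
    return [
        EnzymeCluster(i + 1, frozenset(members))
        for i, members in enumerate(read_clusters(path))
    ]


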