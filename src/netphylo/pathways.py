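"""Per-pathway shared-enzyme statistics for a pair of organisms.

Two organisms that sit close in the reconstructed tree share many clusters;
tallying, for each KEGG pathway map, how many constituent enzymes of their
shared clusters are annotated with that pathway localizes *which* parts of
metabolism drive the placement.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import pandas as pd

from .alignment import EnzymeCluster
from .network import MetabolicNetwork, ValidationError


def shared_pathway_counts(
    clusters: Iterable[EnzymeCluster],
    networks: Mapping[str, MetabolicNetwork],
    org_a: str,
    org_b: str,
) -> dict[str, int]:
    """Count constituent enzymes per pathway inside shared clusters.

    Restricted to clusters containing at least one enzyme of each organism;
    every member enzyme belonging to either organism contributes one count to
    each pathway it is annotated with.  Symmetric in (org_a, org_b); pathways
    with zero count are omitted.
    """
    for org in (org_a, org_b):
        if org not in networks:
            raise ValidationError(f"unknown organism {org!r}")
    counts: Counter[str] = Counter()
    for cl in clusters:
        orgs = cl.organisms
        if org_a not in orgs or org_b not in orgs:
            continue
        for org, node in cl.members:
            if org not in (org_a, org_b):
                continue
            rec = networks[org].nodes.get(node)
            if rec is None:
                raise ValidationError(f"member ({org},{node}) unresolvable")
            for pw in rec.pathway_ids:
                counts[pw] += 1
    return dict(counts)


def compare_pairs(
    counts1: Mapping[str, int], counts2: Mapping[str, int]
) -> pd.DataFrame:
    """Outer-join two pathway count maps.

    Columns: pathway_id, count1, count2, difference (= count1 - count2);
    sorted by |difference| descending, ties by pathway_id.
    """
    pathways = sorted(set(counts1) | set(counts2))
    rows = [
        {
            "pathway_id": pw,
            "count1": int(counts1.get(pw, 0)),
            "count2": int(counts2.get(pw, 0)),
            "difference": int(counts1.get(pw, 0)) - int(counts2.get(pw, 0)),
        }
        for pw in pathways
    ]
    df = pd.DataFrame(rows, columns=["pathway_id", "count1", "count2", "difference"])
    if len(df):
        df = df.reindex(
            df.assign(_abs=df["difference"].abs())
            .sort_values(["_abs", "pathway_id"], ascending=[False, True])
            .index
        ).reset_index(drop=True)
    return df
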