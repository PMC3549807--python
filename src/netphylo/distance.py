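"""Organism-by-organism distances from cluster co-membership.

For organisms A and B, let n_both be the number of (entropy-filtered)
clusters containing at least one enzyme of each, and n_either the number
containing at least one enzyme of either.  The Jaccard-style distance

    d(A, B) = 1 - n_both / n_either

is 0 when the organisms always co-occur and 1 when they never share a
cluster.  A cluster counts once no matter how many members it contributes
per organism.  The raw ratio n_both / n_either (a similarity) is exposed as
an alternative form.  The matrix is written both as full-precision TSV and
in the PHYLIP square distance format (10-character names, mangled when
needed, with a sidecar name map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignment import EnzymeCluster
from .network import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric organism distance matrix with entries in [0, 1]."""

    organism_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.organism_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match organism count")
        if len(set(self.organism_ids)) != n:
            raise ValidationError("duplicate organism ids")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("diagonal not zero")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite distances")

    def get(self, org_a: str, org_b: str) -> float:
        i = self.organism_ids.index(org_a)
        j = self.organism_ids.index(org_b)
        return float(self.values[i, j])


def organism_distance(
    clusters: Iterable[EnzymeCluster],
    org_a: str,
    org_b: str,
    form: str = "one-minus-jaccard",
) -> float:
    """Distance between two organisms over a filtered cluster list.

    ``form`` is ``one-minus-jaccard`` (default) or ``raw-ratio`` (the shared
    fraction itself).  When neither organism appears in any cluster the
    distance is 1 (raw ratio 0) with a logged warning.
    """
    if org_a == org_b:
        return 0.0 if form == "one-minus-jaccard" else 1.0
    n_both = 0
    n_either = 0
    for cl in clusters:
        orgs = cl.organisms
        in_a = org_a in orgs
        in_b = org_b in orgs
        if in_a or in_b:
            n_either += 1
        if in_a and in_b:
            n_both += 1
    if n_either == 0:
        logger.warning(
            "organisms %s and %s appear in no cluster; distance set to 1",
            org_a,
            org_b,
        )
        ratio = 0.0
    else:
        ratio = n_both / n_either
    if form == "raw-ratio":
        return ratio
    if form == "one-minus-jaccard":
        return 1.0 - ratio
    raise ValidationError(f"unknown distance form {form!r}")


def distance_matrix(
    clusters: Sequence[EnzymeCluster],
    organism_ids: Sequence[str],
    form: str = "one-minus-jaccard",
) -> DistanceMatrix:
    """All pairwise organism distances (symmetric, zero diagonal)."""
    ids = list(organism_ids)
    if not ids:
        raise ValidationError("no organisms")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate organism ids")
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = organism_distance(clusters, ids[i], ids[j], form)
            vals[i, j] = vals[j, i] = d
    if form == "raw-ratio":
        # raw ratio is a similarity with unit diagonal; keep it symmetric but
        # bypass the zero-diagonal distance validation
        np.fill_diagonal(vals, 1.0)
        dm = DistanceMatrix.__new__(DistanceMatrix)
        dm.organism_ids = ids
        dm.values = vals
        return dm
    return DistanceMatrix(ids, vals)


def _mangle_names(names: Sequence[str]) -> dict[str, str]:
    """Map organism ids to unique 10-character PHYLIP taxon names."""
    out: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        short = name[:10]
        if short in used:
            k = 1
            while True:
                suffix = str(k)
                cand = name[: 10 - len(suffix)] + suffix
                if cand not in used:
                    short = cand
                    break
                k += 1
        used.add(short)
        out[name] = short
    return out


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Write the square PHYLIP distance format plus a name-map sidecar.

    Names longer than 10 characters are truncated and disambiguated with a
    numeric suffix; the sidecar ``<path>.names.tsv`` maps mangled names back
    to the originals.
    """
    path = Path(path)
    mangled = _mangle_names(dm.organism_ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(dm.organism_ids)}\n")
        for i, org in enumerate(dm.organism_ids):
            row = " ".join(f"{dm.values[i, j]:.6f}" for j in range(len(dm.organism_ids)))
            fh.write(f"{mangled[org]:<10} {row}\n")
    with open(path.with_name(path.name + ".names.tsv"), "w", encoding="utf-8") as fh:
        for org in dm.organism_ids:
            fh.write(f"{mangled[org]}\t{org}\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Re-parse a square PHYLIP matrix written by :func:`write_phylip`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    names: list[str] = []
    vals = np.zeros((n, n))
    for i, line in enumerate(lines[1 : n + 1]):
        name = line[:10].strip()
        cells = line[10:].split()
        names.append(name)
        vals[i] = [float(c) for c in cells]
    # symmetrize against 6-decimal rounding before validation
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(names, vals)


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Full-precision TSV: header row/column of organism ids."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("organism\t" + "\t".join(dm.organism_ids) + "\n")
        for i, org in enumerate(dm.organism_ids):
            row = "\t".join(f"{v:.17g}" for v in dm.values[i])
            fh.write(f"{org}\t{row}\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        vals = []
        for line in fh:
            if line.strip():
                vals.append([float(c) for c in line.rstrip("\n").split("\t")[1:]])
    return DistanceMatrix(header, np.array(vals))
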