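"""Prophage clustering, strain phagotypes and prophage-conferred immunity.

Active prophages are clustered from a pairwise intergenomic-similarity
matrix (percent scale, as produced by whole-genome phage similarity tools)
by single-linkage at a chosen threshold — 95% approximating phage species,
70% genera.  Each strain's combination of genus-level clusters defines its
*phagotype*; strains of the same (or nested) phagotype are expected to be
immune to each other's induced phages, which `protection_statistic`
quantifies against a plaque-assay matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

RELATIONS = ("equal", "subset_either", "donor_subset_of_recipient")


@dataclass
class ClusterAssignment:
    """Prophage id -> cluster id at one similarity threshold."""

    threshold_percent: float
    members: dict[str, str]  # prophage id -> cluster id

    def clusters(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for pid, cid in self.members.items():
            out.setdefault(cid, set()).add(pid)
        return out


@dataclass
class PhagotypeAssignment:
    """Strain -> set of prophage-cluster ids; identical sets share an id."""

    cluster_sets: dict[str, frozenset[str]]  # strain -> cluster ids
    phagotype_ids: dict[str, str]  # strain -> phagotype id


@dataclass
class ProtectionReport:
    relation: str
    within_plaquing: int
    within_total: int
    all_plaquing: int
    all_total: int
    permutation_p: float | None = None

    @property
    def within_fraction(self) -> float:
        return self.within_plaquing / self.within_total if self.within_total else 0.0

    @property
    def all_fraction(self) -> float:
        return self.all_plaquing / self.all_total if self.all_total else 0.0


# ---------------------------------------------------------------------------


def validate_similarity(matrix: pd.DataFrame) -> None:
    vals = matrix.to_numpy(dtype=float)
    if matrix.shape[0] != matrix.shape[1] or list(matrix.index) != list(matrix.columns):
        raise ValueError("similarity matrix must be square with matching labels")
    if not np.allclose(vals, vals.T, atol=1e-6):
        raise ValueError("similarity matrix must be symmetric")
    if vals.min() < 0 or vals.max() > 100 + 1e-6:
        raise ValueError("similarities must be on the [0, 100] percent scale")


def cluster_by_similarity(matrix: pd.DataFrame, threshold_percent: float) -> ClusterAssignment:
    """Single-linkage clusters: connected components of the >= threshold graph.

    Cluster ids are deterministic — the lexicographically smallest member
    label.  A threshold above 100 leaves every prophage a singleton.
    """
    validate_similarity(matrix)
    labels = list(matrix.index.astype(str))
    adj = csr_matrix(matrix.to_numpy(dtype=float) >= threshold_percent)
    _, comp = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for lab, c in zip(labels, comp):
        groups.setdefault(int(c), []).append(lab)
    members = {
        lab: min(group) for group in groups.values() for lab in group
    }
    return ClusterAssignment(threshold_percent=threshold_percent, members=members)


def assign_phagotypes(
    strain_sips: Mapping[str, Sequence[str]], clusters: ClusterAssignment
) -> PhagotypeAssignment:
    """Group strains by their set of prophage clusters.

    A strain with no prophages carries the empty set, itself a valid
    phagotype.  Raises if a prophage lacks a cluster assignment.
    """
    cluster_sets: dict[str, frozenset[str]] = {}
    for strain, sips in strain_sips.items():
        missing = [s for s in sips if s not in clusters.members]
        if missing:
            raise ValueError(f"prophages without cluster assignment: {missing}")
        cluster_sets[strain] = frozenset(clusters.members[s] for s in sips)
    # deterministic phagotype ids: sort set signatures, number them
    signatures = sorted({cs for cs in cluster_sets.values()}, key=lambda s: sorted(s))
    sig_id = {cs: f"PT{i + 1:02d}" for i, cs in enumerate(signatures)}
    phagotype_ids = {strain: sig_id[cs] for strain, cs in cluster_sets.items()}
    return PhagotypeAssignment(cluster_sets=cluster_sets, phagotype_ids=phagotype_ids)


def _relation_holds(donor: frozenset, recipient: frozenset, relation: str) -> bool:
    if relation == "equal":
        return donor == recipient
    if relation == "subset_either":
        return donor <= recipient or recipient <= donor
    if relation == "donor_subset_of_recipient":
        return donor <= recipient
    raise ValueError(f"unknown relation {relation!r}; use one of {RELATIONS}")


def protection_statistic(
    plaques: pd.DataFrame,
    phagotypes: PhagotypeAssignment,
    relation: str = "subset_either",
    include_empty: bool = True,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ProtectionReport:
    """Plaquing rate among same/nested-phagotype pairs vs all pairs.

    ``plaques`` is a boolean donor (rows) x recipient (columns) matrix;
    self-interactions (diagonal) are excluded throughout.  ``relation``
    selects which donor/recipient cluster-set relation counts as
    "within-group"; ``include_empty`` controls whether strains with no
    prophages participate in within-group pairs (the empty set is a subset
    of everything).  A seeded permutation test shuffles the assignment of
    cluster sets to strains and reports the fraction of shuffles with a
    within-group plaquing rate at most the observed one.
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}; use one of {RELATIONS}")
    strains = list(plaques.index.astype(str))
    if list(plaques.columns.astype(str)) != strains:
        raise ValueError("plaque matrix rows and columns must list the same strains")
    missing = [s for s in strains if s not in phagotypes.cluster_sets]
    if missing:
        raise ValueError(f"strains without phagotype assignment: {missing}")
    mat = plaques.to_numpy(dtype=bool)
    n = len(strains)
    off_diag = ~np.eye(n, dtype=bool)
    sets = [phagotypes.cluster_sets[s] for s in strains]

    def within_counts(assigned: list[frozenset]) -> tuple[int, int]:
        plaquing = total = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if not include_empty and (not assigned[i] or not assigned[j]):
                    continue
                if _relation_holds(assigned[i], assigned[j], relation):
                    total += 1
                    plaquing += int(mat[i, j])
        return plaquing, total

    w_plaq, w_tot = within_counts(sets)
    a_plaq, a_tot = int(mat[off_diag].sum()), int(off_diag.sum())

    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        obs = w_plaq / w_tot if w_tot else 0.0
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            pp, pt = within_counts([sets[k] for k in perm])
            stat = pp / pt if pt else 0.0
            if stat <= obs:
                hits += 1
        p_value = (1 + hits) / (1 + n_permutations)

    return ProtectionReport(
        relation=relation,
        within_plaquing=w_plaq,
        within_total=w_tot,
        all_plaquing=a_plaq,
        all_total=a_tot,
        permutation_p=p_value,
    )


def dereplicate_by_prophage_content(
    genome_sets: Mapping[str, Sequence[str]], distinguish_empty: bool = False
) -> dict[str, list[str]]:
    """Partition genomes by identical predicted-prophage cluster sets.

    Returns ``{representative: [members]}`` with the lexicographically
    smallest genome id as representative.  Genomes with empty sets share
    one group unless ``distinguish_empty`` keeps them as singletons (for
    workflows that retain every prophage-free isolate).
    """
    groups: dict[object, list[str]] = {}
    for gid in sorted(genome_sets):
        sig: object = frozenset(genome_sets[gid])
        if distinguish_empty and not sig:
            sig = ("empty", gid)
        groups.setdefault(sig, []).append(gid)
    return {min(members): sorted(members) for members in groups.values()}


def accessory_in_sip_fraction(
    genes: pd.DataFrame, sips: Sequence
) -> tuple[int, int, float]:
    """Accessory-gene attribution to active-prophage (SIP) regions.

    ``genes`` needs columns genome_id, start, end (0-based half-open) and
    category ("core"/"accessory").  A gene is inside a SIP if its midpoint
    falls within a SIP interval — robust to genes straddling att sites.
    Returns (accessory genes in SIPs, accessory genes total, fraction).
    """
    acc = genes[genes["category"] == "accessory"]
    total = len(acc)
    if total == 0:
        return 0, 0, 0.0
    in_sip = 0
    for _, row in acc.iterrows():
        mid = (int(row["start"]) + int(row["end"])) // 2
        if any(iv.genome_id == row["genome_id"] and iv.contains(mid) for iv in sips):
            in_sip += 1
    return in_sip, total, in_sip / total
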