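"""Gene-set overlap testing, metagene networks and clustering similarity.

Two metagenes that share many member genes likely track the same pathway.
Significance of an overlap of size n between sets of sizes Na and Nb drawn
from a universe of N genes is the upper tail of the hypergeometric
distribution, P(X >= n).  Pairwise tests (BH-adjusted) plus a minimum-overlap
rule build an undirected metagene network; the same machinery tests a
metagene against a functional gene-set collection (GO, mSigDB-style GMT).

Cluster similarity between two views of the same entities (e.g. metagene
score patterns versus the underlying RPPA protein patterns) is measured by
the plain Rand index of the partitions obtained by complete-linkage
hierarchical clustering (Euclidean distance) of each view's correlation
matrix, cut into k classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import rand_score

from .derivation import Metagene, bh_adjust
from .exceptions import DataError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

#: Minimum common genes for a network edge.
MIN_OVERLAP = 5

#: FDR threshold for significant intersections.
FDR_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# Hypergeometric overlap test
# ---------------------------------------------------------------------------

def hypergeom_upper_p(Na: int, Nb: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= n) for an overlap of n between sets of Na and
    Nb genes drawn from a universe of N genes.

    Evaluated through the hypergeometric survival function (log-space
    internally), so tiny tail probabilities do not underflow to careless
    zeros for moderate set sizes.
    """
    Na, Nb, n, N = int(Na), int(Nb), int(n), int(N)
    if min(Na, Nb, n, N) < 0:
        raise ValueError("counts must be non-negative")
    if n > min(Na, Nb) or max(Na, Nb) > N:
        raise ValueError(
            f"inconsistent counts: n={n}, Na={Na}, Nb={Nb}, N={N}"
        )
    if n == 0:
        return 1.0
    return float(stats.hypergeom.sf(n - 1, N, Na, Nb))


@dataclass
class OverlapTest:
    """One tested intersection between two gene sets."""

    set_a_name: str
    set_b_name: str
    Na: int
    Nb: int
    n_overlap: int
    N_universe: int
    p: float
    q: float = float("nan")


# ---------------------------------------------------------------------------
# Metagene intersection network
# ---------------------------------------------------------------------------

@dataclass
class MetageneNetwork:
    """Undirected network linking significantly intersecting metagenes.

    Every node is a metagene; an edge requires at least ``min_overlap``
    common genes and BH-adjusted hypergeometric q <= ``fdr_threshold``.
    """

    graph: nx.Graph
    tests: list[OverlapTest] = field(default_factory=list)
    min_overlap: int = MIN_OVERLAP
    fdr_threshold: float = FDR_THRESHOLD

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, int, float]]:
        return sorted(
            (min(a, b), max(a, b), d["n_overlap"], d["q"])
            for a, b, d in self.graph.edges(data=True)
        )

    def components(self) -> list[set[str]]:
        """Connected components, largest first."""
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))

    def cluster(self, method: str = "components", seed: int = 0) -> dict[str, int]:
        """Optional node grouping: connected components (default) or an
        asynchronous label-propagation pass."""
        if method == "components":
            groups: Iterable[set[str]] = self.components()
        elif method == "label-propagation":
            groups = nx.algorithms.community.asyn_lpa_communities(
                self.graph, seed=seed
            )
        else:
            raise ValueError(f"unknown clustering method {method!r}")
        labels: dict[str, int] = {}
        for i, grp in enumerate(groups, start=1):
            for node in grp:
                labels[node] = i
        return labels

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def to_sif(self, path: str | Path, relation: str = "intersects") -> None:
        with open(path, "w") as fh:
            for a, b, *_ in self.edges:
                fh.write(f"{a}\t{relation}\t{b}\n")
            for node in self.nodes:
                if self.graph.degree(node) == 0:
                    fh.write(f"{node}\n")

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set_a": t.set_a_name, "set_b": t.set_b_name,
                    "Na": t.Na, "Nb": t.Nb, "n_overlap": t.n_overlap,
                    "N_universe": t.N_universe, "p": t.p, "q": t.q,
                }
                for t in self.tests
            ]
        )


def build_network(
    metagenes: Sequence[Metagene],
    universe: Sequence[str],
    min_overlap: int = MIN_OVERLAP,
    fdr_threshold: float = FDR_THRESHOLD,
) -> MetageneNetwork:
    """Test all unordered metagene pairs for significant intersection.

    Overlap counts the union of up- and down-members (coefficient signs are
    ignored).  BH runs across all pairs; edges require both the adjusted q
    and the minimum-overlap rule.  The edge set does not depend on the order
    metagenes are supplied in.
    """
    universe_set = {str(g) for g in universe}
    if not universe_set:
        raise DataError("empty gene universe")
    N = len(universe_set)
    by_name = {mg.name: set(mg.genes) for mg in sorted(metagenes, key=lambda m: m.name)}
    if len(by_name) != len(metagenes):
        raise DataError("duplicate metagene names")
    for name, genes in by_name.items():
        extra = genes - universe_set
        if extra:
            raise DataError(
                f"metagene {name!r} has members outside the universe: "
                f"{sorted(extra)[:5]}"
            )
    tests: list[OverlapTest] = []
    for a, b in itertools.combinations(sorted(by_name), 2):
        ga, gb = by_name[a], by_name[b]
        n = len(ga & gb)
        tests.append(
            OverlapTest(a, b, len(ga), len(gb), n, N,
                        hypergeom_upper_p(len(ga), len(gb), n, N))
        )
    if tests:
        for t, q in zip(tests, bh_adjust([t.p for t in tests])):
            t.q = float(q)
    graph = nx.Graph()
    graph.add_nodes_from(by_name)
    for t in tests:
        if t.n_overlap >= min_overlap and t.q <= fdr_threshold:
            graph.add_edge(t.set_a_name, t.set_b_name,
                           n_overlap=t.n_overlap, p=t.p, q=t.q)
    return MetageneNetwork(graph=graph, tests=tests,
                           min_overlap=min_overlap, fdr_threshold=fdr_threshold)


def enrich(
    metagene: Metagene,
    collection: GeneSetCollection,
    universe: Sequence[str],
    fdr_threshold: float = FDR_THRESHOLD,
) -> list[OverlapTest]:
    """Functional enrichment of one metagene against a gene-set collection.

    Each class is intersected with the universe before testing; BH runs
    across the classes of the collection.  Results are sorted by p.
    """
    universe_set = {str(g) for g in universe}
    if not universe_set:
        raise DataError("empty gene universe")
    genes = set(metagene.genes)
    extra = genes - universe_set
    if extra:
        raise DataError(
            f"metagene {metagene.name!r} has members outside the universe: "
            f"{sorted(extra)[:5]}"
        )
    N = len(universe_set)
    tests: list[OverlapTest] = []
    for name, class_genes in collection:
        cls = set(class_genes) & universe_set
        if not cls:
            continue
        n = len(genes & cls)
        tests.append(
            OverlapTest(metagene.name, name, len(genes), len(cls), n, N,
                        hypergeom_upper_p(len(genes), len(cls), n, N))
        )
    if tests:
        for t, q in zip(tests, bh_adjust([t.p for t in tests])):
            t.q = float(q)
    return sorted(tests, key=lambda t: (t.p, t.set_b_name))


def enrichment_report(tests: Sequence[OverlapTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metagene": t.set_a_name, "class": t.set_b_name,
                "Na": t.Na, "Nb": t.Nb, "n_overlap": t.n_overlap,
                "N_universe": t.N_universe, "p": t.p, "q": t.q,
            }
            for t in tests
        ]
    )


# ---------------------------------------------------------------------------
# Partitions and cluster similarity
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """A hard clustering of named items into classes labelled 1..k."""

    item_ids: list[str]
    labels: np.ndarray
    label_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.item_ids = [str(i) for i in self.item_ids]
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.item_ids) != len(self.labels):
            raise DataError("item_ids and labels length mismatch")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise DataError("duplicate item ids in partition")
        # relabel to contiguous 1..k in order of first appearance
        seen: dict[int, int] = {}
        names = {}
        new = np.empty_like(self.labels)
        for i, lab in enumerate(self.labels):
            if lab not in seen:
                seen[lab] = len(seen) + 1
                if self.label_names and lab in self.label_names:
                    names[seen[lab]] = self.label_names[lab]
            new[i] = seen[lab]
        self.labels = new
        self.label_names = names or None

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def label_of(self, item: str) -> int:
        return int(self.labels[self.item_ids.index(item)])

    def to_series(self) -> pd.Series:
        if self.label_names:
            values = [self.label_names.get(int(l), str(l)) for l in self.labels]
        else:
            values = self.labels
        return pd.Series(values, index=self.item_ids, name="class")


def rand_index(a: Partition, b: Partition) -> float:
    """Plain (unadjusted) Rand index: fraction of item pairs on which the two
    partitions agree (together in both, or apart in both)."""
    if set(a.item_ids) != set(b.item_ids):
        raise DataError("partitions cover different item sets")
    order = a.item_ids
    b_labels = np.array([b.label_of(i) for i in order])
    return float(rand_score(a.labels, b_labels))


def correlation_partition(
    profiles: pd.DataFrame,
    k: int = 3,
) -> Partition:
    """Partition entities by hierarchical clustering of their correlation matrix.

    The Pearson correlation matrix of the rows of ``profiles`` (entities x
    features) is computed; complete-linkage hierarchical clustering with
    Euclidean distance is applied to its rows, and the tree is cut into
    exactly k classes.  Zero-variance entities cannot be correlated and are
    excluded with a warning.
    """
    if not isinstance(profiles, pd.DataFrame):
        profiles = pd.DataFrame(profiles)
    variances = profiles.var(axis=1, ddof=0)
    flat = variances[variances == 0]
    if len(flat):
        logger.warning(
            "excluding %d zero-variance entit(ies) from clustering: %s",
            len(flat), ", ".join(map(str, flat.index[:5])),
        )
        profiles = profiles.drop(index=flat.index)
    n = len(profiles)
    if n < k:
        raise DataError(f"need >= k={k} entities with variance, have {n}")
    corr = np.corrcoef(profiles.to_numpy())
    if n == k:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(corr, method="complete", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    return Partition(item_ids=list(profiles.index.astype(str)), labels=labels)
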