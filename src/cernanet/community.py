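"""Module detection (Louvain), modularity and the module report.

Only Louvain is implemented; MCL, MCODE and EPCA are registered names behind
the same interface that raise ``NotImplementedError``.  Isolated nodes are
never assigned to a module.  Modularity is the Newman-Girvan partition score
Q = sum_c [ e_c/m - (d_c/2m)^2 ].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SUPPORTED_ALGORITHMS = ("louvain",)
REGISTERED_ALGORITHMS = ("louvain", "mcl", "mcode", "epca")


@dataclass(frozen=True)
class ModulePartition:
    """Connected-node -> module-id assignment plus provenance."""

    module_of: dict[str, int]
    algorithm: str
    parameters: dict = field(default_factory=dict)

    @property
    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, mod in self.module_of.items():
            out.setdefault(mod, []).append(node)
        return {k: sorted(v) for k, v in sorted(out.items())}

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of.values()))


def detect_modules(
    network: nx.Graph,
    algorithm: str = "louvain",
    resolution: float = 1.0,
    seed: int = 0,
) -> ModulePartition:
    """Partition the connected part of the network into modules.

    Louvain runs on the unweighted graph with node order canonicalized
    (sorted symbols) and a fixed RNG seed, so the partition is reproducible.
    """
    if algorithm not in REGISTERED_ALGORITHMS:
        raise ValueError(
            f"unsupported algorithm {algorithm!r}; registered: "
            f"{', '.join(REGISTERED_ALGORITHMS)}"
        )
    if algorithm != "louvain":
        raise NotImplementedError(
            f"{algorithm!r} is registered but not implemented; use 'louvain'"
        )
    if network.number_of_nodes() == 0:
        raise ValueError("cannot detect modules on an empty network")
    connected = [n for n, d in sorted(network.degree()) if d > 0]
    canon = nx.Graph()
    canon.add_nodes_from(sorted(connected))
    canon.add_edges_from(
        sorted(tuple(sorted(e)) for e in network.subgraph(connected).edges)
    )
    if canon.number_of_nodes() == 0:
        return ModulePartition({}, algorithm, {"resolution": resolution, "seed": seed})
    communities = nx.community.louvain_communities(
        canon, weight=None, resolution=resolution, seed=seed
    )
    # canonical module ids: sorted by (size desc, smallest member)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    module_of = {node: i for i, comm in enumerate(ordered) for node in comm}
    return ModulePartition(
        module_of, algorithm, {"resolution": resolution, "seed": seed}
    )


def modularity(network: nx.Graph, partition: ModulePartition) -> float:
    """Newman-Girvan modularity of a partition of the connected nodes."""
    m = network.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for nodes in partition.modules.values():
        node_set = set(nodes)
        e_c = sum(
            1 for u, v in network.edges(nodes) if u in node_set and v in node_set
        )
        d_c = sum(network.degree(n) for n in nodes)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


@dataclass(frozen=True)
class ModuleReport:
    """Per-module statistics plus global summary and distributions."""

    per_module: pd.DataFrame  # module, size, n_edges, density, mirnas
    n_modules: int
    modularity: float
    average_density: float

    def to_dict(self) -> dict:
        return {
            "n_modules": self.n_modules,
            "modularity": self.modularity,
            "average_density": self.average_density,
            "modules": self.per_module.to_dict(orient="records"),
        }


def module_report(network: nx.Graph, partition: ModulePartition) -> ModuleReport:
    """Size, internal edge count, density and associated miRNAs per module.

    density(c) = e_c / C(size_c, 2), 0 for singletons; associated miRNAs are
    the union of the shared-miRNA sets over the module's internal edges.
    Average density is the unweighted mean over modules.
    """
    rows = []
    for mod, nodes in partition.modules.items():
        node_set = set(nodes)
        internal = [
            (u, v, d)
            for u, v, d in network.edges(nodes, data=True)
            if u in node_set and v in node_set
        ]
        size = len(nodes)
        n_edges = len(internal)
        density = n_edges / (size * (size - 1) / 2) if size > 1 else 0.0
        mirnas: set[str] = set()
        for _, _, d in internal:
            sm = d.get("shared_mirnas", "")
            if isinstance(sm, str):
                mirnas.update(s for s in sm.split(";") if s)
            else:
                mirnas.update(sm)
        rows.append(
            {
                "module": mod,
                "size": size,
                "n_edges": n_edges,
                "density": density,
                "mirnas": ";".join(sorted(mirnas)),
            }
        )
    per_module = pd.DataFrame(
        rows, columns=["module", "size", "n_edges", "density", "mirnas"]
    )
    avg_density = float(per_module["density"].mean()) if rows else 0.0
    return ModuleReport(
        per_module=per_module,
        n_modules=len(rows),
        modularity=modularity(network, partition),
        average_density=avg_density,
    )


def parameter_scan(
    network: nx.Graph,
    algorithm: str = "louvain",
    resolutions=(0.5, 1.0, 2.0),
    seeds=(0,),
) -> pd.DataFrame:
    """One module-report summary row per (resolution, seed) grid point."""
    rows = []
    for res in resolutions:
        for seed in seeds:
            part = detect_modules(network, algorithm, resolution=res, seed=seed)
            rep = module_report(network, part)
            rows.append(
                {
                    "algorithm": algorithm,
                    "resolution": res,
                    "seed": seed,
                    "n_modules": rep.n_modules,
                    "modularity": rep.modularity,
                    "average_density": rep.average_density,
                    "max_module_size": int(rep.per_module["size"].max())
                    if rep.n_modules
                    else 0,
                }
            )
    return pd.DataFrame(rows)
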