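"""Seeded synthetic fixtures: toy ontologies, annotations, networks, ECs.

Emulates the structure the real inputs provide — a rooted layered term
DAG, genes annotated clade-wise to leaf terms, a planted-partition
co-functional network whose modules can be aligned with the annotation
clades, and EC groups equal to (or shuffled against) those modules — so
the whole pipeline is testable offline. Everything is driven by a single
seeded generator; the same spec and seed reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .evaluation import ECGroups
from .network import CoFunctionalNetwork
from .ontology import AnnotationMap, OntologyDAG

ASPECT_CODE = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark instance.

    ``aligned=True`` plants the signal the benchmark is meant to detect:
    network modules, annotation clades and EC groups coincide, so genes
    sharing an EC sit close both in the DAG and in the network. With
    ``aligned=False`` the EC grouping is shuffled against everything else
    and the benchmark statistic should hover around zero.
    """

    seed: int = 0
    n_terms: int = 15
    depth: int = 3  # layers below the root
    branching: int = 2  # growth factor of successive layers
    n_genes: int = 30
    n_modules: int = 3  # planted functional groups
    p_intra: float = 0.6  # edge probability within a module
    p_inter: float = 0.05  # edge probability between modules
    weight_range: tuple[float, float] = (0.5, 1.5)
    terms_per_gene: int = 2  # annotation specificity: leaf terms per gene
    aligned: bool = True
    namespace: str = "molecular_function"

    def __post_init__(self) -> None:
        if self.n_modules > self.n_genes:
            raise ValueError("more modules than genes")
        if self.n_genes // self.n_modules < 2:
            raise ValueError("modules must hold at least 2 genes each")
        if self.n_terms < self.depth + 1:
            raise ValueError("n_terms too small for the requested depth")
        if self.aligned and self.p_intra < self.p_inter:
            raise ValueError("aligned fixtures need p_intra >= p_inter")
        if not (0 <= self.p_inter <= 1 and 0 <= self.p_intra <= 1):
            raise ValueError("edge probabilities must be in [0, 1]")
        if self.weight_range[0] <= 0 or self.weight_range[1] < self.weight_range[0]:
            raise ValueError("weight_range must be positive and ordered")


@dataclass
class Fixture:
    spec: FixtureSpec
    dag: OntologyDAG
    annotations: AnnotationMap
    network: CoFunctionalNetwork
    ec_groups: ECGroups
    modules: dict[str, int]  # gene -> planted module


def _term_id(k: int) -> str:
    return f"GO:{k + 1:07d}"


def _layer_sizes(spec: FixtureSpec) -> list[int]:
    """Sizes of the layers below the root, totalling n_terms - 1."""
    remaining = spec.n_terms - 1
    sizes: list[int] = []
    prev = 1
    for level in range(spec.depth):
        levels_left = spec.depth - level - 1
        target = min(prev * spec.branching, remaining - levels_left)
        if level == spec.depth - 1:
            target = remaining
        sizes.append(target)
        remaining -= target
        prev = target
    return sizes


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the four pipeline inputs with planted modular structure."""
    rng = np.random.default_rng(spec.seed)

    # layered DAG, all is_a, 1-2 parents from the previous layer
    sizes = _layer_sizes(spec)
    edges: list[tuple[str, str, str]] = []
    prev_layer = [_term_id(0)]
    next_id = 1
    layers = [prev_layer]
    for size in sizes:
        layer = [_term_id(next_id + i) for i in range(size)]
        next_id += size
        for k, term in enumerate(layer):
            # spread first parents round-robin so every parent keeps children
            first = prev_layer[k % len(prev_layer)]
            parents = {first}
            if len(prev_layer) > 1 and rng.random() < 0.3:
                parents.add(prev_layer[int(rng.integers(len(prev_layer)))])
            for p in sorted(parents):
                edges.append((term, p, "is_a"))
        layers.append(layer)
        prev_layer = layer
    all_terms = [_term_id(i) for i in range(spec.n_terms)]
    dag = OntologyDAG.from_edges(all_terms, edges, spec.namespace)

    leaves = layers[-1]
    if len(leaves) < spec.n_modules:
        raise ValueError(
            f"only {len(leaves)} leaf terms for {spec.n_modules} modules; "
            "increase n_terms or branching"
        )

    # genes partitioned into contiguous network modules; annotations are
    # clade-wise (one leaf block per gene). Aligned fixtures use the same
    # partition for both; misaligned ones draw an independent permutation,
    # so annotation clades, network modules and EC groups are decoupled.
    genes = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    modules = {g: i * spec.n_modules // spec.n_genes for i, g in enumerate(genes)}
    if spec.aligned:
        ann_module = modules
    else:
        perm = rng.permutation(spec.n_genes)
        ann_module = {
            genes[int(perm[i])]: modules[genes[i]] for i in range(spec.n_genes)
        }
    leaf_blocks = [
        leaves[m * len(leaves) // spec.n_modules : (m + 1) * len(leaves) // spec.n_modules]
        for m in range(spec.n_modules)
    ]
    direct: dict[str, set[str]] = {}
    for g in genes:
        block = leaf_blocks[ann_module[g]]
        k = min(spec.terms_per_gene, len(block))
        pick = rng.choice(len(block), size=k, replace=False)
        direct[g] = {block[i] for i in pick}
    annotations = AnnotationMap.from_direct(dag, direct)

    # planted-partition network
    lo, hi = spec.weight_range
    net_edges: list[tuple[str, str, float]] = []
    degree = {g: 0 for g in genes}
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            same = modules[genes[i]] == modules[genes[j]]
            p = spec.p_intra if same else spec.p_inter
            if rng.random() < p:
                w = float(rng.uniform(lo, hi))
                net_edges.append((genes[i], genes[j], w))
                degree[genes[i]] += 1
                degree[genes[j]] += 1
    # keep every gene in the walk: tether isolated genes inside their module
    for g in genes:
        if degree[g] == 0:
            mates = [m for m in genes if m != g and modules[m] == modules[g]]
            mate = mates[int(rng.integers(len(mates)))]
            net_edges.append((g, mate, float(rng.uniform(lo, hi))))
            degree[g] += 1
            degree[mate] += 1
    network = CoFunctionalNetwork.from_edges(net_edges)

    # EC groups: the planted modules, or a shuffled relabelling
    if spec.aligned:
        ec_assign = modules
    else:
        perm = rng.permutation(spec.n_genes)
        ec_assign = {genes[int(perm[i])]: modules[genes[i]] for i in range(spec.n_genes)}
    group_sets: dict[str, set[str]] = {}
    for g, m in ec_assign.items():
        ec = f"1.1.{m // 100 + 1}.{m % 100 + 1}"
        group_sets.setdefault(ec, set()).add(g)
    ec_groups = ECGroups(groups={e: frozenset(s) for e, s in group_sets.items()})

    return Fixture(
        spec=spec,
        dag=dag,
        annotations=annotations,
        network=network,
        ec_groups=ec_groups,
        modules=modules,
    )


# -- on-disk formats ---------------------------------------------------


def write_obo(fixture: Fixture, path) -> None:
    dag = fixture.dag
    with open(path, "w") as out:
        out.write("format-version: 1.2\n")
        out.write(f"ontology: synthetic-{fixture.spec.seed}\n")
        for term in sorted(dag.terms):
            out.write("\n[Term]\n")
            out.write(f"id: {term}\n")
            out.write(f"name: synthetic term {term[3:].lstrip('0') or '0'}\n")
            out.write(f"namespace: {dag.namespace}\n")
            for parent in sorted(dag.parents(term)):
                rel = dag.graph[term][parent]["relation"]
                if rel == "is_a":
                    out.write(f"is_a: {parent}\n")
                else:
                    out.write(f"relationship: part_of {parent}\n")


def write_gaf(fixture: Fixture, path) -> None:
    aspect = ASPECT_CODE[fixture.dag.namespace]
    with open(path, "w") as out:
        out.write("!gaf-version: 2.2\n")
        for gene in sorted(fixture.annotations.direct):
            for term in sorted(fixture.annotations.direct[gene]):
                fields = [
                    "SYNTH", gene, gene, "enables", term, "SYNTH:0000001",
                    "IEA", "", aspect, "", "", "gene", "taxon:0", "20160101",
                    "SYNTH", "", "",
                ]
                out.write("\t".join(fields) + "\n")


def write_network_tsv(fixture: Fixture, path) -> None:
    net = fixture.network
    w = net.weights.tocoo()
    rows = sorted(
        (net.genes[i], net.genes[j], float(v))
        for i, j, v in zip(w.row, w.col, w.data)
        if i < j
    )
    with open(path, "w") as out:
        out.write("# synthetic co-functional network\n")
        for a, b, v in rows:
            out.write(f"{a}\t{b}\t{v:.6f}\n")


def write_ec_tsv(fixture: Fixture, path) -> None:
    with open(path, "w") as out:
        for ec in fixture.ec_groups.ecs:
            for gene in sorted(fixture.ec_groups[ec]):
                out.write(f"{gene}\t{ec}\n")


def write_fixture(fixture: Fixture, out_dir) -> dict[str, Path]:
    """Write all four artifacts plus the resolved spec for provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": out_dir / "fixture.obo",
        "gaf": out_dir / "fixture.gaf",
        "network": out_dir / "network.tsv",
        "ec": out_dir / "ec.tsv",
        "spec": out_dir / "spec.yaml",
    }
    write_obo(fixture, paths["obo"])
    write_gaf(fixture, paths["gaf"])
    write_network_tsv(fixture, paths["network"])
    write_ec_tsv(fixture, paths["ec"])
    resolved = dataclasses.asdict(fixture.spec)
    resolved["weight_range"] = list(resolved["weight_range"])
    with open(paths["spec"], "w") as out:
        yaml.safe_dump(resolved, out, sort_keys=True)
    return paths
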