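"""Consensus map construction by weighted DAG union.

Each individual map's chromosome is a directed path of markers in map order;
the consensus graph is the union of those paths over shared vertices, every
input map carrying equal weight (1.0).  Ordering conflicts between maps show
up as cycles; they are resolved by deleting, inside each strongly connected
component, the adjacency supported by the fewest maps (ties: larger
distance, then lexicographic), so that every marker stays mapped.  The
acyclic graph is then linearised: consensus order is a topological sort with
ties broken by mean anchored source position, and the consensus position of
a marker is the mean of its per-map positions after each map is shifted onto
a common frame, projected to monotonicity along the consensus order by
pool-adjacent-violators (isotonic regression).  Finally positions are
rescaled by the mean, over source maps, of the OLS slope of consensus on
source positions, correcting the distance inflation that map merging
produces.

Markers landing at identical consensus positions form the consensus
recombinant bins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from ._util import parse_chromosome, round_half_up
from .map_builder import LinkageMap

POSITION_DECIMALS = 6  # positions equal after rounding here share a bin


@dataclass
class MapDAG:
    graph: nx.DiGraph
    chromosome: str
    source_names: list[str]
    paths: dict = field(default_factory=dict)  # path name -> oriented DataFrame

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class ConsensusMap:
    """Merged map: one table over all chromosomes plus merge diagnostics."""

    table: pd.DataFrame  # marker, chromosome, position_cM, bin_id, n_source_maps, sources, assay
    conflict_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    slopes: dict = field(default_factory=dict)

    def chromosome_table(self, chromosome: str) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == chromosome]
        return sub.sort_values(["position_cM", "marker"]).reset_index(drop=True)

    def chromosomes(self) -> list[str]:
        return sorted(self.table["chromosome"].unique())

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["sources"] = out["sources"].map(lambda s: ",".join(s))
        out.to_csv(path, sep="\t", index=False)

    def summary(self) -> pd.DataFrame:
        per_chrom = (
            self.table.groupby("chromosome")
            .agg(markers=("marker", "size"), bins=("bin_id", "nunique"),
                 length_cM=("position_cM", "max"))
            .reset_index()
        )
        return summarize_chromosome_table(per_chrom)


def _chromosome_paths(maps: list[LinkageMap], chromosome: str) -> dict[str, pd.DataFrame]:
    """Ordered marker/position paths for one chromosome, one per linkage
    group of each input map (split chromosomes contribute several paths)."""
    out = {}
    for lm in maps:
        if hasattr(lm, "chromosome_paths"):
            for name, df in lm.chromosome_paths(chromosome):
                out[name] = df
        else:  # bare table fallback
            sub = lm.chromosome_table(chromosome)
            if len(sub):
                out[getattr(lm, "name", "map")] = sub[["marker", "position_cM"]].reset_index(drop=True)
    return {k: v for k, v in out.items() if len(v)}


def _orient_paths(paths: dict[str, pd.DataFrame], chromosome: str
                  ) -> dict[str, pd.DataFrame]:
    """Co-orient paths: group orientation within one map is arbitrary, so
    each path is flipped when its shared markers run counter to the paths
    already accepted (sign of the position covariance over shared markers).
    Paths are taken in an order that always bridges through shared markers.
    """
    names = list(paths)
    placed: dict[str, float] = {}
    oriented: dict[str, pd.DataFrame] = {}
    pending = list(names)
    while pending:
        if not oriented:
            pick = pending[0]
        else:
            pick = next((n for n in pending
                         if set(paths[n]["marker"]) & placed.keys()), None)
            if pick is None:
                warnings.warn(
                    f"some maps share no marker on {chromosome}; merged without orientation")
                pick = pending[0]
        pending.remove(pick)
        df = paths[pick]
        shared = df[df["marker"].isin(placed)]
        if len(shared) >= 2:
            ref = np.array([placed[m] for m in shared["marker"]])
            own = shared["position_cM"].to_numpy(dtype=float)
            if np.cov(ref, own, bias=True)[0, 1] < 0:
                top = df["position_cM"].max()
                df = df.iloc[::-1].assign(position_cM=lambda d: top - d["position_cM"])
                df = df.reset_index(drop=True)
        oriented[pick] = df
        for m, p in zip(df["marker"], df["position_cM"]):
            placed.setdefault(m, float(p))
    return {n: oriented[n] for n in names}


def maps_to_dag(maps: list[LinkageMap], chromosome: str,
                weight: float = 1.0) -> MapDAG:
    """Union of per-map adjacency paths over shared vertices.

    Every linkage group of every input map contributes one directed path of
    equal weight; markers at identical positions within one path are chained
    in name order (zero-length edges).  A path sharing no marker with the
    union of the others is excluded with a warning.
    """
    paths = _chromosome_paths(maps, chromosome)
    if not paths:
        raise ValueError(f"no input map covers chromosome {chromosome}")
    if len(paths) > 1:
        # keep the largest cluster of paths connected by shared markers
        share = nx.Graph()
        share.add_nodes_from(paths)
        names = list(paths)
        sets = {n: set(paths[n]["marker"]) for n in names}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if sets[a] & sets[b]:
                    share.add_edge(a, b)
        components = sorted(nx.connected_components(share),
                            key=lambda c: (-sum(len(sets[n]) for n in c), min(c)))
        keep = components[0]
        for name in names:
            if name not in keep:
                warnings.warn(f"map {name} shares no marker on {chromosome}; excluded")
        paths = {n: paths[n] for n in names if n in keep}
    paths = _orient_paths(paths, chromosome)
    g = nx.DiGraph()
    for name, df in paths.items():
        markers = df["marker"].tolist()
        pos = df["position_cM"].to_numpy(dtype=float)
        for m, p in zip(markers, pos):
            if m not in g:
                g.add_node(m, positions={})
            g.nodes[m]["positions"][name] = float(p)
        for (a, pa), (b, pb) in zip(zip(markers[:-1], pos[:-1]), zip(markers[1:], pos[1:])):
            dist = float(pb - pa)
            if g.has_edge(a, b):
                g[a][b]["support"] += weight
                g[a][b]["distances"].append(dist)
            else:
                g.add_edge(a, b, support=weight, distances=[dist])
    for _a, _b, data in g.edges(data=True):
        data["distance"] = float(np.mean(data["distances"]))
    return MapDAG(g, chromosome, list(paths), paths=dict(paths))


def resolve_conflicts(dag: MapDAG) -> tuple[MapDAG, pd.DataFrame]:
    """Delete minimal-support edges inside SCCs until the graph is acyclic."""
    g = dag.graph.copy()
    log = []
    while True:
        sccs = [c for c in nx.strongly_connected_components(g) if len(c) > 1]
        if not sccs:
            break
        for comp in sccs:
            edges = [(a, b, d) for a, b, d in g.edges(comp, data=True) if b in comp]
            a, b, d = min(edges, key=lambda e: (e[2]["support"], -e[2]["distance"], e[0], e[1]))
            g.remove_edge(a, b)
            log.append((dag.chromosome, a, b, d["support"], d["distance"]))
            break  # recompute SCCs after each deletion
    log_df = pd.DataFrame(log, columns=["chromosome", "from", "to", "support", "distance"])
    return MapDAG(g, dag.chromosome, list(dag.source_names), paths=dict(dag.paths)), log_df


def _anchored_positions(dag: MapDAG) -> dict[str, dict[str, float]]:
    """Shift each source path so shared markers align on a common frame.

    The first path is the reference; every further path is taken once it
    shares a marker with the already-anchored set (bridging through shared
    vertices) and shifted so that its first shared marker (in its own order)
    matches that marker's current mean anchored position.  Paths sharing no
    marker keep shift 0 (disconnected components, warned on elsewhere).
    """
    per_path: dict[str, dict[str, float]] = {
        name: dict(zip(df["marker"], df["position_cM"].astype(float)))
        for name, df in dag.paths.items()
    }
    anchored: dict[str, dict[str, float]] = {}
    placed: dict[str, list[float]] = {}
    pending = [n for n in dag.source_names if per_path.get(n)]
    while pending:
        if not anchored:
            name = pending[0]
        else:
            name = next((n for n in pending if set(per_path[n]) & placed.keys()),
                        pending[0])
        pending.remove(name)
        positions = per_path[name]
        shift = 0.0
        shared = [(p, m) for m, p in positions.items() if m in placed]
        if shared:
            p0, m0 = min(shared)
            shift = float(np.mean(placed[m0])) - p0
        anchored[name] = {m: p + shift for m, p in positions.items()}
        for m, p in anchored[name].items():
            placed.setdefault(m, []).append(p)
    return anchored


def linearize(dag: MapDAG) -> pd.DataFrame:
    """Topological order + mean anchored position + isotonic projection.

    Returns a per-marker table (marker, position_cM, n_source_maps, sources)
    in consensus order with monotone positions starting at 0.  A
    disconnected DAG is handled by the anchor-order tie-break with a
    warning (components are interleaved by mean anchored position).
    """
    g = dag.graph
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["marker", "position_cM", "n_source_maps", "sources"])
    anchored = _anchored_positions(dag)
    mean_pos = {}
    sources = {}
    for node in g.nodes:
        ps = [anchored[name][node] for name in anchored if node in anchored[name]]
        mean_pos[node] = float(np.mean(ps))
        sources[node] = sorted(name for name in anchored if node in anchored[name])
    if nx.number_weakly_connected_components(g) > 1:
        warnings.warn(f"consensus DAG for {dag.chromosome} is disconnected; "
                      "components ordered by anchored positions")
    order = list(nx.lexicographical_topological_sort(
        g, key=lambda n: (mean_pos[n], n)))
    raw = np.array([mean_pos[n] for n in order])
    weights = np.array([len(sources[n]) for n in order], dtype=float)
    iso = isotonic_regression(raw, weights=weights, increasing=True)
    pos = np.asarray(iso.x, dtype=float)
    pos = pos - pos[0]
    return pd.DataFrame({
        "marker": order,
        "position_cM": np.round(pos, 12),
        "n_source_maps": [len(sources[n]) for n in order],
        "sources": [sources[n] for n in order],
    })


def rescale(linear: pd.DataFrame, dag: MapDAG) -> tuple[pd.DataFrame, dict[str, float]]:
    """Divide consensus positions by the mean per-map OLS slope.

    For each source map the slope of consensus positions regressed on that
    map's own positions is computed over shared markers; degenerate maps
    (fewer than 2 shared markers or zero position variance) are skipped with
    a warning.
    """
    cons_pos = dict(zip(linear["marker"], linear["position_cM"]))
    slopes: dict[str, float] = {}
    for name in dag.source_names:
        xs, ys = [], []
        for node, data in dag.graph.nodes(data=True):
            if name in data["positions"] and node in cons_pos:
                xs.append(data["positions"][name])
                ys.append(cons_pos[node])
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float)
        if len(x) < 2 or np.allclose(x.var(), 0.0):
            warnings.warn(f"map {name}: degenerate regression on {dag.chromosome}; skipped")
            continue
        slopes[name] = float(np.cov(x, y, bias=True)[0, 1] / x.var())
    out = linear.copy()
    if slopes:
        mean_slope = float(np.mean(list(slopes.values())))
        if mean_slope > 0:
            out["position_cM"] = out["position_cM"] / mean_slope
    return out, slopes


def _assign_bins(table: pd.DataFrame, chromosome: str) -> pd.Series:
    rounded = table["position_cM"].round(POSITION_DECIMALS)
    codes = rounded.rank(method="dense").astype(int)
    return codes.map(lambda c: f"{chromosome}_bin{c:04d}")


def build_consensus(maps: list[LinkageMap],
                    assays: dict[str, str] | None = None) -> ConsensusMap:
    """Merge chromosome-assigned maps into one consensus map.

    ``assays`` optionally maps marker -> assay id (multi-locus assays);
    markers absent from it keep their own name as assay id.  Chromosomes
    present in no input map are simply absent from the output.
    """
    chroms = sorted({c for lm in maps for c in lm.table["chromosome"].dropna().unique()})
    tables, logs, slope_log = [], [], {}
    for chrom in chroms:
        dag = maps_to_dag(maps, chrom)
        dag, log = resolve_conflicts(dag)
        linear = linearize(dag)
        linear, slopes = rescale(linear, dag)
        linear["chromosome"] = chrom
        linear["bin_id"] = _assign_bins(linear, chrom)
        tables.append(linear)
        if len(log):
            logs.append(log)
        slope_log[chrom] = slopes
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["marker", "position_cM", "n_source_maps", "sources", "chromosome", "bin_id"])
    table["assay"] = table["marker"].map(lambda m: (assays or {}).get(m, m))
    cols = ["marker", "chromosome", "position_cM", "bin_id", "n_source_maps", "sources", "assay"]
    conflict = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame(
        columns=["chromosome", "from", "to", "support", "distance"])
    return ConsensusMap(table[cols], conflict_log=conflict, slopes=slope_log)


def summarize_chromosome_table(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-chromosome (markers, bins, length) rows into the
    standard consensus-map characteristics table.

    Adds marker densities (markers/cM, half-up to 2 decimals) per
    chromosome, per genome letter, per homoeologous group, and a total row.
    Chromosome names must parse as <group digit><genome letter>.
    """
    df = per_chrom.copy()
    req = {"chromosome", "markers", "bins", "length_cM"}
    if not req <= set(df.columns):
        raise ValueError(f"need columns {sorted(req)}")
    parsed = df["chromosome"].map(parse_chromosome)
    df["group"] = parsed.map(lambda t: t[0])
    df["genome"] = parsed.map(lambda t: t[1])

    def agg(sub: pd.DataFrame, klass: str, label) -> dict:
        markers = int(sub["markers"].sum())
        bins = int(sub["bins"].sum())
        length = float(sub["length_cM"].sum())
        return {
            "class": klass, "name": str(label), "markers": markers, "bins": bins,
            "length_cM": round_half_up(length, 2),
            "density": round_half_up(markers / length, 2) if length > 0 else float("nan"),
        }

    rows = [agg(df[df["chromosome"] == c], "chromosome", c)
            for c in sorted(df["chromosome"].unique())]
    rows += [agg(df[df["genome"] == g], "genome", g)
             for g in sorted(df["genome"].unique())]
    rows += [agg(df[df["group"] == h], "homoeologous_group", h)
             for h in sorted(df["group"].unique())]
    rows.append(agg(df, "total", "total"))
    return pd.DataFrame(rows)


def summary_statistics(summary: pd.DataFrame) -> dict:
    """Headline aggregates of a characteristics table (see Results prose):
    overall density, total length, per-genome densities, mean chromosome
    length / markers per chromosome, mean homoeologous-group length."""
    total = summary[summary["class"] == "total"].iloc[0]
    chroms = summary[summary["class"] == "chromosome"]
    groups = summary[summary["class"] == "homoeologous_group"]
    genomes = summary[summary["class"] == "genome"].set_index("name")
    out = {
        "total_markers": int(total["markers"]),
        "total_bins": int(total["bins"]),
        "total_length_cM": float(total["length_cM"]),
        "overall_density": float(total["density"]),
        "mean_chromosome_length_cM": round_half_up(
            float(total["length_cM"]) / len(chroms), 2) if len(chroms) else float("nan"),
        "mean_markers_per_chromosome": round_half_up(
            int(total["markers"]) / len(chroms), 0) if len(chroms) else float("nan"),
        "mean_group_length_cM": round_half_up(
            float(total["length_cM"]) / len(groups), 2) if len(groups) else float("nan"),
    }
    for g, row in genomes.iterrows():
        out[f"genome_{g}_density"] = float(row["density"])
    return out


def write_summary_json(summary: pd.DataFrame, path) -> None:
    payload = {
        "rows": summary.to_dict(orient="records"),
        "statistics": summary_statistics(summary),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
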