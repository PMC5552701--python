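"""Single-population linkage map construction.

Four stages, mirroring the classic high-density RIL workflow:

1. **Binning** — markers with zero observed recombinants (k = 0 over the
   lines informative for both) are clustered by single linkage into
   recombinant bins; one *frame marker* per bin is elected by minimum
   missing-data rate, ties broken by a seeded random draw.
2. **Grouping** — frame markers are partitioned by single-linkage transitive
   closure over pairs with LOD >= threshold (default 7); frames in no
   qualifying pair are reported unlinked.
3. **Ordering** — each group is seriated to minimise SARF (the sum of
   adjacent meiotic recombination fractions): greedy nearest-neighbour chain
   construction, then 2-opt segment reversals, then a window-4 ripple, until
   no move improves.  Orientation is canonicalised so the first frame name
   sorts before the last.
4. **Assembly** — positions are cumulative map distances (Kosambi by
   default) between adjacent frames; binned markers are reintegrated at
   their frame's position; groups are assigned to chromosomes by majority
   vote of their members' anchor chromosomes when an anchor table is given.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._util import round_half_up
from .linkage import PairwiseEngine, map_distance
from .rilsim import GenotypeMatrix

DEFAULT_LOD_THRESHOLD = 7.0


@dataclass
class RecombinantBin:
    bin_id: str
    member_markers: list[str]
    frame_marker: str
    frame_missing_rate: float


@dataclass
class LinkageMap:
    """One population's map: ordered markers with cM positions per group.

    ``table`` columns: marker, linkage_group, chromosome, position_cM,
    bin_id, is_frame.  ``unlinked`` lists frame markers in no group.
    """

    table: pd.DataFrame
    unlinked: list[str] = field(default_factory=list)
    name: str = "map"

    REQUIRED = ["marker", "linkage_group", "chromosome", "position_cM", "bin_id", "is_frame"]

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"map table missing columns {sorted(missing)}")
        for _, sub in self.table.groupby("linkage_group"):
            pos = sub["position_cM"].to_numpy()
            if len(pos) and (np.diff(np.sort(pos)) < -1e-12).any():
                raise ValueError("positions must be nondecreasing within a group")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def total_length(self) -> float:
        return float(self.table.groupby("linkage_group")["position_cM"].max().sum())

    @property
    def marker_density(self) -> float:
        length = self.total_length
        return self.n_markers / length if length > 0 else float("nan")

    def groups(self) -> list[str]:
        return sorted(self.table["linkage_group"].unique())

    def chromosome_table(self, chromosome: str) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == chromosome]
        return sub.sort_values(["position_cM", "marker"]).reset_index(drop=True)

    def chromosome_paths(self, chromosome: str) -> list[tuple[str, pd.DataFrame]]:
        """One ordered (marker, position_cM) path per linkage group on the
        chromosome — a chromosome split into several groups yields several
        independent paths, each starting at 0."""
        sub = self.table[self.table["chromosome"] == chromosome]
        out = []
        for gid, g in sub.groupby("linkage_group"):
            path = g.sort_values(["position_cM", "marker"])[["marker", "position_cM"]]
            out.append((f"{self.name}/{gid}", path.reset_index(drop=True)))
        return sorted(out)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name: str = "map") -> "LinkageMap":
        df = pd.read_csv(path, sep="\t", dtype={"marker": str, "linkage_group": str,
                                                "chromosome": str, "bin_id": str})
        return cls(df, name=name)

    @classmethod
    def from_positions(cls, positions: pd.DataFrame, name: str = "map") -> "LinkageMap":
        """Build a map from a bare (marker, chromosome, position_cM) table."""
        df = positions.copy()
        if "linkage_group" not in df.columns:
            df["linkage_group"] = df["chromosome"].astype(str)
        if "bin_id" not in df.columns:
            df["bin_id"] = df["marker"]
        if "is_frame" not in df.columns:
            df["is_frame"] = True
        return cls(df[cls.REQUIRED], name=name)


def bin_markers(genotypes: GenotypeMatrix, engine: PairwiseEngine | None = None,
                seed: int = 0) -> list[RecombinantBin]:
    """Cluster zero-recombinant markers into bins and elect frame markers."""
    engine = engine or PairwiseEngine(genotypes)
    zero = (engine.k == 0) & (engine.n > 0)
    np.fill_diagonal(zero, False)
    n_comp, labels = connected_components(csr_matrix(zero), directed=False)
    missing = genotypes.missing_rate()
    rng = np.random.default_rng(seed)
    bins = []
    for comp in range(n_comp):
        members_idx = np.flatnonzero(labels == comp)
        members = [genotypes.marker_ids[i] for i in members_idx]
        rates = missing[members_idx]
        best = rates.min()
        tied = members_idx[np.isclose(rates, best)]
        frame_idx = int(tied[0]) if len(tied) == 1 else int(rng.choice(tied))
        bins.append(RecombinantBin(
            bin_id=f"bin{comp + 1:05d}",
            member_markers=members,
            frame_marker=genotypes.marker_ids[frame_idx],
            frame_missing_rate=float(missing[frame_idx]),
        ))
    return bins


def group_markers(frame_markers: list[str], engine: PairwiseEngine,
                  lod_threshold: float = DEFAULT_LOD_THRESHOLD
                  ) -> tuple[list[list[str]], list[str]]:
    """Single-linkage grouping of frames at LOD >= threshold.

    Returns (groups, unlinked); a frame is unlinked if no pair involving it
    reaches the threshold.
    """
    idx = [engine._index[m] for m in frame_markers]
    lod = engine.lod_matrix()[np.ix_(idx, idx)]
    adj = np.nan_to_num(lod, nan=-np.inf) >= lod_threshold
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups, unlinked = [], []
    for comp in range(n_comp):
        members = [frame_markers[i] for i in np.flatnonzero(labels == comp)]
        if len(members) == 1:
            unlinked.append(members[0])
        else:
            groups.append(members)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups, sorted(unlinked)


def _sarf(order: np.ndarray, dist: np.ndarray) -> float:
    return float(dist[order[:-1], order[1:]].sum())


def _greedy_chain(dist: np.ndarray) -> list[int]:
    m = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    chain = [int(i), int(j)]
    used = {int(i), int(j)}
    while len(chain) < m:
        free = np.array([x for x in range(m) if x not in used])
        d_head = d[chain[0], free]
        d_tail = d[chain[-1], free]
        if d_head.min() <= d_tail.min():
            nxt = int(free[np.argmin(d_head)])
            chain.insert(0, nxt)
        else:
            nxt = int(free[np.argmin(d_tail)])
            chain.append(nxt)
        used.add(nxt)
    return chain


def _two_opt(order: list[int], dist: np.ndarray) -> list[int]:
    """Path 2-opt: reverse segments while any reversal lowers SARF."""
    order = list(order)
    m = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                left = dist[order[i - 1], order[j]] - dist[order[i - 1], order[i]] if i > 0 else 0.0
                right = dist[order[i], order[j + 1]] - dist[order[j], order[j + 1]] if j < m - 1 else 0.0
                if left + right < -1e-12:
                    order[i:j + 1] = reversed(order[i:j + 1])
                    improved = True
    return order


def _ripple(order: list[int], dist: np.ndarray, window: int = 4) -> list[int]:
    """Exhaustively permute every length-``window`` window while it helps."""
    order = list(order)
    m = len(order)
    if m <= 2:
        return order
    w = min(window, m)
    perms = list(itertools.permutations(range(w)))
    improved = True
    while improved:
        improved = False
        for start in range(m - w + 1):
            seg = order[start:start + w]
            best_perm, best_cost = None, _window_cost(order, start, w, seg, dist)
            for p in perms:
                cand = [seg[i] for i in p]
                cost = _window_cost(order, start, w, cand, dist)
                if cost < best_cost - 1e-12:
                    best_cost, best_perm = cost, cand
            if best_perm is not None:
                order[start:start + w] = best_perm
                improved = True
    return order


def _window_cost(order, start, w, segment, dist):
    cost = dist[np.array(segment[:-1]), np.array(segment[1:])].sum() if w > 1 else 0.0
    if start > 0:
        cost += dist[order[start - 1], segment[0]]
    if start + w < len(order):
        cost += dist[segment[-1], order[start + w]]
    return float(cost)


def order_markers(group: list[str], engine: PairwiseEngine, seed: int = 0) -> list[str]:
    """Seriate one group by SARF minimisation; deterministic given inputs."""
    if len(group) < 2:
        return list(group)
    idx = [engine._index[m] for m in group]
    dist = engine.r_meiotic_matrix()[np.ix_(idx, idx)]
    # missing pairwise estimates are treated as uninformative (r = 0.5)
    dist = np.nan_to_num(dist, nan=0.5)
    if len(group) == 2:
        order = [0, 1]
    else:
        order = _greedy_chain(dist)
        order = _two_opt(order, dist)
        order = _ripple(order, dist, window=4)
        order = _two_opt(order, dist)
    names = [group[i] for i in order]
    if names[0] > names[-1]:
        names.reverse()
    return names


def exhaustive_order(group: list[str], engine: PairwiseEngine) -> tuple[list[str], float]:
    """Exact minimum-SARF order by enumerating all permutations (<= 9 markers)."""
    if len(group) > 9:
        raise ValueError("exhaustive search limited to 9 markers")
    idx = np.array([engine._index[m] for m in group])
    dist = np.nan_to_num(engine.r_meiotic_matrix()[np.ix_(idx, idx)], nan=0.5)
    m = len(group)
    perms = np.array(list(itertools.permutations(range(m))))
    costs = dist[perms[:, :-1], perms[:, 1:]].sum(axis=1)
    best = perms[np.argmin(costs)]
    names = [group[i] for i in best]
    if names[0] > names[-1]:
        names.reverse()
    return names, float(costs.min())


def assemble_map(
    groups: list[list[str]],
    bins: list[RecombinantBin],
    engine: PairwiseEngine,
    anchors: dict[str, str] | None = None,
    map_function: str = "kosambi",
    unlinked: list[str] | None = None,
    name: str = "map",
) -> LinkageMap:
    """Accumulate distances along ordered groups and reintegrate bin members.

    ``groups`` are ordered frame lists (from :func:`order_markers`);
    ``anchors`` maps marker -> chromosome for majority-vote assignment.
    """
    frame_to_bin = {b.frame_marker: b for b in bins}
    r_mat = engine.r_meiotic_matrix()
    rows = []
    for g_num, frames in enumerate(groups, start=1):
        gid = f"LG{g_num:03d}"
        pos = [0.0]
        for a, b in zip(frames[:-1], frames[1:]):
            i, j = engine._index[a], engine._index[b]
            r = r_mat[i, j]
            r = 0.5 if np.isnan(r) else r
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pos.append(pos[-1] + map_distance(r, map_function))
        members_chroms = []
        group_rows = []
        for frame, p in zip(frames, pos):
            bin_ = frame_to_bin.get(frame)
            members = bin_.member_markers if bin_ else [frame]
            bin_id = bin_.bin_id if bin_ else frame
            for m in members:
                group_rows.append([m, gid, None, float(p), bin_id, m == frame])
                if anchors and m in anchors:
                    members_chroms.append(anchors[m])
        chrom = None
        if members_chroms:
            counts = pd.Series(members_chroms).value_counts()
            if len(counts) == 1 or counts.iloc[0] > counts.iloc[1]:
                chrom = counts.index[0]
            else:
                warnings.warn(f"anchor tie for group {gid}; left unassigned")
        for row in group_rows:
            row[2] = chrom
        rows.extend(group_rows)
    table = pd.DataFrame(rows, columns=LinkageMap.REQUIRED)
    return LinkageMap(table, unlinked=list(unlinked or []), name=name)


def build_single_map(
    genotypes: GenotypeMatrix,
    lod_threshold: float = DEFAULT_LOD_THRESHOLD,
    anchors: dict[str, str] | None = None,
    map_function: str = "kosambi",
    seed: int = 0,
    min_group_size: int = 2,
) -> tuple[LinkageMap, dict]:
    """Full single-population pipeline: bin -> group -> order -> assemble.

    Returns the map and a small run summary (bin/group/unlinked counts,
    length, density rounded to printed precision).
    """
    engine = PairwiseEngine(genotypes)
    bins = bin_markers(genotypes, engine, seed=seed)
    frames = [b.frame_marker for b in bins]
    groups, unlinked = group_markers(frames, engine, lod_threshold)
    groups = [g for g in groups if len(g) >= min_group_size]
    ordered = [order_markers(g, engine, seed=seed) for g in groups]
    lmap = assemble_map(ordered, bins, engine, anchors=anchors,
                        map_function=map_function, unlinked=unlinked,
                        name=genotypes.name)
    summary = {
        "n_markers_in": genotypes.n_markers,
        "n_bins": len(bins),
        "n_frames": len(frames),
        "n_groups": len(groups),
        "n_unlinked_frames": len(unlinked),
        "n_markers_mapped": lmap.n_markers,
        "total_length_cM": round_half_up(lmap.total_length, 2),
        "marker_density": round_half_up(lmap.marker_density, 2)
        if lmap.total_length > 0 else None,
    }
    return lmap, summary
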