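"""Map concordance and structure statistics.

Spearman rank correlations of marker order between maps, classification of
a query map against a reference (consistent / inconsistent chromosome
assignment / newly mapped), multi-map marker-sharing (Venn) counts, and
marker/bin interval profiles with gap detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_SHARED_FOR_RHO = 3


def spearman_order(pos_a, pos_b) -> float:
    """Spearman rank correlation of two position vectors (ties mid-ranked).

    Returns NaN when fewer than 3 pairs are available.
    """
    a = np.asarray(pos_a, dtype=float)
    b = np.asarray(pos_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("position vectors must have equal length")
    if len(a) < MIN_SHARED_FOR_RHO:
        return float("nan")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


def _position_frame(map_like) -> pd.DataFrame:
    """Accept a ConsensusMap, LinkageMap or bare DataFrame -> marker/chromosome/position."""
    table = getattr(map_like, "table", map_like)
    return table[["marker", "chromosome", "position_cM"]].dropna(subset=["chromosome"])


@dataclass
class ComparisonReport:
    per_chromosome: pd.DataFrame  # chromosome, n_query, n_consistent, n_inconsistent, n_new, rho
    totals: dict

    def to_tsv(self, path) -> None:
        self.per_chromosome.to_csv(path, sep="\t", index=False)


def classify_vs_reference(query, reference) -> ComparisonReport:
    """Label every query marker against a reference map.

    consistent: present in both with the same chromosome; inconsistent:
    present in both on different chromosomes; new: query only.  Spearman rho
    is computed per chromosome on consistent markers only.  Per-chromosome
    rows are keyed by the query-side chromosome.
    """
    q = _position_frame(query).rename(columns={"chromosome": "chrom_q", "position_cM": "pos_q"})
    r = _position_frame(reference).rename(columns={"chromosome": "chrom_r", "position_cM": "pos_r"})
    merged = q.merge(r, on="marker", how="left")
    merged["status"] = np.where(
        merged["chrom_r"].isna(), "new",
        np.where(merged["chrom_q"] == merged["chrom_r"], "consistent", "inconsistent"),
    )
    rows = []
    for chrom, sub in merged.groupby("chrom_q"):
        cons = sub[sub["status"] == "consistent"]
        rows.append({
            "chromosome": chrom,
            "n_query": len(sub),
            "n_consistent": int((sub["status"] == "consistent").sum()),
            "n_inconsistent": int((sub["status"] == "inconsistent").sum()),
            "n_new": int((sub["status"] == "new").sum()),
            "rho": spearman_order(cons["pos_q"], cons["pos_r"]),
        })
    per_chrom = pd.DataFrame(rows).sort_values("chromosome").reset_index(drop=True)
    totals = {
        "n_query": int(per_chrom["n_query"].sum()),
        "n_consistent": int(per_chrom["n_consistent"].sum()),
        "n_inconsistent": int(per_chrom["n_inconsistent"].sum()),
        "n_new": int(per_chrom["n_new"].sum()),
    }
    totals["n_shared"] = totals["n_consistent"] + totals["n_inconsistent"]
    return ComparisonReport(per_chrom, totals)


def venn_sharing(maps: list) -> pd.DataFrame:
    """Count markers present in exactly 1..n of the given maps.

    Accepts LinkageMap/ConsensusMap objects, DataFrames with a ``marker``
    column, or bare marker-id collections.  Category counts always
    partition the union of distinct markers.
    """
    if len(maps) < 2:
        raise ValueError("venn_sharing requires >= 2 maps")
    sets = []
    for m in maps:
        table = getattr(m, "table", m)
        if isinstance(table, pd.DataFrame):
            sets.append(set(table["marker"]))
        else:
            sets.append(set(table))
    counts: dict[str, int] = {}
    for s in sets:
        for marker in s:
            counts[marker] = counts.get(marker, 0) + 1
    n = len(sets)
    return pd.DataFrame({
        "n_maps": np.arange(1, n + 1),
        "n_markers": [sum(1 for v in counts.values() if v == k) for k in range(1, n + 1)],
    })


@dataclass
class IntervalProfile:
    window: float
    per_chromosome: pd.DataFrame  # chromosome, window_start, n_markers, n_bins
    gaps: pd.DataFrame            # chromosome, start_cM, end_cM, gap_cM
    pearson_r: pd.DataFrame       # chromosome, r (marker vs bin window counts)


def interval_profile(map_like, window: float = 5.0,
                     gap_threshold: float = 10.0) -> IntervalProfile:
    """Marker/bin counts in half-open windows [0,w), [w,2w), ... and gaps.

    Gaps are intervals between adjacent *distinct* positions exceeding the
    threshold.  The Pearson correlation between per-window marker and bin
    counts is reported per chromosome (NaN when undefined).
    """
    table = getattr(map_like, "table", map_like)
    if "bin_id" not in table.columns:
        table = table.assign(bin_id=table["marker"])
    win_rows, gap_rows, r_rows = [], [], []
    for chrom, sub in table.groupby("chromosome"):
        pos = sub["position_cM"].to_numpy(dtype=float)
        length = pos.max()
        n_win = max(int(np.floor(length / window)) + 1, 1)
        edges = np.arange(0, (n_win + 1) * window, window)
        w_idx = np.clip(np.digitize(pos, edges) - 1, 0, n_win - 1)
        bin_first = sub.groupby("bin_id")["position_cM"].min().to_numpy()
        b_idx = np.clip(np.digitize(bin_first, edges) - 1, 0, n_win - 1)
        m_counts = np.bincount(w_idx, minlength=n_win)
        b_counts = np.bincount(b_idx, minlength=n_win)
        for w in range(n_win):
            win_rows.append((chrom, float(edges[w]), int(m_counts[w]), int(b_counts[w])))
        distinct = np.unique(pos)
        diffs = np.diff(distinct)
        for s, d in zip(distinct[:-1], diffs):
            if d > gap_threshold:
                gap_rows.append((chrom, float(s), float(s + d), float(d)))
        if n_win >= 2 and np.ptp(m_counts) > 0 and np.ptp(b_counts) > 0:
            r = float(stats.pearsonr(m_counts, b_counts).statistic)
        else:
            r = float("nan")
        r_rows.append((chrom, r))
    return IntervalProfile(
        window=window,
        per_chromosome=pd.DataFrame(win_rows, columns=["chromosome", "window_start",
                                                       "n_markers", "n_bins"]),
        gaps=pd.DataFrame(gap_rows, columns=["chromosome", "start_cM", "end_cM", "gap_cM"]),
        pearson_r=pd.DataFrame(r_rows, columns=["chromosome", "r"]),
    )
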