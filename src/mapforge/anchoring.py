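"""Physical anchoring of markers from tabular homology hits.

Consumes precomputed BLAST tabular output (outfmt 6) of SNP flanking
sequences against a genome or chromosome-survey database, selects a best
hit per marker under a strict E-value cutoff (< 1e-10 passes), links SNPs
to deletion-bin-mapped ESTs, and summarises chromosome-bin coverage of a
genetic map.  Also computes genetic-vs-physical order concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import parse_chromosome, round_half_up
from .validation import spearman_order

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                   "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
DEFAULT_E_THRESHOLD = 1e-10


def read_blast_tab(path) -> pd.DataFrame:
    """Read BLAST tabular (outfmt 6) hits, with line-numbered parse errors."""
    try:
        df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#",
                         dtype={"qseqid": str, "sseqid": str})
    except Exception as exc:  # re-raise with file context
        raise ValueError(f"cannot parse BLAST tabular file {path}: {exc}") from exc
    for col in ("pident", "evalue", "bitscore"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (np.flatnonzero(bad) + 1).tolist()
            raise ValueError(f"malformed numeric field {col!r} at line(s) {lines} of {path}")
        df[col] = pd.to_numeric(df[col])
    return df


def best_hit(hits: pd.DataFrame, e_threshold: float = DEFAULT_E_THRESHOLD) -> pd.DataFrame:
    """Minimum-E-value hit per query under a strict E-value cutoff.

    Ties are broken by higher identity, then lexicographic subject id, so
    the result is stable under row reordering.  Queries with no qualifying
    hit are absent from the output.
    """
    kept = hits[hits["evalue"] < e_threshold]
    if kept.empty:
        return kept.copy()
    ordered = kept.sort_values(["qseqid", "evalue", "pident", "sseqid"],
                               ascending=[True, True, False, True],
                               kind="mergesort")
    return ordered.groupby("qseqid", as_index=False).first()


def subject_chromosome(sseqid: str) -> str:
    """Chromosome of a subject id; arm suffixes (1AS/1AL) are stripped."""
    token = str(sseqid).split("_")[0].split(":")[0]
    group, genome = parse_chromosome(token)
    return f"{group}{genome}"


def subject_arm(sseqid: str) -> str | None:
    """Arm letter of a subject id (S/L), or None when not distinguished."""
    token = str(sseqid).split("_")[0].split(":")[0]
    return token[2] if len(token) >= 3 and token[2] in "SL" else None


@dataclass
class BinAssignment:
    snp_bins: pd.DataFrame        # marker, chromosome, bin_id, est
    per_chromosome: pd.DataFrame  # chromosome, n_ests, n_snps, corresponding_bins, all_bins, coverage
    per_genome: pd.DataFrame
    total: dict
    cross_assignments: pd.DataFrame


def _coverage(corresponding: int, all_bins: int) -> float:
    return round_half_up(100.0 * corresponding / all_bins, 1) if all_bins else 0.0


def coverage_summary(per_chrom: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Genome-level and total bin-coverage summary from per-chromosome rows.

    Expects columns chromosome, n_ests, n_snps, corresponding_bins,
    all_bins; genome-level corresponding/all counts are sums over the
    genome's chromosomes and coverage = 100 * corresponding / all (half-up,
    1 decimal).
    """
    df = per_chrom.copy()
    df["genome"] = df["chromosome"].map(lambda c: parse_chromosome(c)[1])
    df["coverage"] = [
        _coverage(c, a) for c, a in zip(df["corresponding_bins"], df["all_bins"])
    ]
    g_rows = []
    for genome, sub in df.groupby("genome"):
        g_rows.append({
            "genome": genome,
            "n_ests": int(sub["n_ests"].sum()),
            "n_snps": int(sub["n_snps"].sum()),
            "corresponding_bins": int(sub["corresponding_bins"].sum()),
            "all_bins": int(sub["all_bins"].sum()),
            "coverage": _coverage(int(sub["corresponding_bins"].sum()),
                                  int(sub["all_bins"].sum())),
        })
    total = {
        "n_ests": int(df["n_ests"].sum()),
        "n_snps": int(df["n_snps"].sum()),
        "corresponding_bins": int(df["corresponding_bins"].sum()),
        "all_bins": int(df["all_bins"].sum()),
        "coverage": _coverage(int(df["corresponding_bins"].sum()),
                              int(df["all_bins"].sum())),
    }
    return pd.DataFrame(g_rows), total


def assign_bins(markers: pd.DataFrame, snp_est: pd.DataFrame,
                est_bin: pd.DataFrame, all_bins: pd.DataFrame) -> BinAssignment:
    """Assign chromosome bins to mapped SNPs through linked ESTs.

    ``markers``: (marker, chromosome) of the genetic map; ``snp_est``:
    (marker, est) links; ``est_bin``: (est, chromosome, bin_id);
    ``all_bins``: (chromosome, n_bins) denominators.  ESTs redundant within
    one chromosomal location (same est, chromosome, bin) are deduplicated.
    An EST whose bin chromosome differs from the SNP's map chromosome is
    logged as a cross-assignment and excluded from coverage.
    """
    est_bin = est_bin.drop_duplicates(subset=["est", "chromosome", "bin_id"])
    linked = (markers.merge(snp_est, on="marker")
              .merge(est_bin.rename(columns={"chromosome": "bin_chromosome"}), on="est"))
    cross = linked[linked["chromosome"] != linked["bin_chromosome"]].copy()
    ok = linked[linked["chromosome"] == linked["bin_chromosome"]]
    snp_bins = ok[["marker", "chromosome", "bin_id", "est"]].drop_duplicates()
    rows = []
    for _, arow in all_bins.iterrows():
        chrom = arow["chromosome"]
        sub = ok[ok["chromosome"] == chrom]
        corresponding = int(sub["bin_id"].nunique())
        rows.append({
            "chromosome": chrom,
            "n_ests": int(sub["est"].nunique()),
            "n_snps": int(sub["marker"].nunique()),
            "corresponding_bins": corresponding,
            "all_bins": int(arow["n_bins"]),
        })
    per_chrom = pd.DataFrame(rows)
    per_genome, total = coverage_summary(per_chrom)
    per_chrom["coverage"] = [
        _coverage(c, a) for c, a in zip(per_chrom["corresponding_bins"], per_chrom["all_bins"])
    ]
    return BinAssignment(snp_bins, per_chrom, per_genome, total,
                         cross.reset_index(drop=True))


def physical_concordance(map_like, best_hits: pd.DataFrame,
                         position_col: str = "sstart") -> pd.DataFrame:
    """Per-chromosome Spearman rho between genetic and physical order.

    ``best_hits`` is the output of :func:`best_hit`; the physical coordinate
    defaults to the subject start.  Returns one row per chromosome with the
    rho and the (cM, physical) pair count; the underlying pair table is
    attached as ``.attrs['pairs']`` for plotting/export.
    """
    table = getattr(map_like, "table", map_like)
    hits = best_hits.rename(columns={"qseqid": "marker"})
    merged = table.merge(hits[["marker", "sseqid", position_col]], on="marker")
    rows = []
    for chrom, sub in merged.groupby("chromosome"):
        rows.append({
            "chromosome": chrom,
            "n_anchored": len(sub),
            "rho": spearman_order(sub["position_cM"], sub[position_col]),
        })
    out = pd.DataFrame(rows).sort_values("chromosome").reset_index(drop=True)
    out.attrs["pairs"] = merged[["marker", "chromosome", "position_cM", position_col]]
    return out
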