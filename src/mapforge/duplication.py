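"""Multi-locus assay analysis: duplication and translocation evidence.

One array assay mapping to two or more genome positions ("multi-locus SNP")
is evidence for duplicated sequence.  All unordered pairs of its loci are
expanded (m loci -> m(m-1)/2 pairs) and each pair classified by wheat-style
chromosome nomenclature (<homoeologous-group digit><genome letter>):

- homoeologous: same group, different genome (1A-1B) — expected paralogy
  between the A/B/D subgenomes;
- intra_genomic: same genome, different group (1A-2A);
- inter_genomic: different genome and different group (1A-2B).

Non-homoeologous pairs are the raw evidence for chromosomal translocations.
Two loci of one assay on the same chromosome do not form a pair; they are
logged separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import parse_chromosome
from .validation import spearman_order

CATEGORIES = ("homoeologous", "intra_genomic", "inter_genomic")


@dataclass
class LocusPair:
    assay: str
    locus_a: tuple[str, float]  # (chromosome, position)
    locus_b: tuple[str, float]
    category: str | None


def _locus_table(consensus_or_df) -> pd.DataFrame:
    """Normalise input to a (assay, chromosome, position_cM) locus table."""
    table = getattr(consensus_or_df, "table", consensus_or_df)
    if "assay" not in table.columns:
        raise ValueError("input must carry an 'assay' column per mapped locus")
    return table[["assay", "chromosome", "position_cM"]].reset_index(drop=True)


def find_multi_locus(consensus_or_df) -> pd.DataFrame:
    """Loci of every assay mapped to more than one position."""
    loci = _locus_table(consensus_or_df)
    counts = loci.groupby("assay")["chromosome"].transform("size")
    multi = loci[counts >= 2].sort_values(["assay", "chromosome", "position_cM"])
    return multi.reset_index(drop=True)


def expand_pairs(multi_loci: pd.DataFrame) -> pd.DataFrame:
    """All unordered locus pairs per assay: m loci -> m(m-1)/2 pairs."""
    rows = []
    for assay, sub in multi_loci.groupby("assay"):
        recs = list(sub[["chromosome", "position_cM"]].itertuples(index=False))
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                rows.append((assay, recs[i][0], float(recs[i][1]),
                             recs[j][0], float(recs[j][1])))
    return pd.DataFrame(rows, columns=["assay", "chrom_a", "pos_a", "chrom_b", "pos_b"])


def classify_pair(chrom_a: str, chrom_b: str,
                  nomenclature: dict | None = None) -> str | None:
    """Category of one chromosome pair; None for a same-chromosome pair."""
    ga, la = parse_chromosome(chrom_a, nomenclature)
    gb, lb = parse_chromosome(chrom_b, nomenclature)
    if (ga, la) == (gb, lb):
        return None
    if ga == gb and la != lb:
        return "homoeologous"
    if la == lb:
        return "intra_genomic"
    return "inter_genomic"


def classify_pairs(pairs: pd.DataFrame, nomenclature: dict | None = None
                   ) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Classify expanded pairs; returns (table, category counts, pair matrix).

    The matrix counts pairs per unordered chromosome pair.  Same-chromosome
    pairs are excluded from the categories and counted under
    ``same_chromosome``.  Unparseable chromosome names raise with the full
    offender list.
    """
    bad = []
    for name in pd.concat([pairs["chrom_a"], pairs["chrom_b"]]).unique():
        try:
            parse_chromosome(name, nomenclature)
        except ValueError:
            bad.append(str(name))
    if bad:
        raise ValueError(f"unparseable chromosome names: {sorted(set(bad))}")
    out = pairs.copy()
    out["category"] = [classify_pair(a, b, nomenclature)
                       for a, b in zip(out["chrom_a"], out["chrom_b"])]
    counts = {c: int((out["category"] == c).sum()) for c in CATEGORIES}
    counts["same_chromosome"] = int(out["category"].isna().sum())
    counts["total_pairs"] = len(out)
    cross = out[out["category"].notna()]
    chroms = sorted(set(cross["chrom_a"]) | set(cross["chrom_b"]))
    matrix = pd.DataFrame(0, index=chroms, columns=chroms, dtype=int)
    for a, b in zip(cross["chrom_a"], cross["chrom_b"]):
        lo, hi = sorted([a, b])
        matrix.loc[lo, hi] += 1
    return out, counts, matrix


def homoeolog_collinearity(pairs: pd.DataFrame, chrom_a: str, chrom_b: str) -> float:
    """Spearman rho of paired positions on one homoeologous chromosome pair.

    NaN when fewer than 3 locus pairs connect the two chromosomes.
    """
    lo, hi = sorted([chrom_a, chrom_b])
    fwd = pairs[(pairs["chrom_a"] == lo) & (pairs["chrom_b"] == hi)]
    rev = pairs[(pairs["chrom_a"] == hi) & (pairs["chrom_b"] == lo)]
    pos_a = np.concatenate([fwd["pos_a"].to_numpy(), rev["pos_b"].to_numpy()])
    pos_b = np.concatenate([fwd["pos_b"].to_numpy(), rev["pos_a"].to_numpy()])
    return spearman_order(pos_a, pos_b)


def collinearity_table(pairs: pd.DataFrame, nomenclature: dict | None = None
                       ) -> pd.DataFrame:
    """Collinearity rho for every homoeologous chromosome pair with >= 3 pairs."""
    classified, _, _ = classify_pairs(pairs, nomenclature)
    homo = classified[classified["category"] == "homoeologous"]
    rows = []
    seen = set()
    for a, b in zip(homo["chrom_a"], homo["chrom_b"]):
        key = tuple(sorted([a, b]))
        if key in seen:
            continue
        seen.add(key)
        rows.append((key[0], key[1], homoeolog_collinearity(pairs, *key)))
    return pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "rho"]).sort_values(
        ["chrom_a", "chrom_b"]).reset_index(drop=True)
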