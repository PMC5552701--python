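"""Two-point linkage engine for RIL populations.

Estimates the observed recombinant-line fraction R between marker pairs,
corrects it to the meiotic recombination fraction r via the
Haldane–Waddington relation for selfed RILs (R = 2r / (1 + 2r), hence
r = R / (2(1 - R))), scores linkage with a binomial LOD, and converts r to
map distance with the Kosambi (default) or Haldane function.

F6/F8 RILs are treated as fully inbred for the R<->r transform: the
generation-specific correction changes distances by well under a percent at
those generations.  Heterozygous calls are excluded from pair counts,
consistent with the QC module's H-masking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rilsim import A, B, GenotypeMatrix

LOG10_HALF = np.log10(0.5)
DEFAULT_MAX_DISTANCE_CM = 100.0


class UndefinedPairError(ValueError):
    """No line is informative (non-missing, homozygous) at both markers."""


@dataclass
class PairwiseLinkage:
    marker_a: str
    marker_b: str
    n_informative: int
    k_recombinant: int
    R_hat: float
    r_meiotic: float
    lod: float


def ril_to_meiotic(R: float) -> float:
    """Invert Haldane–Waddington: meiotic r from observed RIL fraction R.

    R is capped at 0.5 (independence) before inversion; R >= 1 is a domain
    error.  Exact inverse of r -> 2r/(1+2r) on [0, 0.5].
    """
    R = np.asarray(R, dtype=float)
    if np.any(R >= 1.0) or np.any(R < 0.0):
        raise ValueError("RIL fraction must lie in [0, 1)")
    R = np.minimum(R, 0.5)
    out = R / (2.0 * (1.0 - R))
    return float(out) if out.ndim == 0 else out


def meiotic_to_ril(r: float) -> float:
    """Expected recombinant-line fraction in fully selfed RILs: 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * r / (1.0 + 2.0 * r)
    return float(out) if out.ndim == 0 else out


def map_distance(r, function: str = "kosambi",
                 max_distance: float = DEFAULT_MAX_DISTANCE_CM):
    """Map distance in cM from meiotic recombination fraction.

    kosambi: 25 * ln((1+2r)/(1-2r));  haldane: -50 * ln(1-2r).
    r >= 0.5 is capped at ``max_distance`` with a warning.
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr < 0.0):
        raise ValueError("recombination fraction must be >= 0")
    capped = r_arr >= 0.5
    if capped.any():
        warnings.warn("r >= 0.5 capped at max_distance", stacklevel=2)
    safe = np.where(capped, 0.25, r_arr)
    if function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * safe) / (1.0 - 2.0 * safe))
    elif function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * safe)
    else:
        raise ValueError(f"unknown map function {function!r}")
    d = np.where(capped, max_distance, np.minimum(d, max_distance))
    return float(d[0]) if np.isscalar(r) or np.ndim(r) == 0 else d


def _lod(k, n, R):
    """Binomial log10 likelihood ratio vs independence, at fraction R."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_k = np.where(k > 0, k * np.log10(R), 0.0)
        term_nk = np.where(n - k > 0, (n - k) * np.log10(1.0 - R), 0.0)
    return term_k + term_nk - n * LOG10_HALF


def lod_score(k: int, n: int) -> float:
    """LOD at the (capped) MLE R = k/n; R floored at 1/(2n) when k = 0."""
    if n <= 0:
        raise UndefinedPairError("no informative lines")
    R = k / n
    if k == 0:
        R = 1.0 / (2.0 * n)
    R = min(R, 0.5)
    return float(max(_lod(k, n, R), 0.0))


def estimate_pair(calls_a: np.ndarray, calls_b: np.ndarray,
                  name_a: str = "a", name_b: str = "b") -> PairwiseLinkage:
    """Two-point estimate from two call vectors (H treated as missing)."""
    a = np.asarray(calls_a, dtype=np.int8)
    b = np.asarray(calls_b, dtype=np.int8)
    informative = np.isin(a, [A, B]) & np.isin(b, [A, B])
    n = int(informative.sum())
    if n == 0:
        raise UndefinedPairError(f"no informative lines for pair ({name_a}, {name_b})")
    k = int((a[informative] != b[informative]).sum())
    R_hat = min(k / n, 0.5)
    return PairwiseLinkage(
        marker_a=name_a, marker_b=name_b, n_informative=n, k_recombinant=k,
        R_hat=R_hat, r_meiotic=ril_to_meiotic(R_hat), lod=lod_score(k, n),
    )


class PairwiseEngine:
    """Vectorised all-pairs two-point statistics over one genotype matrix.

    Encodes homozygous calls as +/-1 and everything else as 0, so that the
    informative count and the agreement count of every marker pair fall out
    of two matrix products.
    """

    def __init__(self, genotypes: GenotypeMatrix):
        self.genotypes = genotypes
        self.marker_ids = list(genotypes.marker_ids)
        self._index = {m: i for i, m in enumerate(self.marker_ids)}
        calls = genotypes.calls
        signed = np.zeros(calls.shape, dtype=np.float64)
        signed[calls == A] = 1.0
        signed[calls == B] = -1.0
        mask = (signed != 0).astype(np.float64)
        self.n = (mask @ mask.T).astype(np.int64)          # informative lines
        agree = signed @ signed.T                           # agreements - disagreements
        self.k = np.rint((self.n - agree) / 2.0).astype(np.int64)  # recombinants

    def R_matrix(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.where(self.n > 0, self.k / np.maximum(self.n, 1), np.nan)
        return np.minimum(R, 0.5)

    def r_meiotic_matrix(self) -> np.ndarray:
        R = self.R_matrix()
        return R / (2.0 * (1.0 - R))

    def lod_matrix(self) -> np.ndarray:
        n = self.n.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.where(self.n > 0, self.k / np.maximum(n, 1.0), np.nan)
            R = np.where((self.k == 0) & (self.n > 0), 1.0 / (2.0 * np.maximum(n, 1.0)), R)
        R = np.minimum(R, 0.5)
        lod = _lod(self.k, n, R)
        lod = np.where(self.n > 0, np.maximum(lod, 0.0), np.nan)
        np.fill_diagonal(lod, np.nan)
        return lod

    def pair(self, marker_a: str, marker_b: str) -> PairwiseLinkage:
        i, j = self._index[marker_a], self._index[marker_b]
        n = int(self.n[i, j])
        if n == 0:
            raise UndefinedPairError(f"no informative lines for pair ({marker_a}, {marker_b})")
        k = int(self.k[i, j])
        R_hat = min(k / n, 0.5)
        return PairwiseLinkage(marker_a, marker_b, n, k, R_hat,
                               ril_to_meiotic(R_hat), lod_score(k, n))

    def to_table(self) -> pd.DataFrame:
        """Upper-triangle pairwise results as a tidy table."""
        rows = []
        m = len(self.marker_ids)
        R = self.R_matrix()
        r = self.r_meiotic_matrix()
        lod = self.lod_matrix()
        for i in range(m):
            for j in range(i + 1, m):
                if self.n[i, j] == 0:
                    continue
                rows.append((self.marker_ids[i], self.marker_ids[j],
                             int(self.n[i, j]), int(self.k[i, j]),
                             R[i, j], r[i, j], lod[i, j]))
        return pd.DataFrame(rows, columns=["marker_a", "marker_b", "n", "k", "R", "r", "lod"])
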