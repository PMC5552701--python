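"""Genotype quality control for RIL SNP matrices.

Three rules, applied in order: (i) heterozygous calls are masked to missing
(a RIL assay call of H is treated as unreliable); (ii) markers with a
missing-call fraction strictly over ``max_missing_rate`` are dropped;
(iii) markers whose allele-A frequency over the remaining non-missing calls
falls outside the inclusive band [``allele_freq_min``, ``allele_freq_max``]
are dropped.  Boundary conventions — "over 10%" strict, the frequency band
inclusive — are fixed here and stated in every report so filtered counts are
exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .rilsim import A, H, MISSING, GenotypeMatrix


@dataclass
class QCConfig:
    max_missing_rate: float = 0.10
    allele_freq_min: float = 0.3
    allele_freq_max: float = 0.7

    def __post_init__(self):
        if not (0.0 <= self.allele_freq_min < self.allele_freq_max <= 1.0):
            raise ValueError("require 0 <= allele_freq_min < allele_freq_max <= 1")
        if not (0.0 <= self.max_missing_rate <= 1.0):
            raise ValueError("max_missing_rate outside [0, 1]")


@dataclass
class QCReport:
    n_input_markers: int
    n_het_calls_masked: int
    n_dropped_missing: int
    n_dropped_freq: int
    n_retained: int
    conventions: str = (
        "H masked to missing; missing fraction strictly > threshold drops; "
        "allele-A frequency band inclusive at both bounds"
    )

    def __post_init__(self):
        assert self.n_retained == (
            self.n_input_markers - self.n_dropped_missing - self.n_dropped_freq
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def apply_qc(genotypes: GenotypeMatrix, config: QCConfig | None = None
             ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the three QC rules; returns the filtered matrix and a report.

    An empty output (all markers dropped) is reported, not raised.
    """
    config = config or QCConfig()
    calls = genotypes.calls.copy()
    n_het = int((calls == H).sum())
    calls[calls == H] = MISSING

    n_lines = calls.shape[1]
    missing_frac = (calls == MISSING).mean(axis=1) if n_lines else np.zeros(calls.shape[0])
    keep_missing = missing_frac <= config.max_missing_rate

    n_nonmissing = (calls != MISSING).sum(axis=1)
    n_a = (calls == A).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_a = np.where(n_nonmissing > 0, n_a / np.maximum(n_nonmissing, 1), np.nan)
    keep_freq = (freq_a >= config.allele_freq_min) & (freq_a <= config.allele_freq_max)
    keep_freq &= n_nonmissing > 0

    n_dropped_missing = int((~keep_missing).sum())
    n_dropped_freq = int((keep_missing & ~keep_freq).sum())
    keep = keep_missing & keep_freq

    marker_ids = [m for m, k in zip(genotypes.marker_ids, keep) if k]
    out = GenotypeMatrix(
        marker_ids,
        list(genotypes.line_ids),
        calls[keep],
        genotypes.marker_meta.loc[marker_ids],
        name=genotypes.name,
    )
    report = QCReport(
        n_input_markers=genotypes.n_markers,
        n_het_calls_masked=n_het,
        n_dropped_missing=n_dropped_missing,
        n_dropped_freq=n_dropped_freq,
        n_retained=len(marker_ids),
    )
    return out, report
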