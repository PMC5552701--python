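"""Synthetic recombinant-inbred-line (RIL) panel generator.

Emulates the statistical structure of multi-population wheat RIL studies:
several F2:6/F2:8 populations genotyped on a shared marker panel, with each
population segregating for only a subset of the markers, plus configurable
missing data, genotyping error, residual heterozygosity, multi-locus
(duplicated) assays and chromosomal translocations — all with a known true
map so downstream map construction can be scored against the truth.

Meiosis model: crossovers form a no-interference (Poisson) process along the
chromosome, one expected crossover per 100 cM.  At the marker level this is
simulated exactly as a Markov phase process: the transmitted phase switches
between adjacent markers separated by d cM with the Haldane probability
r = (1 - exp(-2d/100)) / 2, independently across intervals.  Lines descend
from an F1 by `selfing_generation - 1` rounds of selfing simulated
generation by generation, so residual heterozygosity decays as (1/2)^g and
differs between F2:6 and F2:8 panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# genotype codes in the call matrix
A, B, H, MISSING = np.int8(0), np.int8(1), np.int8(2), np.int8(-1)
CODE_TO_CHAR = {0: "A", 1: "B", 2: "H", -1: "-"}
CHAR_TO_CODE = {"A": 0, "B": 1, "H": 2, "-": -1}


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass
class TrueMap:
    """Ground-truth genetic map used to drive the simulator.

    ``chromosomes`` is a list of (name, length in cM); ``markers`` is a
    DataFrame with columns marker, chromosome, position_cM, genome, group
    (homoeologous group) and assay (assay id; equals the marker name except
    for multi-locus assays).
    """

    chromosomes: list[tuple[str, float]]
    markers: pd.DataFrame

    def __post_init__(self):
        req = {"marker", "chromosome", "position_cM", "genome", "group"}
        missing = req - set(self.markers.columns)
        if missing:
            raise ConfigError(f"true map missing columns: {sorted(missing)}")
        if "assay" not in self.markers.columns:
            self.markers = self.markers.assign(assay=self.markers["marker"])
        if self.markers["marker"].duplicated().any():
            raise ConfigError("marker names must be unique")
        lengths = dict(self.chromosomes)
        for chrom, sub in self.markers.groupby("chromosome"):
            if chrom not in lengths:
                raise ConfigError(f"marker on unknown chromosome {chrom}")
            pos = sub["position_cM"].to_numpy()
            if (pos < 0).any() or (pos > lengths[chrom] + 1e-9).any():
                raise ConfigError(f"marker positions outside chromosome {chrom}")
        self.markers = (
            self.markers.sort_values(["chromosome", "position_cM", "marker"])
            .reset_index(drop=True)
        )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def positions(self, chromosome: str) -> pd.DataFrame:
        return self.markers[self.markers["chromosome"] == chromosome]

    def to_tsv(self, path) -> None:
        self.markers.to_csv(path, sep="\t", index=False)


@dataclass
class TranslocationSpec:
    """Relocate the [start, end] cM segment of one chromosome to another.

    Markers in the segment are reassigned to ``chrom_to`` and appended past
    its current end, preserving their relative spacing — the simulated
    inheritance then follows the rearranged map while the nominal marker
    names (and any anchor table built from the original map) still reflect
    the un-rearranged genome.
    """

    chrom_from: str
    start: float
    end: float
    chrom_to: str


@dataclass
class SimConfig:
    """Panel-level simulation parameters.

    ``n_lines`` may be a single size or one size per population (the four
    source populations of the emulated study ranged from 176 to 275 lines).
    ``selfing_generation`` is 6 for F2:6 and 8 for F2:8 RILs.
    """

    n_lines: int | Sequence[int] = 250
    selfing_generation: int = 6
    missing_rate: float = 0.05
    error_rate: float = 0.005
    residual_het_rate: Optional[float] = None
    population_marker_fraction: float = 0.4
    n_populations: int = 4
    seed: int = 0
    duplications: list[tuple[str, list[tuple[str, float]]]] = field(default_factory=list)
    translocation: Optional[TranslocationSpec] = None

    def __post_init__(self):
        for name in ("missing_rate", "error_rate", "population_marker_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.residual_het_rate is not None and not (0.0 <= self.residual_het_rate <= 1.0):
            raise ConfigError("residual_het_rate outside [0, 1]")
        sizes = self.line_counts()
        if any(n < 2 for n in sizes):
            raise ConfigError("n_lines must be >= 2")
        if self.selfing_generation < 2:
            raise ConfigError("selfing_generation must be >= 2")
        if self.n_populations < 1:
            raise ConfigError("n_populations must be >= 1")

    def line_counts(self) -> list[int]:
        if np.isscalar(self.n_lines):
            return [int(self.n_lines)] * self.n_populations
        sizes = [int(n) for n in self.n_lines]
        if len(sizes) != self.n_populations:
            raise ConfigError("len(n_lines) must equal n_populations")
        return sizes


@dataclass
class GenotypeMatrix:
    """Markers x lines matrix of biallelic RIL calls.

    ``calls`` is int8 with codes 0=A, 1=B, 2=H, -1=missing.  ``marker_meta``
    carries per-marker truth (chromosome, position, assay) when simulated.
    """

    marker_ids: list[str]
    line_ids: list[str]
    calls: np.ndarray
    marker_meta: pd.DataFrame = None
    name: str = "population"

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.marker_ids), len(self.line_ids)):
            raise ConfigError("call matrix shape inconsistent with ids")
        bad = ~np.isin(self.calls, [A, B, H, MISSING])
        if bad.any():
            raise ConfigError("call matrix contains invalid codes")
        if self.marker_meta is None:
            self.marker_meta = pd.DataFrame(index=pd.Index(self.marker_ids, name="marker"))

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing calls (H counts as a call here)."""
        return (self.calls == MISSING).mean(axis=1)

    def subset(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {m: i for i, m in enumerate(self.marker_ids)}
        rows = [index[m] for m in marker_ids]
        return GenotypeMatrix(
            list(marker_ids),
            list(self.line_ids),
            self.calls[rows],
            self.marker_meta.loc[list(marker_ids)],
            name=self.name,
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("marker\t" + "\t".join(self.line_ids) + "\n")
            for mid, row in zip(self.marker_ids, self.calls):
                fh.write(mid + "\t" + "\t".join(CODE_TO_CHAR[int(c)] for c in row) + "\n")

    @classmethod
    def from_tsv(cls, path, name: str = "population") -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str)
        marker_ids = df.iloc[:, 0].tolist()
        line_ids = list(df.columns[1:])
        try:
            calls = df.iloc[:, 1:].map(lambda c: CHAR_TO_CODE[c]).to_numpy(dtype=np.int8)
        except KeyError as exc:
            raise ConfigError(f"invalid genotype code {exc} in {path}") from exc
        return cls(marker_ids, line_ids, calls, name=name)


WHEAT_GENOMES = ("A", "B", "D")


def wheat_chromosome_names(n_groups: int = 7, genomes: Sequence[str] = WHEAT_GENOMES) -> list[str]:
    return [f"{g}{letter}" for g in range(1, n_groups + 1) for letter in genomes]


def simulate_true_map(
    chromosome_lengths: dict[str, float] | Sequence[tuple[str, float]],
    markers_per_chromosome: int | dict[str, int],
    seed: int = 0,
    grid: bool = False,
) -> TrueMap:
    """Place markers on chromosomes, uniformly at random or on an even grid.

    Chromosome names are parsed as <group digit><genome letter> to fill the
    genome / homoeologous-group metadata used by the duplication analysis.
    """
    from ._util import parse_chromosome

    chroms = list(chromosome_lengths.items()) if isinstance(chromosome_lengths, dict) else [
        (str(c), float(length)) for c, length in chromosome_lengths
    ]
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chroms:
        if length <= 0:
            raise ConfigError(f"chromosome {chrom} has non-positive length {length}")
        count = markers_per_chromosome[chrom] if isinstance(markers_per_chromosome, dict) \
            else int(markers_per_chromosome)
        if count < 2:
            raise ConfigError(f"chromosome {chrom} needs >= 2 markers, got {count}")
        if grid:
            pos = np.linspace(0.0, length, count)
        else:
            pos = np.sort(rng.uniform(0.0, length, size=count))
        try:
            group, genome = parse_chromosome(chrom)
        except ValueError:
            group, genome = 0, "?"
        for i, p in enumerate(pos):
            rows.append((f"{chrom}_m{i:03d}", chrom, float(p), genome, group))
    markers = pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM", "genome", "group"])
    return TrueMap([(c, float(l)) for c, l in chroms], markers)


def apply_translocation(true_map: TrueMap, spec: TranslocationSpec) -> TrueMap:
    """Return a rearranged true map with one segment moved between chromosomes."""
    markers = true_map.markers.copy()
    lengths = dict(true_map.chromosomes)
    if spec.chrom_from not in lengths or spec.chrom_to not in lengths:
        raise ConfigError("translocation references unknown chromosome")
    in_seg = (
        (markers["chromosome"] == spec.chrom_from)
        & (markers["position_cM"] >= spec.start)
        & (markers["position_cM"] <= spec.end)
    )
    offset = lengths[spec.chrom_to] - spec.start
    markers.loc[in_seg, "position_cM"] = markers.loc[in_seg, "position_cM"] + offset
    markers.loc[in_seg, "chromosome"] = spec.chrom_to
    new_lengths = dict(lengths)
    new_lengths[spec.chrom_to] = lengths[spec.chrom_to] + (spec.end - spec.start)
    return TrueMap(list(new_lengths.items()), markers)


def translocate_loci(loci: pd.DataFrame, spec: TranslocationSpec) -> pd.DataFrame:
    """Apply a translocation's relocation rule to a (chromosome, position_cM)
    locus table — e.g. the duplication registry — so that truth-side analyses
    see the rearranged genome."""
    out = loci.copy()
    in_seg = (
        (out["chromosome"] == spec.chrom_from)
        & (out["position_cM"] >= spec.start)
        & (out["position_cM"] <= spec.end)
    )
    out.loc[in_seg, "position_cM"] = out.loc[in_seg, "position_cM"] - spec.start
    out.loc[in_seg, "chromosome"] = spec.chrom_to
    return out


def _interval_switch_probs(positions: np.ndarray) -> np.ndarray:
    """Haldane switch probability for each inter-marker interval (cM)."""
    d = np.diff(positions)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def _gametes(hap0: np.ndarray, hap1: np.ndarray, switch_p: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete per line from (hap0, hap1), shape (n_lines, n_markers)."""
    n_lines, n_markers = hap0.shape
    start = rng.integers(0, 2, size=(n_lines, 1), dtype=np.int8)
    if n_markers > 1:
        switches = (rng.random((n_lines, n_markers - 1)) < switch_p).astype(np.int8)
        phase = np.concatenate([start, switches], axis=1)
        np.bitwise_xor.accumulate(phase, axis=1, out=phase)
    else:
        phase = start
    return np.where(phase == 1, hap1, hap0)


def simulate_population(
    true_map: TrueMap,
    config: SimConfig,
    n_lines: Optional[int] = None,
    seed: Optional[int] = None,
    name: str = "population",
) -> GenotypeMatrix:
    """Simulate one RIL population on the full marker set of ``true_map``.

    Each line descends from a single F1 through ``selfing_generation - 1``
    rounds of selfing; genotyping errors (symmetric allele flips) are applied
    to homozygous calls after inheritance, then missingness.  Multi-locus
    assays from ``config.duplications`` are emitted as one extra column named
    by the assay, carrying the genotypes of the assay's first locus; all true
    loci are recorded in the marker metadata (column ``assay`` plus the
    registry returned by :func:`duplication_registry`).
    """
    n = int(n_lines if n_lines is not None else config.line_counts()[0])
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # extend each chromosome's marker list with duplication loci
    dup_rows = []
    for assay, loci in config.duplications:
        if len(loci) < 2:
            raise ConfigError(f"duplicated assay {assay} needs >= 2 loci")
        for j, (chrom, pos) in enumerate(loci):
            dup_rows.append((f"{assay}.L{j + 1}", chrom, float(pos), assay, j == 0))
    dup_df = pd.DataFrame(dup_rows, columns=["marker", "chromosome", "position_cM", "assay", "emitted"])

    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    for chrom, _length in true_map.chromosomes:
        sub = true_map.positions(chrom)
        pos = sub["position_cM"].to_numpy(dtype=float)
        names = sub["marker"].tolist()
        assays = sub["assay"].tolist()
        d_here = dup_df[dup_df["chromosome"] == chrom]
        all_pos = np.concatenate([pos, d_here["position_cM"].to_numpy(dtype=float)])
        all_names = names + d_here["marker"].tolist()
        all_assays = assays + d_here["assay"].tolist()
        emitted = [True] * len(names) + d_here["emitted"].tolist()
        order = np.argsort(all_pos, kind="stable")
        all_pos = all_pos[order]
        all_names = [all_names[i] for i in order]
        all_assays = [all_assays[i] for i in order]
        emitted = [emitted[i] for i in order]
        m = len(all_pos)
        if m == 0:
            continue
        switch_p = _interval_switch_probs(all_pos)
        hap0 = np.zeros((n, m), dtype=np.int8)  # F1: one parent-A haplotype,
        hap1 = np.ones((n, m), dtype=np.int8)   # one parent-B haplotype
        for _gen in range(config.selfing_generation - 1):
            g0 = _gametes(hap0, hap1, switch_p, rng)
            g1 = _gametes(hap0, hap1, switch_p, rng)
            hap0, hap1 = g0, g1
        dosage = hap0 + hap1  # 0 = AA, 2 = BB, 1 = het
        geno = np.full((n, m), H, dtype=np.int8)
        geno[dosage == 0] = A
        geno[dosage == 2] = B
        for j in range(m):
            if not emitted[j]:
                continue
            marker_ids.append(all_names[j])
            columns.append(geno[:, j].copy())
            meta_rows.append((all_names[j], chrom, float(all_pos[j]), all_assays[j]))

    calls = np.stack(columns, axis=0) if columns else np.empty((0, n), dtype=np.int8)

    # duplicated assays report under the assay name, not the locus name
    renamed = []
    for mid in marker_ids:
        meta = dup_df[dup_df["marker"] == mid]
        renamed.append(meta["assay"].iloc[0] if len(meta) else mid)
    marker_ids = renamed
    meta = pd.DataFrame(meta_rows, columns=["marker", "chromosome", "position_cM", "assay"])
    meta["marker"] = marker_ids
    meta = meta.set_index("marker")

    het = calls == H
    if config.residual_het_rate is not None and het.any():
        keep = rng.random(calls.shape) < config.residual_het_rate
        resolve = het & ~keep
        calls[resolve] = rng.integers(0, 2, size=calls.shape, dtype=np.int8)[resolve]
    if config.error_rate > 0:
        flip = (rng.random(calls.shape) < config.error_rate) & np.isin(calls, [A, B])
        calls[flip] = 1 - calls[flip]
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    line_ids = [f"{name}_L{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(marker_ids, line_ids, calls, meta, name=name)


def duplication_registry(true_map: TrueMap, config: SimConfig) -> pd.DataFrame:
    """True loci of every multi-locus assay: assay, locus, chromosome, position."""
    rows = []
    for assay, loci in config.duplications:
        for j, (chrom, pos) in enumerate(loci):
            rows.append((assay, f"{assay}.L{j + 1}", chrom, float(pos)))
    return pd.DataFrame(rows, columns=["assay", "locus", "chromosome", "position_cM"])


def make_panel(true_map: TrueMap, config: SimConfig) -> tuple[list[GenotypeMatrix], pd.DataFrame]:
    """Simulate ``config.n_populations`` populations plus a sharing report.

    Each population genotypes an independent Bernoulli(``population_marker_
    fraction``) subset of the assays.  The report counts assays shared by
    exactly 1..n populations; the counts always partition the union of
    genotyped assays.
    """
    if config.n_populations < 2:
        raise ConfigError("make_panel requires n_populations >= 2")
    if config.population_marker_fraction <= 0:
        raise ConfigError("population_marker_fraction must be > 0 (empty populations)")
    sizes = config.line_counts()
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * config.n_populations)
    pops: list[GenotypeMatrix] = []
    for i in range(config.n_populations):
        full = simulate_population(
            true_map, config, n_lines=sizes[i],
            seed=int(seeds[2 * i] % (2**31)), name=f"pop{i + 1}",
        )
        sub_rng = np.random.default_rng(int(seeds[2 * i + 1] % (2**31)))
        keep = sub_rng.random(full.n_markers) < config.population_marker_fraction
        if not keep.any():
            raise ConfigError(f"population {i + 1} received no markers")
        pops.append(full.subset([m for m, k in zip(full.marker_ids, keep) if k]))
    counts: dict[str, int] = {}
    for pop in pops:
        for m in pop.marker_ids:
            counts[m] = counts.get(m, 0) + 1
    n = config.n_populations
    share = pd.DataFrame({
        "n_populations": np.arange(1, n + 1),
        "n_markers": [sum(1 for v in counts.values() if v == k) for k in range(1, n + 1)],
    })
    return pops, share
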