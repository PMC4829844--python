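"""Synthetic-data generators: copy-number specs, binned read counts,
control panels, growth curves and STR fixtures.

The simulator emulates shallow whole-genome sequencing of a tumor
sample: per-bin read counts follow the mixed copy number of tumor and
admixed normal cells, modulated by a smooth unimodal GC bias and
negative-binomial counting noise.  Everything is bit-reproducible given
a seed.

Copy-number presets encode the karyotypes of the MUG-CC1 clival
chordoma cell line, its parental tumor (80% purity) and the balanced
MUG-CC1-LCL lymphoblastoid line, so that the whole pipeline can be
exercised without any external data.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .genome import AUTOSOMES, GenomeModel

# --------------------------------------------------------------------------
# Copy-number specifications
# --------------------------------------------------------------------------

# Fraction-of-arm lookup for cytoband labels, measured from the
# centromere outward on either arm.  This is a documented package
# convention for turning band names into coordinates on the simulated
# genome, not a claim about hg19 band boundaries: band group 1 spans
# [0, 0.10] of the arm (five sub-bands of 0.02), group 2 spans
# [0.10, 0.55] (bands 21-24 at 0.0875 each, band 25 the remainder),
# group 3 spans [0.55, 1.0] (six sub-bands of 0.075).
_BAND_FRACTIONS: dict[int, tuple[float, float]] = {}
for _i, _band in enumerate(range(11, 16)):
    _BAND_FRACTIONS[_band] = (0.02 * _i, 0.02 * (_i + 1))
for _i, _band in enumerate(range(21, 25)):
    _BAND_FRACTIONS[_band] = (0.10 + 0.0875 * _i, 0.10 + 0.0875 * (_i + 1))
_BAND_FRACTIONS[25] = (0.45, 0.55)
for _i, _band in enumerate(range(31, 37)):
    _BAND_FRACTIONS[_band] = (0.55 + 0.075 * _i, 0.55 + 0.075 * (_i + 1))

_BAND_RE = re.compile(r"^([0-9XY]+)([pq])(\d+)$")


@dataclasses.dataclass(frozen=True)
class CNASpec:
    """Ordered list of copy-number events over a diploid background.

    Each event is ``(region, copy_number)`` where region is a whole
    chromosome (``"7"``), an arm (``"9p"``), or a cytoband interval
    (``"1q21-1q24"``).  Later events override earlier ones where they
    overlap.  The background is CN 2 on autosomes and sex-appropriate
    on X/Y (``"XY"``: one copy each; ``"XX"``: two X, zero Y).
    """

    events: tuple[tuple[str, int], ...] = ()
    sex: str = "XY"

    def __post_init__(self):
        if self.sex not in ("XY", "XX"):
            raise ConfigError(f"sex must be 'XY' or 'XX', got {self.sex!r}")
        for region, cn in self.events:
            if not (isinstance(cn, (int, np.integer)) and cn >= 0):
                raise ConfigError(f"copy number for {region!r} must be a non-negative integer")

    def baseline(self, genome: GenomeModel) -> np.ndarray:
        """Per-bin copy number of a normal cell of this sex."""
        cn = np.full(genome.n_bins, 2.0)
        x = genome.chrom_bins("X")
        y = genome.chrom_bins("Y")
        if self.sex == "XY":
            cn[x] = 1.0
            cn[y] = 1.0
        else:
            cn[y] = 0.0
        return cn

    def resolve(self, genome: GenomeModel) -> np.ndarray:
        """Per-bin integer copy number after applying all events in order."""
        cn = self.baseline(genome)
        for region, copy_number in self.events:
            idx = resolve_region(region, genome)
            if len(idx) == 0:
                raise DataError(f"region {region!r} resolves to no bins")
            cn[idx] = float(copy_number)
        return cn


def resolve_region(region: str, genome: GenomeModel) -> np.ndarray:
    """Bin indices covered by a region label.

    Accepts a chromosome name (``"7"``, ``"X"``), an arm (``"9p"``) or a
    band interval (``"1q21-1q24"``, ``"Xp11-Xp22"``).
    """
    region = region.strip()
    if region in genome.chrom_names:
        return genome.chrom_bins(region)
    m = re.match(r"^([0-9XY]+)([pq])$", region)
    if m:
        chrom, arm = m.groups()
        if chrom not in genome.chrom_names:
            raise DataError(f"unknown chromosome in region {region!r}")
        return genome.arm_bins(chrom, arm)
    if "-" in region:
        left, right = region.split("-", 1)
        m1 = _BAND_RE.match(left.strip())
        m2 = _BAND_RE.match(right.strip())
        if m1 and m2:
            chrom, arm, b1 = m1.group(1), m1.group(2), int(m1.group(3))
            chrom2, arm2, b2 = m2.group(1), m2.group(2), int(m2.group(3))
            if chrom2 not in ("", chrom) or arm2 != arm:
                raise DataError(f"band interval {region!r} must stay on one arm")
            return _band_interval_bins(chrom, arm, b1, b2, genome)
    raise DataError(f"cannot parse region {region!r}")


def _band_interval_bins(
    chrom: str, arm: str, band_lo: int, band_hi: int, genome: GenomeModel
) -> np.ndarray:
    if band_lo > band_hi:
        band_lo, band_hi = band_hi, band_lo
    for b in (band_lo, band_hi):
        if b not in _BAND_FRACTIONS:
            raise DataError(f"band {arm}{b} not in the band lookup")
    f0 = _BAND_FRACTIONS[band_lo][0]
    f1 = _BAND_FRACTIONS[band_hi][1]
    c = genome.chromosome(chrom)
    if arm == "q":
        arm_start, arm_len = c.centromere, c.length - c.centromere
        lo = arm_start + f0 * arm_len
        hi = arm_start + f1 * arm_len
    else:
        # p-arm bands are numbered from the centromere toward the telomere,
        # i.e. against genomic coordinates
        arm_len = c.centromere
        lo = c.centromere - f1 * arm_len
        hi = c.centromere - f0 * arm_len
    b = genome.bins
    sel = (
        (b["chrom"].to_numpy() == chrom)
        & (b["start"].to_numpy() < hi)
        & (b["end"].to_numpy() > lo)
    )
    return np.flatnonzero(sel)


def mug_cc1_spec() -> CNASpec:
    """Karyotype of the MUG-CC1 cell line.

    Whole-chromosome gains of 7, 8, 12, 13, 16, 18 and 20; arm gains of
    1q and 6q shared with the parental tumor; losses of 3, 9p, 10, 14
    and 21; focal high-level (CN 4) gains at 1q21-1q24, 17q21-17q25 and
    Xp11-Xp22; gain of X to two copies and complete loss of Y in a male
    background.
    """
    events = (
        ("1q", 3), ("6q", 3),
        ("3", 1), ("9p", 1), ("10", 1), ("14", 1), ("21", 1),
        ("7", 3), ("8", 3), ("12", 3), ("13", 3), ("16", 3), ("18", 3), ("20", 3),
        ("1q21-1q24", 4), ("17q21-17q25", 4),
        ("X", 2), ("Xp11-Xp22", 4),
        ("Y", 0),
    )
    return CNASpec(events=events, sex="XY")


def primary_tumor_spec() -> tuple[CNASpec, float]:
    """Karyotype of the parental clival tumor and its purity (0.8).

    Gains of 1q and 6q, losses of 3, 9p, 10, 14 and 21, diluted by
    roughly 20% non-neoplastic cells.
    """
    events = (
        ("1q", 3), ("6q", 3),
        ("3", 1), ("9p", 1), ("10", 1), ("14", 1), ("21", 1),
    )
    return CNASpec(events=events, sex="XY"), 0.8


def balanced_spec(sex: str = "XY") -> CNASpec:
    """Copy-number-balanced karyotype (the lymphoblastoid line, controls)."""
    return CNASpec(events=(), sex=sex)


# --------------------------------------------------------------------------
# Binned read counts
# --------------------------------------------------------------------------


@dataclasses.dataclass
class BinnedCounts:
    """Raw per-bin read counts of one sample, in genome order."""

    sample_id: str
    counts: np.ndarray
    total_reads: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise DataError("negative bin count")
        if int(self.counts.sum()) > self.total_reads:
            raise DataError("sum of bin counts exceeds total_reads")


@dataclasses.dataclass
class ControlPanel:
    """Copy-number-balanced control samples sharing one genome model."""

    samples: list[BinnedCounts]

    def __post_init__(self):
        if len(self.samples) < 2:
            raise ConfigError("control panel needs at least 2 samples")
        n = {len(s.counts) for s in self.samples}
        if len(n) != 1:
            raise DataError("control samples disagree on bin count")

    @property
    def size(self) -> int:
        return len(self.samples)

    def count_matrix(self) -> np.ndarray:
        """(n_samples, n_bins) integer matrix."""
        return np.stack([s.counts for s in self.samples])


@dataclasses.dataclass(frozen=True)
class GCBias:
    """Unimodal quadratic coverage bias g(gc) = 1 - amplitude/span^2 * (gc-peak)^2.

    ``amplitude`` is the fractional coverage drop at ``span`` GC units
    from the peak (default: 30% at 0.25 from the 0.45 peak).
    """

    peak: float = 0.45
    amplitude: float = 0.30
    span: float = 0.25
    floor: float = 0.05

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        g = 1.0 - self.amplitude / self.span**2 * (np.asarray(gc) - self.peak) ** 2
        return np.maximum(g, self.floor)


DEFAULT_TOTAL_READS = 2_000_000
DEFAULT_DISPERSION = 0.05


def expected_rates(
    genome: GenomeModel,
    cna_spec: CNASpec,
    purity: float = 1.0,
    gc_bias: GCBias | None = None,
) -> np.ndarray:
    """Expected per-bin read fractions (sum to 1 over unmasked bins).

    The rate of bin *i* is proportional to the purity-mixed copy number
    ``purity*CN_i + (1-purity)*CN_normal_i`` times the GC bias at the
    bin's GC fraction; PAR-masked bins have rate 0.
    """
    if not (0.0 < purity <= 1.0):
        raise ConfigError(f"purity must be in (0, 1], got {purity}")
    gc_bias = gc_bias or GCBias()
    cn_tumor = cna_spec.resolve(genome)
    cn_normal = cna_spec.baseline(genome)
    cn_mix = purity * cn_tumor + (1.0 - purity) * cn_normal
    rate = cn_mix * gc_bias(genome.bins["gc"].to_numpy())
    rate[genome.par_mask] = 0.0
    total = rate.sum()
    if total <= 0:
        raise DataError("all expected rates are zero")
    return rate / total


def simulate_sample(
    genome: GenomeModel,
    cna_spec: CNASpec,
    purity: float = 1.0,
    total_reads: int = DEFAULT_TOTAL_READS,
    dispersion: float = DEFAULT_DISPERSION,
    gc_bias: GCBias | None = None,
    seed: int | np.random.SeedSequence = 0,
    sample_id: str = "sample",
) -> BinnedCounts:
    """Draw per-bin read counts for one sample.

    Counts are negative-binomial with mean ``total_reads * rate_i`` and
    variance ``mean * (1 + dispersion)`` (Poisson when dispersion is 0).
    PAR-masked bins receive zero counts.  Deterministic given the seed.
    """
    if total_reads <= 0:
        raise ConfigError("total_reads must be positive")
    if dispersion < 0:
        raise ConfigError("dispersion must be non-negative")
    rate = expected_rates(genome, cna_spec, purity, gc_bias)
    mu = total_reads * rate
    rng = np.random.default_rng(seed)
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        # var = mu*(1+d)  <=>  NB(size=mu/d, p=1/(1+d))
        counts = np.zeros_like(mu, dtype=np.int64)
        pos = mu > 0
        counts[pos] = rng.negative_binomial(mu[pos] / dispersion, 1.0 / (1.0 + dispersion))
    counts = counts.astype(np.int64)
    return BinnedCounts(sample_id=sample_id, counts=counts, total_reads=int(counts.sum()))


def simulate_control_panel(
    genome: GenomeModel,
    n: int = 30,
    total_reads: int = DEFAULT_TOTAL_READS,
    dispersion: float = DEFAULT_DISPERSION,
    gc_bias: GCBias | None = None,
    seed: int | np.random.SeedSequence = 0,
    sex: str = "XY",
) -> ControlPanel:
    """Simulate ``n`` balanced, sex-matched control samples.

    Per-sample seeds are spawned from the panel seed, so the panel is
    reproducible as a whole and each sample individually.
    """
    if n < 2:
        raise ConfigError("control panel needs n >= 2")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    spec = balanced_spec(sex)
    samples = [
        simulate_sample(
            genome, spec, 1.0, total_reads, dispersion, gc_bias,
            seed=child, sample_id=f"control_{k:02d}",
        )
        for k, child in enumerate(ss.spawn(n))
    ]
    return ControlPanel(samples=samples)


# --------------------------------------------------------------------------
# Growth curves
# --------------------------------------------------------------------------


@dataclasses.dataclass
class GrowthCurve:
    """Impedance-style proliferation record: hours vs dimensionless cell index."""

    times: np.ndarray
    cell_index: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cell_index = np.asarray(self.cell_index, dtype=float)
        if len(self.times) != len(self.cell_index):
            raise DataError("times and cell_index lengths differ")
        if len(self.times) < 3:
            raise DataError("growth curve needs at least 3 points")
        if (np.diff(self.times) <= 0).any():
            raise DataError("times must be strictly increasing")
        if (self.cell_index < 0).any():
            raise DataError("cell index must be non-negative")


def simulate_growth_curve(
    doubling_time_hours: float,
    ci0: float = 1.0,
    duration_hours: float = 171.0,
    interval_minutes: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> GrowthCurve:
    """Exponential growth with multiplicative log-normal noise.

    ``cell_index(t) = ci0 * 2**(t / DT) * exp(eps_t)`` with
    ``eps_t ~ N(0, noise_sd^2)``.  Defaults mirror a 171 h run sampled
    every 20 minutes (514 points).
    """
    if doubling_time_hours <= 0:
        raise ConfigError("doubling time must be positive")
    if ci0 <= 0:
        raise ConfigError("initial cell index must be positive")
    step = interval_minutes / 60.0
    n = int(np.floor(duration_hours / step + 1e-9)) + 1
    times = np.arange(n) * step
    ci = ci0 * np.exp2(times / doubling_time_hours)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ci = ci * np.exp(rng.normal(0.0, noise_sd, size=n))
    return GrowthCurve(times=times, cell_index=ci)


# --------------------------------------------------------------------------
# STR fixtures
# --------------------------------------------------------------------------

# PowerPlex-16 profiles of the parental tumor, MUG-CC1 and MUG-CC1-LCL,
# in Table-1 CSV layout (alleles comma-separated within a cell).
TABLE1_STR_CSV = """\
marker,Tumor Tissue,MUG-CC1,MUG-CC1 LCL
D3S1358,"16,18",16,"16,18"
TH01,9.3,9.3,9.3
D21S11,"28,30",28,"28,30"
D18S51,12,12,12
Penta E,"10,13",10,"10,13"
D5S818,"11,12","11,12","11,12"
D13S317,"12,13","12,13","12,13"
D7S820,"8,11","8,11","8,11"
D16S539,"9,14","9,14","9,14"
CSF1PO,11,11,11
Penta D,"10,13",13,"10,13"
AMEL,"X,Y",X,"X,Y"
vWA,"16,18","16,18","16,18"
D8S1179,"13,15","13,15","13,15"
TPOX,"8,11","8,11","8,11"
FGA,23,23,23
"""


def table1_str_profiles():
    """The three STR profiles (tumor, MUG-CC1, MUG-CC1-LCL)."""
    from .authenticate import parse_str_table

    tumor, cc1, lcl = parse_str_table(TABLE1_STR_CSV)
    return tumor, cc1, lcl


def simulate_str_profile(seed: int = 0, sample_id: str = "random") :
    """An unrelated random profile over the PowerPlex-16 panel.

    Allele repeat numbers are drawn uniformly from marker-typical
    ranges; used as a negative control for authentication.
    """
    from .authenticate import POWERPLEX16_MARKERS, STRProfile

    rng = np.random.default_rng(seed)
    markers = {}
    for marker in POWERPLEX16_MARKERS:
        if marker == "AMEL":
            markers[marker] = frozenset(["X", "Y"] if rng.random() < 0.5 else ["X"])
            continue
        alleles = {str(int(a)) for a in rng.integers(6, 25, size=2)}
        markers[marker] = frozenset(alleles)
    return STRProfile(sample_id=sample_id, markers=markers)
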