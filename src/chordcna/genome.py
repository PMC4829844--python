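"""Binned genome model shared by the simulator and the analysis pipeline.

A :class:`GenomeModel` carries the chromosome table (name, length,
centromere) and a bin table with per-bin GC fraction, arm label and a
PAR (pseudo-autosomal region) mask.  Reads mapping to the PAR are
ambiguous between X and Y, so PAR bins are excluded from coverage-based
copy-number inference throughout.

Two genome scales are provided:

``toy``
    hg19 chromosome lengths divided by 10, 100 kb bins (~3,100 bins).
    Small enough for permutation-based segmentation in seconds; the
    default for tests and worked examples.
``full``
    hg19 lengths, 50 kb bins (~62,000 bins).

GC content is simulated as a spatially autocorrelated series: a
first-order autoregression on a logistic scale squashed into
(0.2, 0.7) with mean ~0.41, which mimics the smooth megabase-scale GC
waves of the human genome without shipping a reference sequence.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

#: hg19 (GRCh37) chromosome lengths in bp.
HG19_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

CHROMOSOMES: tuple[str, ...] = tuple(HG19_LENGTHS)
AUTOSOMES: tuple[str, ...] = CHROMOSOMES[:22]

# PAR intervals at the tips of X and Y, unscaled bp (approximate hg19
# extents, applied identically to both sex chromosomes for simplicity).
_PAR1_TIP = 2_700_000   # first bases of the chromosome
_PAR2_TIP = 350_000     # last bases of the chromosome

# Fraction of chromosome length at which the centromere sits in the
# simulated genomes (metacentric-ish stand-in; hg19 band positions are
# deliberately not claimed).
CENTROMERE_FRACTION = 0.4


@dataclasses.dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int


@dataclasses.dataclass(frozen=True)
class GenomeModel:
    """Immutable binned genome.

    Attributes
    ----------
    chromosomes:
        Ordered chromosome records (name, length, centromere position).
    bin_size:
        Nominal bin width in bp (the last bin of a chromosome may be
        shorter).
    bins:
        DataFrame with columns ``chrom, start, end, gc, par_masked, arm``
        in genome order, 0-based half-open coordinates.
    """

    chromosomes: tuple[Chromosome, ...]
    bin_size: int
    bins: pd.DataFrame

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise DataError(f"unknown chromosome {name!r}")

    def chrom_bins(self, name: str) -> np.ndarray:
        """Indices (into the bin table) of the bins of one chromosome."""
        return np.flatnonzero(self.bins["chrom"].to_numpy() == name)

    def arm_bins(self, name: str, arm: str) -> np.ndarray:
        sel = (self.bins["chrom"].to_numpy() == name) & (
            self.bins["arm"].to_numpy() == arm
        )
        return np.flatnonzero(sel)

    @property
    def par_mask(self) -> np.ndarray:
        """Boolean array, True on PAR-masked bins."""
        return self.bins["par_masked"].to_numpy()

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        self.bins.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, bin_size: int | None = None) -> "GenomeModel":
        bins = pd.read_csv(path, dtype={"chrom": str})
        required = {"chrom", "start", "end", "gc", "par_masked", "arm"}
        missing = required - set(bins.columns)
        if missing:
            raise DataError(f"genome CSV missing columns: {sorted(missing)}")
        bins["par_masked"] = bins["par_masked"].astype(bool)
        chroms = []
        for name, grp in bins.groupby("chrom", sort=False):
            length = int(grp["end"].max())
            # centromere = boundary between p and q bins
            q = grp[grp["arm"] == "q"]
            cen = int(q["start"].min()) if len(q) else length
            chroms.append(Chromosome(str(name), length, cen))
        if bin_size is None:
            bin_size = int((bins["end"] - bins["start"]).max())
        model = cls(tuple(chroms), int(bin_size), bins.reset_index(drop=True))
        _validate(model)
        return model


def _validate(model: GenomeModel) -> None:
    b = model.bins
    if not ((b["gc"] >= 0) & (b["gc"] <= 1)).all():
        raise DataError("gc fraction outside [0, 1]")
    bad_par = b["par_masked"] & ~b["chrom"].isin(["X", "Y"])
    if bad_par.any():
        raise DataError("PAR mask set on a non-sex chromosome")
    for c in model.chromosomes:
        grp = b[b["chrom"] == c.name]
        if not (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]).all():
            raise DataError(f"bins do not tile chromosome {c.name}")


def _simulate_gc(n: int, rng: np.random.Generator) -> np.ndarray:
    """AR(1) on a logistic scale, squashed into (0.2, 0.7), mean ~0.41."""
    phi = 0.9
    mu = -0.322  # logistic-scale mean so that E[gc] ~ 0.41
    sd_stat = 0.8
    z = np.empty(n)
    z[0] = mu + sd_stat * rng.standard_normal()
    innov_sd = sd_stat * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(n - 1) * innov_sd if n > 1 else np.empty(0)
    for i in range(1, n):
        z[i] = mu + phi * (z[i - 1] - mu) + eps[i - 1]
    return 0.2 + 0.5 / (1.0 + np.exp(-z))


def build_genome(
    scale: str = "toy", bin_size: int = 100_000, seed: int = 1
) -> GenomeModel:
    """Construct a binned genome model.

    Parameters
    ----------
    scale:
        ``"toy"`` (hg19 lengths / 10) or ``"full"`` (hg19 lengths).
    bin_size:
        Bin width in bp; must be positive.
    seed:
        Seed for the simulated GC track (deterministic given the seed).
    """
    if bin_size <= 0:
        raise ConfigError(f"bin_size must be positive, got {bin_size}")
    if scale == "toy":
        divisor = 10
    elif scale == "full":
        divisor = 1
    else:
        raise ConfigError(f"unknown genome scale {scale!r}")

    rng = np.random.default_rng(seed)
    chroms: list[Chromosome] = []
    records: list[tuple] = []
    for name in CHROMOSOMES:
        length = HG19_LENGTHS[name] // divisor
        cen = int(length * CENTROMERE_FRACTION)
        chroms.append(Chromosome(name, length, cen))
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        gc = _simulate_gc(len(starts), rng)
        if name in ("X", "Y"):
            par1 = _PAR1_TIP // divisor
            par2_start = length - _PAR2_TIP // divisor
            par = (starts < par1) | (ends > par2_start)
        else:
            par = np.zeros(len(starts), dtype=bool)
        arm = np.where(ends <= cen, "p", "q")
        for s, e, g, p, a in zip(starts, ends, gc, par, arm):
            records.append((name, int(s), int(e), float(g), bool(p), a))

    bins = pd.DataFrame(
        records, columns=["chrom", "start", "end", "gc", "par_masked", "arm"]
    )
    return GenomeModel(tuple(chroms), bin_size, bins)
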