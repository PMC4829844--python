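"""Raw binned counts -> GC-corrected, control-normalized log2 ratios.

The chain mirrors standard shallow-WGS copy-number practice:

1. count aligned fragments per fixed genomic window (:func:`bin_counts`),
2. divide by the total read count (:func:`total_normalize`),
3. divide out the smooth GC-content bias with a LOWESS fit of rate vs
   GC (:func:`gc_correct`),
4. divide by the median profile of a panel of copy-number-balanced
   controls processed identically (:func:`build_reference`), and
5. take log2, anchoring the modal (diploid) state at zero by median
   centering (:func:`log2_ratio_profile`).

Masking is monotone: a bin masked at any stage (PAR, zero-coverage
reference, non-positive LOWESS fit) stays masked downstream.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DataError
from .genome import GenomeModel
from .simulate import BinnedCounts, ControlPanel

#: Guard added to corrected rates before taking log2 of a ratio.
LOG2_EPSILON = 1e-9


@dataclasses.dataclass
class CorrectedCounts:
    """GC-corrected normalized rates for one sample (mean 1 over usable bins)."""

    sample_id: str
    rates: np.ndarray
    mask: np.ndarray  # True = usable


@dataclasses.dataclass
class NormalizedProfile:
    """Per-bin log2 ratios of a sample against the control reference."""

    sample_id: str
    log2: np.ndarray
    mask: np.ndarray  # True = usable
    genome: GenomeModel

    def to_frame(self) -> pd.DataFrame:
        bins = self.genome.bins
        return pd.DataFrame({
            "chrom": bins["chrom"], "start": bins["start"], "end": bins["end"],
            "log2_ratio": np.where(self.mask, self.log2, np.nan),
            "masked": ~self.mask,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, genome: GenomeModel, sample_id: str = "sample"):
        df = pd.read_csv(path, dtype={"chrom": str})
        required = {"chrom", "start", "end", "log2_ratio", "masked"}
        if required - set(df.columns):
            raise DataError(f"profile CSV missing columns: {sorted(required - set(df.columns))}")
        if len(df) != genome.n_bins:
            raise DataError("profile CSV does not match the genome's bin count")
        mask = ~df["masked"].astype(bool).to_numpy()
        log2 = df["log2_ratio"].to_numpy(dtype=float)
        log2 = np.where(mask, log2, 0.0)
        return cls(sample_id=sample_id, log2=log2, mask=mask, genome=genome)

    def to_bedgraph(self, path) -> None:
        frame = self.to_frame()
        frame = frame[~frame["masked"]]
        with open(path, "w") as fh:
            fh.write('track type=bedGraph name="log2_ratio"\n')
            for row in frame.itertuples(index=False):
                fh.write(f"chr{row.chrom}\t{row.start}\t{row.end}\t{row.log2_ratio:.6f}\n")


# --------------------------------------------------------------------------


def bin_counts(fragments, genome: GenomeModel, sample_id: str = "sample"):
    """Count aligned-fragment start positions per genome bin.

    Parameters
    ----------
    fragments:
        Path to a BED file (chrom, start, end per line, tab- or
        whitespace-separated; "chr" prefixes tolerated) or a DataFrame
        with ``chrom``/``start`` columns.  Each fragment is assigned to
        the bin containing its 0-based start (half-open bins, so a
        start on a boundary goes to the right-hand bin).

    Returns
    -------
    (BinnedCounts, n_skipped):
        Fragments on chromosomes absent from the genome (or inside a
        PAR mask) are skipped and counted.
    """
    if isinstance(fragments, pd.DataFrame):
        df = fragments
        if "chrom" not in df.columns or "start" not in df.columns:
            raise DataError("fragment DataFrame needs 'chrom' and 'start' columns")
        chroms = df["chrom"].astype(str).to_numpy()
        starts = df["start"].to_numpy(dtype=np.int64)
    else:
        chroms, starts = _read_bed(fragments)
    if len(chroms) == 0:
        raise DataError("no fragments in input")

    chroms = np.char.replace(chroms.astype(str), "chr", "")
    counts = np.zeros(genome.n_bins, dtype=np.int64)
    n_skipped = 0
    bin_size = genome.bin_size
    offsets = {}
    pos = 0
    nbins_per = {}
    for c in genome.chromosomes:
        offsets[c.name] = pos
        nb = len(genome.chrom_bins(c.name))
        nbins_per[c.name] = nb
        pos += nb
    for name in np.unique(chroms):
        sel = chroms == name
        if name not in offsets:
            n_skipped += int(sel.sum())
            continue
        idx = starts[sel] // bin_size
        ok = (starts[sel] >= 0) & (idx < nbins_per[name])
        n_skipped += int((~ok).sum())
        np.add.at(counts, offsets[name] + idx[ok], 1)
    # reads on the PAR-masked genome cannot land in the PAR
    par = genome.par_mask
    n_skipped += int(counts[par].sum())
    counts[par] = 0
    return (
        BinnedCounts(sample_id=sample_id, counts=counts, total_reads=len(chroms)),
        n_skipped,
    )


def _read_bed(path) -> tuple[np.ndarray, np.ndarray]:
    chroms, starts = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise DataError(f"malformed BED line {lineno}: expected >= 3 fields")
            try:
                start = int(fields[1])
                int(fields[2])
            except ValueError as exc:
                raise DataError(f"malformed BED line {lineno}: {exc}") from exc
            chroms.append(fields[0])
            starts.append(start)
    return np.asarray(chroms), np.asarray(starts, dtype=np.int64)


def total_normalize(counts, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-bin read fractions: count / total over unmasked bins.

    Masked bins are excluded from the denominator and get rate 0.
    """
    c = counts.counts if isinstance(counts, BinnedCounts) else np.asarray(counts, dtype=float)
    c = c.astype(float)
    if mask is None:
        mask = np.ones(len(c), dtype=bool)
    total = c[mask].sum()
    if total <= 0:
        raise DataError("all-zero counts: cannot normalize")
    rates = np.zeros_like(c)
    rates[mask] = c[mask] / total
    return rates


def gc_correct(
    rates: np.ndarray,
    gc: np.ndarray,
    mask: np.ndarray | None = None,
    lowess_fraction: float = 0.3,
    sample_id: str = "sample",
) -> CorrectedCounts:
    """Divide out the GC-content bias with a LOWESS fit of rate vs GC.

    A LOWESS curve f(gc) is fit to (gc_i, rate_i) over unmasked bins
    (one robustifying iteration); corrected rates are rate_i / f(gc_i),
    rescaled to mean 1 over the usable bins.  Bins where the fitted
    value is non-positive are masked.
    """
    if not (0.0 < lowess_fraction <= 1.0):
        raise DataError(f"lowess_fraction must be in (0, 1], got {lowess_fraction}")
    rates = np.asarray(rates, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if len(rates) != len(gc):
        raise DataError("rates and gc are not aligned")
    if mask is None:
        mask = np.ones(len(rates), dtype=bool)
    mask = mask.copy()
    if np.ptp(gc[mask]) == 0:
        warnings.warn("degenerate GC track (all identical); correction is a global rescale")
        fitted = np.full(len(rates), rates[mask].mean())
    else:
        smoothed = lowess(
            rates[mask], gc[mask], frac=lowess_fraction, it=1,
            return_sorted=True, delta=0.001 * np.ptp(gc[mask]),
        )
        fitted = np.interp(gc, smoothed[:, 0], smoothed[:, 1])
    corrected = np.zeros(len(rates))
    good = mask & (fitted > 0)
    corrected[good] = rates[good] / fitted[good]
    mask &= fitted > 0
    mean = corrected[mask].mean()
    if mean <= 0:
        raise DataError("GC correction produced a non-positive mean rate")
    corrected[mask] /= mean
    corrected[~mask] = 0.0
    return CorrectedCounts(sample_id=sample_id, rates=corrected, mask=mask)


def correct_sample(
    counts: BinnedCounts, genome: GenomeModel, lowess_fraction: float = 0.3
) -> CorrectedCounts:
    """total_normalize + gc_correct for one sample on a genome model."""
    mask = ~genome.par_mask
    rates = total_normalize(counts, mask)
    return gc_correct(
        rates, genome.bins["gc"].to_numpy(), mask, lowess_fraction,
        sample_id=counts.sample_id,
    )


def correct_panel(
    panel: ControlPanel, genome: GenomeModel, lowess_fraction: float = 0.3
) -> list[CorrectedCounts]:
    """GC-correct every control sample individually."""
    return [correct_sample(s, genome, lowess_fraction) for s in panel.samples]


def build_reference(
    panel: ControlPanel,
    genome: GenomeModel,
    lowess_fraction: float = 0.3,
    max_zero_fraction: float = 0.10,
    corrected: list[CorrectedCounts] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Median per-bin reference over the GC-corrected control panel.

    Returns ``(reference, mask)``.  A bin is masked when the median
    reference is non-positive or when more than ``max_zero_fraction``
    of the controls have zero raw counts there (unstable bins).
    """
    if panel.size < 2:
        raise DataError("control panel needs at least 2 samples")
    if corrected is None:
        corrected = correct_panel(panel, genome, lowess_fraction)
    rates = np.stack([c.rates for c in corrected])
    masks = np.stack([c.mask for c in corrected])
    mask = masks.all(axis=0)
    reference = np.median(rates, axis=0)
    zero_frac = (panel.count_matrix() == 0).mean(axis=0)
    mask &= reference > 0
    mask &= zero_frac <= max_zero_fraction
    reference[~mask] = 0.0
    return reference, mask


def log2_ratio_profile(
    sample: CorrectedCounts,
    reference: np.ndarray,
    reference_mask: np.ndarray,
    genome: GenomeModel,
    center: bool = True,
) -> NormalizedProfile:
    """log2 of sample vs reference corrected rates.

    With ``center=True`` (default) the profile is median-centered so the
    modal copy-number state sits at log2 = 0 — this undoes the global
    shift that total-read normalization imposes on heavily aberrant
    genomes, restoring single-copy-gain amplitude ~0.585 at purity 1.
    """
    if len(sample.rates) != genome.n_bins or len(reference) != genome.n_bins:
        raise DataError("sample/reference do not match the genome's bin count")
    mask = sample.mask & reference_mask
    log2 = np.zeros(genome.n_bins)
    with np.errstate(divide="ignore"):
        log2[mask] = np.log2((sample.rates[mask] + LOG2_EPSILON) / reference[mask])
    if center and mask.any():
        log2[mask] -= np.median(log2[mask])
    return NormalizedProfile(
        sample_id=sample.sample_id, log2=log2, mask=mask, genome=genome
    )


def normalize_sample(
    counts: BinnedCounts,
    panel: ControlPanel,
    genome: GenomeModel,
    lowess_fraction: float = 0.3,
    center: bool = True,
    reference: tuple[np.ndarray, np.ndarray] | None = None,
) -> NormalizedProfile:
    """Full chain: total normalize, GC-correct, divide by panel reference.

    ``reference`` may carry a precomputed ``(reference, mask)`` pair so
    the panel is processed once when normalizing many samples.
    """
    if reference is None:
        reference = build_reference(panel, genome, lowess_fraction)
    ref, ref_mask = reference
    corrected = correct_sample(counts, genome, lowess_fraction)
    return log2_ratio_profile(corrected, ref, ref_mask, genome, center=center)
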