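"""Circular binary segmentation (CBS) with a permutation test, segment
pruning, and control-panel z-scores.

CBS treats the bins of a chromosome as a circle and recursively looks
for the arc whose mean differs most from the rest, measured by the
two-sample pooled-variance t statistic.  Because the statistic is
symmetric under complementation, scanning every contiguous arc (i, j]
covers all circular splits.  Significance of the best arc is assessed
by permuting the bin values within the segment; a significant arc
splits the segment into two or three pieces which are then segmented
recursively.

The permutation loop is vectorized over permutations and terminates
early once enough permuted maxima exceed the observed statistic for
significance to be impossible — the accept/reject decision is identical
to running all ``nperm`` permutations.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .genome import GenomeModel
from .normalize import CorrectedCounts, NormalizedProfile

_PERM_BLOCK = 250  # permutations drawn per early-termination block


@dataclasses.dataclass
class Segment:
    """A run of bins with (putatively) constant copy number."""

    chrom: str
    start: int           # bp, half-open
    end: int
    bin_start: int       # global bin indices, half-open
    bin_end: int
    mean: float          # mean log2 ratio over member (unmasked) bins
    n_bins: int          # unmasked bins in the segment
    z_score: float | None = None
    z_undefined: bool = False
    status: str = "unset"


@dataclasses.dataclass
class SegmentSet:
    """Ordered segments covering all unmasked bins of a profile."""

    sample_id: str
    segments: list[Segment]
    params: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.segments])

    # ------------------------------------------------------------------ SEG
    def to_seg(self, path) -> None:
        """Write SEG format (1-based inclusive starts, viewer convention)."""
        with open(path, "w") as fh:
            fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
            for s in self.segments:
                fh.write(
                    f"{self.sample_id}\t{s.chrom}\t{s.start + 1}\t{s.end}\t"
                    f"{s.n_bins}\t{s.mean:.6f}\n"
                )

    @classmethod
    def from_seg(cls, path, genome: GenomeModel | None = None) -> "SegmentSet":
        segments = []
        sample_id = "sample"
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("ID\t"):
                raise DataError("SEG file line 1: missing header")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 6:
                    raise DataError(f"SEG file line {lineno}: expected 6 fields")
                try:
                    sample_id = fields[0]
                    chrom = fields[1]
                    start = int(fields[2]) - 1  # back to half-open
                    end = int(fields[3])
                    n_bins = int(fields[4])
                    mean = float(fields[5])
                except ValueError as exc:
                    raise DataError(f"SEG file line {lineno}: {exc}") from exc
                bin_start = bin_end = -1
                if genome is not None:
                    idx = genome.chrom_bins(chrom)
                    starts = genome.bins["start"].to_numpy()[idx]
                    ends = genome.bins["end"].to_numpy()[idx]
                    inside = np.flatnonzero((starts >= start) & (ends <= end))
                    if len(inside):
                        bin_start = int(idx[inside[0]])
                        bin_end = int(idx[inside[-1]]) + 1
                segments.append(Segment(chrom, start, end, bin_start, bin_end,
                                        mean, n_bins))
        return cls(sample_id=sample_id, segments=segments, params={})

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "sample_id", self.sample_id)
        df.to_csv(path, index=False, float_format="%.6f")


# --------------------------------------------------------------------------
# The arc scan
# --------------------------------------------------------------------------


def _arc_stats(x: np.ndarray, min_width: int):
    """t² for every valid circular arc of ``x``.

    Returns (list over k of t² arrays indexed by arc start i, list of
    boolean validity masks).  An arc (i, i+k] is valid when both it and
    its complement have at least ``min_width`` bins and neither edge
    piece of the induced 2/3-way split falls below ``min_width``.
    """
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    sq = float(np.sum(x * x))
    t2_by_k, valid_by_k = [], []
    for k in range(1, n):
        i = np.arange(n - k + 1)
        j = i + k
        valid = np.ones(n - k + 1, dtype=bool)
        if k < min_width or n - k < min_width:
            valid[:] = False
        # edge pieces of the split must respect min_width (or be empty)
        valid &= (i == 0) | (i >= min_width)
        valid &= (j == n) | (n - j >= min_width)
        sums = S[k:] - S[:-k]
        mean_arc = sums / k
        mean_rest = (total - sums) / (n - k)
        ssw = sq - k * mean_arc**2 - (n - k) * mean_rest**2
        ssw = np.maximum(ssw, 0.0)
        diff2 = (mean_arc - mean_rest) ** 2
        denom = ssw / max(n - 2, 1) * (1.0 / k + 1.0 / (n - k))
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = diff2 / denom
        t2 = np.where(denom > 0, t2, np.where(diff2 > 0, np.inf, 0.0))
        t2_by_k.append(t2)
        valid_by_k.append(valid)
    return t2_by_k, valid_by_k


def best_split(x: np.ndarray, min_width: int = 3):
    """Argmax arc of the t² scan: returns ``(t2_max, i, j)`` or ``None``.

    Ties are broken toward the lexicographically smallest ``(i, j)``.
    """
    n = len(x)
    if n < 2 * min_width:
        return None
    t2_by_k, valid_by_k = _arc_stats(np.asarray(x, dtype=float), min_width)
    best = None  # (t2, i, j)
    for k0, (t2, valid) in enumerate(zip(t2_by_k, valid_by_k)):
        k = k0 + 1
        vals = np.where(valid, t2, -np.inf)
        if not np.isfinite(vals).any() and not np.isposinf(vals).any():
            continue
        i = int(np.argmax(vals))
        v = vals[i]
        if v == -np.inf:
            continue
        cand = (float(v), i, i + k)
        if best is None or cand[0] > best[0] or (
            cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2])
        ):
            best = cand
    if best is not None and best[2] == n and best[1] > 0:
        # the arc (i, n) and its complement (0, i) describe the same
        # partition; canonicalize to the lexicographically smaller one
        # so float noise between the two arithmetic paths cannot flip
        # the tie-break
        best = (best[0], 0, best[1])
    return best


def _perm_max_t2(
    x: np.ndarray, min_width: int, obs_t2: float,
    rng: np.random.Generator, nperm: int, alpha: float,
) -> float:
    """Permutation p-value of the observed max t², with early stop.

    Processes permutations in blocks; stops once the exceedance count
    reaches ``alpha * nperm`` (significance then impossible).
    """
    n = len(x)
    stop_at = alpha * nperm
    exceed = 0
    done = 0
    # precompute validity masks once (shared by all permutations)
    _, valid_by_k = _arc_stats(x, min_width)
    sq = float(np.sum(x * x))
    total = float(np.sum(x))
    while done < nperm:
        b = min(_PERM_BLOCK, nperm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, n)), axis=1)
        C = np.concatenate([np.zeros((b, 1)), np.cumsum(perms, axis=1)], axis=1)
        running = np.full(b, -np.inf)
        for k0, valid in enumerate(valid_by_k):
            if not valid.any():
                continue
            k = k0 + 1
            sums = C[:, k:] - C[:, :-k]
            mean_arc = sums / k
            mean_rest = (total - sums) / (n - k)
            ssw = sq - k * mean_arc**2 - (n - k) * mean_rest**2
            np.maximum(ssw, 0.0, out=ssw)
            diff2 = (mean_arc - mean_rest) ** 2
            denom = ssw / max(n - 2, 1) * (1.0 / k + 1.0 / (n - k))
            with np.errstate(divide="ignore", invalid="ignore"):
                t2 = diff2 / denom
            t2 = np.where(denom > 0, t2, np.where(diff2 > 0, np.inf, 0.0))
            t2[:, ~valid] = -np.inf
            running = np.maximum(running, t2.max(axis=1))
        exceed += int((running >= obs_t2).sum())
        done += b
        if exceed >= stop_at:
            return 1.0  # cannot reach significance; report p >= alpha
    return exceed / nperm


def _segment_chromosome(
    x: np.ndarray, alpha: float, nperm: int, min_width: int,
    seed: int, chrom_index: int,
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's unmasked values.

    Returns half-open index intervals into ``x``.
    """
    out: list[tuple[int, int]] = []
    stack = [(0, len(x), 0)]  # (lo, hi, depth); LIFO keeps genome order via sort later
    while stack:
        lo, hi, depth = stack.pop()
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * min_width or np.ptp(seg) == 0:
            out.append((lo, hi))
            continue
        found = best_split(seg, min_width)
        if found is None or found[0] <= 0:
            out.append((lo, hi))
            continue
        t2, i, j = found
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(chrom_index, depth, lo))
        )
        p = _perm_max_t2(seg, min_width, t2, rng, nperm, alpha)
        if p < alpha:
            pieces = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
            for piece in pieces:
                if piece[1] > piece[0]:
                    stack.append((*piece, depth + 1))
        else:
            out.append((lo, hi))
    return sorted(out)


def cbs_segment(
    profile: NormalizedProfile,
    alpha: float = 0.01,
    nperm: int = 1000,
    min_width: int = 3,
    seed: int = 0,
) -> SegmentSet:
    """Segment a log2-ratio profile chromosome by chromosome.

    Deterministic given the seed: each (chromosome, recursion depth,
    offset) gets its own permutation stream, so results do not depend
    on processing order.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    if nperm < 100:
        raise ConfigError(f"nperm must be >= 100, got {nperm}")
    if min_width < 1:
        raise ConfigError("min_width must be >= 1")
    genome = profile.genome
    starts = genome.bins["start"].to_numpy()
    ends = genome.bins["end"].to_numpy()
    segments: list[Segment] = []
    for ci, chrom in enumerate(genome.chrom_names):
        idx = genome.chrom_bins(chrom)
        unmasked = idx[profile.mask[idx]]
        if len(unmasked) == 0:
            warnings.warn(f"chromosome {chrom} has no unmasked bins; skipped")
            continue
        x = profile.log2[unmasked]
        for lo, hi in _segment_chromosome(x, alpha, nperm, min_width, seed, ci):
            bins = unmasked[lo:hi]
            segments.append(Segment(
                chrom=chrom,
                start=int(starts[bins[0]]),
                end=int(ends[bins[-1]]),
                bin_start=int(bins[0]),
                bin_end=int(bins[-1]) + 1,
                mean=float(x[lo:hi].mean()),
                n_bins=hi - lo,
            ))
    return SegmentSet(
        sample_id=profile.sample_id,
        segments=segments,
        params={"alpha": alpha, "nperm": nperm, "min_width": min_width, "seed": seed},
    )


# --------------------------------------------------------------------------
# Pruning
# --------------------------------------------------------------------------


def prune_segments(
    segset: SegmentSet, profile: NormalizedProfile, sd_undo: float = 1.0
) -> SegmentSet:
    """Merge adjacent segments whose means are indistinguishable.

    Adjacent segments (within a chromosome) whose mean log2 difference
    does not exceed ``sd_undo`` robust standard deviations of the
    bin-level residuals (MAD * 1.4826) are merged, smallest difference first,
    iterated to a fixpoint.  ``sd_undo = 0`` is the identity.
    """
    if sd_undo < 0:
        raise ConfigError("sd_undo must be >= 0")
    if sd_undo == 0 or len(segset.segments) < 2:
        return SegmentSet(segset.sample_id, list(segset.segments),
                          {**segset.params, "sd_undo": sd_undo})
    resid = []
    for s in segset.segments:
        bins = _segment_bins(s, profile)
        resid.append(profile.log2[bins] - s.mean)
    resid = np.concatenate(resid)
    sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    threshold = sd_undo * sd

    merged = [dataclasses.replace(s) for s in segset.segments]
    while True:
        diffs = [
            (abs(merged[i + 1].mean - merged[i].mean), i)
            for i in range(len(merged) - 1)
            if merged[i].chrom == merged[i + 1].chrom
        ]
        candidates = [(d, i) for d, i in diffs if d <= threshold]
        if not candidates:
            break
        _, i = min(candidates)
        a, b = merged[i], merged[i + 1]
        bins = np.concatenate([_segment_bins(a, profile), _segment_bins(b, profile)])
        merged[i: i + 2] = [Segment(
            chrom=a.chrom, start=a.start, end=b.end,
            bin_start=a.bin_start, bin_end=b.bin_end,
            mean=float(profile.log2[bins].mean()), n_bins=a.n_bins + b.n_bins,
        )]
    return SegmentSet(segset.sample_id, merged, {**segset.params, "sd_undo": sd_undo})


def _segment_bins(segment: Segment, profile) -> np.ndarray:
    """Global indices of the unmasked bins inside a segment."""
    idx = np.arange(segment.bin_start, segment.bin_end)
    return idx[profile.mask[idx]]


# --------------------------------------------------------------------------
# z-scores
# --------------------------------------------------------------------------


def segment_zscores(
    segset: SegmentSet,
    sample: CorrectedCounts,
    panel_corrected: list[CorrectedCounts],
) -> SegmentSet:
    """Standardize each segment's mean corrected rate against the controls.

    For segment *s*: ``z = (m_s - mean_k c_sk) / sd_k c_sk`` where
    ``m_s`` is the sample's mean GC-corrected rate over the segment's
    bins and ``c_sk`` the same for control *k* (sample SD, n-1).  A
    zero control SD leaves z undefined and flagged.
    """
    if len(panel_corrected) < 2:
        raise DataError("z-scores need a panel of at least 2 controls")
    panel = np.stack([c.rates for c in panel_corrected])
    out = []
    for s in segset.segments:
        idx = np.arange(s.bin_start, s.bin_end)
        idx = idx[sample.mask[idx]]
        if len(idx) == 0:
            out.append(dataclasses.replace(s, z_score=None, z_undefined=True))
            continue
        m_s = float(sample.rates[idx].mean())
        c = panel[:, idx].mean(axis=1)
        sd = float(c.std(ddof=1))
        if sd == 0:
            out.append(dataclasses.replace(s, z_score=None, z_undefined=True))
        else:
            out.append(dataclasses.replace(
                s, z_score=float((m_s - c.mean()) / sd), z_undefined=False
            ))
    return SegmentSet(segset.sample_id, out, dict(segset.params))
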