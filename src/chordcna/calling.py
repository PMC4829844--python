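"""Gain/loss calls, chromosome-level summaries, purity arithmetic and
profile comparison.

Segments are labelled with fixed log2-ratio thresholds: > 0.2 is a
gain, < -0.2 a loss, >= 0.75 a high-level gain (between the
single-copy-gain amplitude log2(3/2) ~ 0.585 and the two-copy-gain
amplitude 1.0 at purity 1).  A chromosome (or arm) is called gained or
lost as a whole when at least 90% of its unmasked bins fall in segments
of that status.  Normal-cell admixture shrinks every amplitude toward
zero: a copy number ``cn`` at purity ``p`` has expected log2 ratio
``log2((p*cn + (1-p)*normal) / normal)``.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .errors import ConfigError, DataError
from .genome import AUTOSOMES, GenomeModel
from .segment import Segment, SegmentSet

GAIN = "gain"
LOSS = "loss"
HIGH_LEVEL_GAIN = "high_level_gain"
BALANCED = "balanced"

_GAINLIKE = (GAIN, HIGH_LEVEL_GAIN)


@dataclasses.dataclass(frozen=True)
class CallThresholds:
    """Log2-ratio thresholds for status assignment."""

    gain: float = 0.2
    loss: float = -0.2
    high_level_gain: float = 0.75
    chromosome_fraction: float = 0.9

    def __post_init__(self):
        if not (self.loss < 0 < self.gain < self.high_level_gain):
            raise ConfigError("thresholds must satisfy loss < 0 < gain < high_level_gain")
        if not (0 < self.chromosome_fraction <= 1):
            raise ConfigError("chromosome_fraction must be in (0, 1]")


@dataclasses.dataclass
class ChromosomeCall:
    chrom: str
    call: str  # whole_gain | whole_loss | arm_gain(p) | arm_gain(q) | arm_loss(p) | arm_loss(q) | mixed | balanced
    gain_fraction: float
    loss_fraction: float


@dataclasses.dataclass
class CNAProfile:
    """Scored, status-labelled segments plus chromosome-level summaries."""

    sample_id: str
    segments: SegmentSet
    chromosome_summary: dict[str, ChromosomeCall] = dataclasses.field(default_factory=dict)
    focal_high_level: list[Segment] = dataclasses.field(default_factory=list)

    def whole_gains(self, autosomes_only: bool = False) -> list[str]:
        out = [c for c, s in self.chromosome_summary.items() if s.call == "whole_gain"]
        if autosomes_only:
            out = [c for c in out if c in AUTOSOMES]
        return out

    def whole_losses(self) -> list[str]:
        return [c for c, s in self.chromosome_summary.items() if s.call == "whole_loss"]

    def arm_events(self) -> list[str]:
        """Arm-level events as "+9q" / "-9p" strings."""
        out = []
        for c, s in self.chromosome_summary.items():
            if s.call.startswith("arm_gain"):
                out.append(f"+{c}{s.call[-2]}")
            elif s.call.startswith("arm_loss"):
                out.append(f"-{c}{s.call[-2]}")
        return out

    def karyotype_summary(self) -> str:
        """One-line summary, e.g. "+7,+8,...,+Xq,-Y"."""
        parts = [f"+{c}" for c in self.whole_gains()]
        parts += [f"-{c}" for c in self.whole_losses()]
        parts += self.arm_events()

        def _key(p):
            chrom = p[1:].rstrip("pq")
            order = {c: i for i, c in enumerate(
                list(AUTOSOMES) + ["X", "Y"])}
            return (order.get(chrom, 99), p)

        return ",".join(sorted(parts, key=_key)) or "balanced"


def call_segments(segset: SegmentSet, thresholds: CallThresholds | None = None) -> CNAProfile:
    """Assign a status to every segment from its mean log2 ratio."""
    thresholds = thresholds or CallThresholds()
    labelled = []
    for s in segset.segments:
        if not np.isfinite(s.mean) and not np.isneginf(s.mean):
            raise DataError(f"segment mean not finite on {s.chrom}")
        if s.mean >= thresholds.high_level_gain:
            status = HIGH_LEVEL_GAIN
        elif s.mean > thresholds.gain:
            status = GAIN
        elif s.mean < thresholds.loss:
            status = LOSS
        else:
            status = BALANCED
        labelled.append(dataclasses.replace(s, status=status))
    out = SegmentSet(segset.sample_id, labelled, dict(segset.params))
    focal = [s for s in labelled if s.status == HIGH_LEVEL_GAIN]
    return CNAProfile(sample_id=segset.sample_id, segments=out, focal_high_level=focal)


def _bin_status(profile: CNAProfile, genome: GenomeModel) -> np.ndarray:
    """Per-bin status array ('gain'/'loss'/'balanced'/'masked')."""
    status = np.full(genome.n_bins, "masked", dtype=object)
    for s in profile.segments.segments:
        label = BALANCED
        if s.status in _GAINLIKE:
            label = GAIN
        elif s.status == LOSS:
            label = LOSS
        status[s.bin_start:s.bin_end] = label
    return status


def chromosome_calls(
    profile: CNAProfile,
    genome: GenomeModel,
    thresholds: CallThresholds | None = None,
) -> dict[str, ChromosomeCall]:
    """Whole-chromosome and arm-level summaries from segment statuses.

    A chromosome is ``whole_gain``/``whole_loss`` when at least
    ``chromosome_fraction`` of its unmasked bins sit in segments of
    that status; otherwise each arm is tested the same way; otherwise
    the chromosome is ``balanced`` (if mostly balanced) or ``mixed``.
    Results are stored on the profile and returned.
    """
    thresholds = thresholds or CallThresholds()
    frac = thresholds.chromosome_fraction
    status = _bin_status(profile, genome)
    summary: dict[str, ChromosomeCall] = {}
    for chrom in genome.chrom_names:
        idx = genome.chrom_bins(chrom)
        covered = idx[status[idx] != "masked"]
        if len(covered) == 0:
            summary[chrom] = ChromosomeCall(chrom, "balanced", 0.0, 0.0)
            continue
        g = float((status[covered] == GAIN).mean())
        l = float((status[covered] == LOSS).mean())
        b = float((status[covered] == BALANCED).mean())
        if g >= frac:
            call = "whole_gain"
        elif l >= frac:
            call = "whole_loss"
        else:
            call = None
            for arm in ("p", "q"):
                arm_idx = genome.arm_bins(chrom, arm)
                arm_cov = arm_idx[status[arm_idx] != "masked"]
                if len(arm_cov) == 0:
                    continue
                if (status[arm_cov] == GAIN).mean() >= frac:
                    call = f"arm_gain({arm})"
                    break
                if (status[arm_cov] == LOSS).mean() >= frac:
                    call = f"arm_loss({arm})"
                    break
            if call is None:
                call = "balanced" if b >= frac else "mixed"
        summary[chrom] = ChromosomeCall(chrom, call, g, l)
    profile.chromosome_summary = summary
    return summary


def expected_log2(cn: int, purity: float, normal_cn: int = 2) -> float:
    """Expected log2 ratio of copy number ``cn`` at a given purity.

    ``log2((purity*cn + (1-purity)*normal_cn) / normal_cn)``.  The
    degenerate case cn = 0 at purity 1 returns ``-inf`` (complete
    absence of material).
    """
    if cn < 0:
        raise ConfigError("copy number must be >= 0")
    if not (0 < purity <= 1):
        raise ConfigError("purity must be in (0, 1]")
    if normal_cn <= 0:
        raise ConfigError("normal copy number must be positive")
    mix = purity * cn + (1 - purity) * normal_cn
    if mix == 0:
        return float("-inf")
    return float(np.log2(mix / normal_cn))


def compare_profiles(a: CNAProfile, b: CNAProfile, genome: GenomeModel) -> dict:
    """Bin-level concordance of two called profiles.

    Returns a report with the status contingency (shared gain/loss,
    private aberrations, shared balanced), the Jaccard index of
    same-direction aberrant bins, and the chromosome-level events
    private to either profile.
    """
    sa = _bin_status(a, genome)
    sb = _bin_status(b, genome)
    both = (sa != "masked") & (sb != "masked")
    sa, sb = sa[both], sb[both]
    shared_gain = int(((sa == GAIN) & (sb == GAIN)).sum())
    shared_loss = int(((sa == LOSS) & (sb == LOSS)).sum())
    shared_balanced = int(((sa == BALANCED) & (sb == BALANCED)).sum())
    aberrant_a = (sa != BALANCED)
    aberrant_b = (sb != BALANCED)
    union = int((aberrant_a | aberrant_b).sum())
    agree = shared_gain + shared_loss
    jaccard = agree / union if union else 1.0
    private_a = int((aberrant_a & ~aberrant_b).sum())
    private_b = int((aberrant_b & ~aberrant_a).sum())

    if not a.chromosome_summary:
        chromosome_calls(a, genome)
    if not b.chromosome_summary:
        chromosome_calls(b, genome)
    events_a = {c: s.call for c, s in a.chromosome_summary.items()
                if s.call not in ("balanced", "mixed")}
    events_b = {c: s.call for c, s in b.chromosome_summary.items()
                if s.call not in ("balanced", "mixed")}
    private_events_a = sorted(
        f"{c}:{v}" for c, v in events_a.items() if events_b.get(c) != v)
    private_events_b = sorted(
        f"{c}:{v}" for c, v in events_b.items() if events_a.get(c) != v)
    return {
        "sample_a": a.sample_id,
        "sample_b": b.sample_id,
        "shared_gain_bins": shared_gain,
        "shared_loss_bins": shared_loss,
        "shared_balanced_bins": shared_balanced,
        "private_to_a_bins": private_a,
        "private_to_b_bins": private_b,
        "jaccard_aberrant": jaccard,
        "private_events_a": private_events_a,
        "private_events_b": private_events_b,
    }


def comparison_to_json(report: dict) -> str:
    return json.dumps(report, indent=2)
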