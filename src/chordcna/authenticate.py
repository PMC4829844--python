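"""STR-profile cell-line authentication.

Compares PowerPlex-16 short-tandem-repeat profiles with the two
allele-sharing statistics standard in cell-line authentication:

* Tanabe (non-empty-match) score: ``100 * 2*shared / (n_a + n_b)``
* Masters (reference-match) score: ``100 * shared / n_reference``

summed over the markers the two profiles have in common.  Amelogenin is
a sex marker, not a polymorphic STR, so it is excluded from the numeric
scores by default and reported via the allele-loss list instead.
A query is declared to share its origin with the reference when the
Tanabe score reaches the conventional 80% threshold.
"""

from __future__ import annotations

import dataclasses
import io
import json

import pandas as pd

from .errors import DataError

#: PowerPlex-16 marker panel, in the order of the shipped profile table.
POWERPLEX16_MARKERS: tuple[str, ...] = (
    "D3S1358", "TH01", "D21S11", "D18S51", "Penta E", "D5S818", "D13S317",
    "D7S820", "D16S539", "CSF1PO", "Penta D", "AMEL", "vWA", "D8S1179",
    "TPOX", "FGA",
)


@dataclasses.dataclass(frozen=True)
class STRProfile:
    """Marker -> allele-set map for one sample.

    Allele labels are exact strings: repeat counts (``"16"``,
    micro-variants like ``"9.3"``) or ``"X"``/``"Y"`` for AMEL.  Each
    set has one (homozygous) or two members.
    """

    sample_id: str
    markers: dict[str, frozenset[str]]

    def __post_init__(self):
        for marker, alleles in self.markers.items():
            if marker not in POWERPLEX16_MARKERS:
                raise DataError(f"unknown STR marker {marker!r}")
            if not 1 <= len(alleles) <= 2:
                raise DataError(
                    f"marker {marker} of {self.sample_id} has {len(alleles)} alleles; "
                    "expected 1 or 2"
                )

    def alleles(self, exclude_amel: bool = True) -> int:
        """Total allele count over the panel."""
        return sum(
            len(a) for m, a in self.markers.items()
            if not (exclude_amel and m == "AMEL")
        )


@dataclasses.dataclass
class MatchReport:
    """Outcome of authenticating a query profile against a reference."""

    query_id: str
    reference_id: str
    shared_alleles: int
    query_alleles: int
    reference_alleles: int
    tanabe_percent: float
    masters_percent: float
    allele_losses: list[tuple[str, str]]
    verdict: str  # same_origin | different

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["allele_losses"] = [list(t) for t in self.allele_losses]
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        lines = [
            f"Query:      {self.query_id}",
            f"Reference:  {self.reference_id}",
            f"Shared alleles: {self.shared_alleles} "
            f"(query {self.query_alleles}, reference {self.reference_alleles})",
            f"Tanabe score:   {self.tanabe_percent:.1f}%",
            f"Masters score:  {self.masters_percent:.1f}%",
            "Allele losses:  "
            + (", ".join(f"{m} {a}" for m, a in self.allele_losses) or "none"),
            f"Verdict:        {self.verdict}",
        ]
        return "\n".join(lines)


def parse_str_table(table) -> list[STRProfile]:
    """Parse a Table-1-style CSV into one profile per sample column.

    Layout: first column holds marker names (one per row), remaining
    columns one sample each; alleles within a cell are comma-separated
    (quoted).  Whitespace-tolerant.
    """
    if hasattr(table, "read") or "\n" in str(table):
        buf = io.StringIO(table) if isinstance(table, str) else table
    else:
        buf = table  # a path
    df = pd.read_csv(buf, dtype=str, skip_blank_lines=True)
    if df.shape[1] < 2:
        raise DataError("STR table needs a marker column plus at least one sample")
    marker_col = df.columns[0]
    profiles = []
    for sample in df.columns[1:]:
        markers: dict[str, frozenset[str]] = {}
        for _, row in df.iterrows():
            marker = str(row[marker_col]).strip()
            if marker not in POWERPLEX16_MARKERS:
                raise DataError(f"unknown STR marker {marker!r}")
            cell = row[sample]
            if pd.isna(cell) or not str(cell).strip():
                raise DataError(f"empty allele cell at marker {marker}, sample {sample}")
            alleles = frozenset(a.strip() for a in str(cell).split(",") if a.strip())
            if len(alleles) > 2:
                raise DataError(
                    f"marker {marker}, sample {sample}: more than 2 alleles ({sorted(alleles)})"
                )
            markers[marker] = alleles
        profiles.append(STRProfile(sample_id=str(sample).strip(), markers=markers))
    return profiles


def _common_markers(a: STRProfile, b: STRProfile, exclude_amel: bool) -> list[str]:
    common = [
        m for m in POWERPLEX16_MARKERS
        if m in a.markers and m in b.markers and not (exclude_amel and m == "AMEL")
    ]
    if not common:
        raise DataError("profiles share no markers")
    return common


def _tally(a: STRProfile, b: STRProfile, exclude_amel: bool) -> tuple[int, int, int]:
    shared = n_a = n_b = 0
    for m in _common_markers(a, b, exclude_amel):
        sa, sb = a.markers[m], b.markers[m]
        shared += len(sa & sb)
        n_a += len(sa)
        n_b += len(sb)
    return shared, n_a, n_b


def tanabe_score(a: STRProfile, b: STRProfile, exclude_amel: bool = True) -> float:
    """Symmetric allele-sharing percentage, 100 * 2*shared / (n_a + n_b)."""
    shared, n_a, n_b = _tally(a, b, exclude_amel)
    return 100.0 * 2.0 * shared / (n_a + n_b)


def masters_score(query: STRProfile, reference: STRProfile, exclude_amel: bool = True) -> float:
    """Reference-anchored percentage, 100 * shared / n_reference."""
    shared, _, n_ref = _tally(query, reference, exclude_amel)
    if n_ref == 0:
        raise DataError("reference profile has no alleles")
    return 100.0 * shared / n_ref


def allele_losses(reference: STRProfile, query: STRProfile) -> list[tuple[str, str]]:
    """Alleles present in the reference but absent from the query.

    AMEL is included (a lost Y is biologically meaningful).  Output is
    sorted by panel order, then allele label.
    """
    losses: list[tuple[str, str]] = []
    for m in POWERPLEX16_MARKERS:
        if m in reference.markers and m in query.markers:
            for allele in sorted(reference.markers[m] - query.markers[m]):
                losses.append((m, allele))
    return losses


def authenticate(
    query: STRProfile, reference: STRProfile, threshold: float = 80.0
) -> MatchReport:
    """Full authentication report; same_origin iff Tanabe >= threshold."""
    shared, n_q, n_ref = _tally(query, reference, exclude_amel=True)
    tanabe = 100.0 * 2.0 * shared / (n_q + n_ref)
    masters = 100.0 * shared / n_ref
    losses = allele_losses(reference, query)
    verdict = "same_origin" if tanabe >= threshold else "different"
    return MatchReport(
        query_id=query.sample_id,
        reference_id=reference.sample_id,
        shared_alleles=shared,
        query_alleles=n_q,
        reference_alleles=n_ref,
        tanabe_percent=tanabe,
        masters_percent=masters,
        allele_losses=losses,
        verdict=verdict,
    )
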