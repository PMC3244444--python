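"""Functional-region annotation on protamine protein sequences.

Three kinds of regions, all in 0-based half-open residue coordinates:

* DNA-anchoring domains — runs of >= 3 consecutive Arg/Lys flanked by
  short cysteine-containing segments (the protamine-DNA binding motif);
* phosphorylation motifs — ProSite-style consensus patterns for PKC
  ([ST]-x-[RK]), PKA ([RK]-[RK]-x-[ST]) and CK2 ([ST]-x-x-[DE]);
* configured sites (e.g. the precursor's proteolytic cleavage positions),
  given in reference-sequence numbering and mapped through the reference
  row's alignment gaps.

Pattern scanners replace the web services used in the original analyses;
overlapping matches are all reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .seqio import CodonAlignment
from .selection_tests import SitePosterior

__all__ = [
    "Region", "DomainAnnotation", "scan_anchoring", "scan_phospho",
    "map_configured_sites", "profile_regions", "KINASE_PATTERNS",
]

REGION_TYPES = {
    "anchoring", "phospho_PKC", "phospho_PKA", "phospho_CK2", "cleavage",
}

#: consensus patterns; lookahead makes overlapping matches visible
KINASE_PATTERNS: dict[str, tuple[str, int]] = {
    "PKC": (r"(?=([ST].[RK]))", 3),
    "PKA": (r"(?=([RK][RK].[ST]))", 4),
    "CK2": (r"(?=([ST])..[DE])", 4),
}


@dataclass(frozen=True)
class Region:
    """One annotated region: half-open residue interval."""

    type: str
    start: int
    end: int
    source: str = "scanned"   # "scanned" | "configured"

    def __post_init__(self) -> None:
        if self.type not in REGION_TYPES:
            raise ValueError(f"unknown region type {self.type!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class DomainAnnotation:
    """A set of regions on one coordinate system (residues)."""

    regions: list[tuple[str, tuple[int, int], str]] = field(default_factory=list)

    @classmethod
    def from_regions(cls, regions: list[Region]) -> "DomainAnnotation":
        return cls([(r.type, r.interval, r.source) for r in regions])

    def add(self, regions: list[Region]) -> "DomainAnnotation":
        self.regions.extend((r.type, r.interval, r.source) for r in regions)
        return self

    def to_bed_rows(self, seq_id: str) -> list[tuple]:
        """BED-like rows: (sequence id, start, end, type, source)."""
        return [
            (seq_id, start, end, rtype, source)
            for rtype, (start, end), source in self.regions
        ]


def scan_anchoring(
    seq: str, flank_window: int = 5, flank_mode: str = "any"
) -> list[Region]:
    """DNA-anchoring domains: >=3 consecutive R/K with cysteine flanks.

    A maximal Arg/Lys run qualifies when a cysteine occurs within
    ``flank_window`` residues of the run on at least one side
    (``flank_mode="any"``, default) or on both (``"both"``).  The reported
    interval is the run extended to the qualifying cysteines; overlapping
    qualifying regions are merged.
    """
    if flank_mode not in ("any", "both"):
        raise ValueError("flank_mode must be 'any' or 'both'")
    seq = seq.upper()
    intervals: list[tuple[int, int]] = []
    for m in re.finditer(r"[RK]{3,}", seq):
        s, e = m.start(), m.end()
        left = seq[max(0, s - flank_window):s]
        right = seq[e:e + flank_window]
        left_c = left.rfind("C")
        right_c = right.find("C")
        has_left, has_right = left_c != -1, right_c != -1
        ok = (has_left and has_right) if flank_mode == "both" else (
            has_left or has_right
        )
        if not ok:
            continue
        start = (max(0, s - flank_window) + left_c) if has_left else s
        end = (e + right_c + 1) if has_right else e
        intervals.append((start, end))
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return [Region("anchoring", s, e, "scanned") for s, e in merged]


def scan_phospho(seq: str, kinases: set[str] | None = None) -> list[Region]:
    """Phosphorylation-motif matches for the requested kinases.

    Patterns: PKC [ST]-x-[RK]; PKA [RK]-[RK]-x-[ST]; CK2 [ST]-x-x-[DE].
    All (including overlapping) matches are reported, each spanning the
    full pattern.
    """
    kinases = kinases if kinases is not None else set(KINASE_PATTERNS)
    unknown = kinases - set(KINASE_PATTERNS)
    if unknown:
        raise ValueError(f"unknown kinase id(s): {sorted(unknown)}")
    seq = seq.upper()
    out: list[Region] = []
    for kin in sorted(kinases):
        pattern, span = KINASE_PATTERNS[kin]
        for m in re.finditer(pattern, seq):
            start = m.start()
            if start + span <= len(seq):
                out.append(Region(f"phospho_{kin}", start, start + span,
                                  "scanned"))
    return sorted(out, key=lambda r: (r.start, r.type))


def map_configured_sites(
    alignment: CodonAlignment,
    site_list: list[int],
    region_type: str,
    reference: str,
) -> list[Region]:
    """Map reference-numbered residue positions to alignment columns.

    ``site_list`` holds 0-based positions in the UNGAPPED reference
    protein; each maps through the reference row's gaps to its alignment
    column and becomes a single-residue region.
    """
    if reference not in alignment.taxa:
        raise KeyError(f"reference taxon {reference!r} not in alignment")
    row = alignment.sequences[alignment.taxa.index(reference)]
    columns = []
    for c in range(len(row) // 3):
        if row[3 * c:3 * c + 3] != "---":
            columns.append(c)
    out = []
    for pos in site_list:
        if pos < 0 or pos >= len(columns):
            raise IndexError(
                f"position {pos} beyond ungapped reference length "
                f"{len(columns)}"
            )
        col = columns[pos]
        out.append(Region(region_type, col, col + 1, "configured"))
    return out


def profile_regions(
    posterior: SitePosterior, annotation: DomainAnnotation
) -> dict[str, dict]:
    """Selective-class composition of each region type.

    For every region type present, the percent of covered sites in
    classes 1/2/3, the covered-site count, and the positively selected
    sites (PP > 0.95 under the posterior's model) falling inside the
    type's regions.  Types covering no sites are omitted with a note.
    """
    L = posterior.n_sites
    by_type: dict[str, set[int]] = {}
    for rtype, (start, stop), _src in annotation.regions:
        if start < 0 or stop > L:
            raise IndexError(
                f"region [{start},{stop}) outside {L}-site posterior"
            )
        by_type.setdefault(rtype, set()).update(range(start, stop))
    out: dict[str, dict] = {}
    flagged = set(posterior.pp95)
    for rtype, sites in sorted(by_type.items()):
        if not sites:
            out[rtype] = {"note": "covers no sites"}
            continue
        idx = sorted(sites)
        cls = posterior.assigned_class[idx]
        n = len(idx)
        out[rtype] = {
            "n_sites": n,
            "percent": {
                c: round(100.0 * int((cls == c).sum()) / n, 2)
                for c in (1, 2, 3)
            },
            "positively_selected": sorted(flagged & set(idx)),
        }
    return out
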