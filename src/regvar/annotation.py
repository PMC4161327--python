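"""Overlap of candidate variants with regulatory-annotation peak tracks.

Implements the prioritization funnel: LD proxies are intersected with open
chromatin (DNase/FAIRE), histone-mark and transcription-factor ChIP-seq
peaks from disease-relevant cell types; a variant becomes a candidate when
it falls inside at least one open-chromatin peak, and candidates are ranked
by the breadth of supporting evidence.

Coordinate conventions are the classic trap here and are centralised in
:func:`variant_overlaps_track`: peak files are BED-style 0-based half-open,
variants are VCF-style 1-based, so a variant at 1-based position ``pos``
overlaps ``[start, end)`` iff ``start <= pos - 1 < end``.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ld import VariantRecord

#: fixed assay-name → assay-class lookup
ASSAY_CLASSES: dict[str, str] = {
    "DNase": "open_chromatin",
    "FAIRE": "open_chromatin",
    "H3K4me1": "histone_mark",
    "H3K9ac": "histone_mark",
    "H3K27ac": "histone_mark",
    "H3K4me3": "histone_mark",
    "FOXA1": "tf_chip",
    "FOXA2": "tf_chip",
}

ASSAY_CLASS_ORDER = ("open_chromatin", "histone_mark", "tf_chip")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' so that 'chr10' and '10' compare equal."""
    return name[3:] if name.startswith("chr") else name


@dataclass
class PeakTrack:
    """A named peak track with cell-type and assay metadata.

    Intervals are kept sorted by (chrom, start); per-chromosome start arrays
    and prefix maxima of ends are precomputed so point overlap is a binary
    search even when peaks nest.
    """

    track_id: str
    cell_type: str
    assay_name: str
    intervals: list[GenomicInterval]
    assay_class: str = field(default="")

    def __post_init__(self) -> None:
        expected = ASSAY_CLASSES.get(self.assay_name)
        if expected is None:
            raise ValueError(
                f"unknown assay name {self.assay_name!r}; known: {sorted(ASSAY_CLASSES)}"
            )
        if self.assay_class and self.assay_class != expected:
            raise ValueError(
                f"assay_class {self.assay_class!r} inconsistent with "
                f"assay {self.assay_name!r} (expected {expected!r})"
            )
        self.assay_class = expected
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for iv in self.intervals:
            self._by_chrom.setdefault(normalize_chrom(iv.chrom), ([], []))  # type: ignore[arg-type]
        grouped: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            grouped.setdefault(normalize_chrom(iv.chrom), []).append(iv)
        for chrom, ivs in grouped.items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, np.maximum.accumulate(ends))

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """True iff the 0-based position ``pos0`` lies inside some peak."""
        entry = self._by_chrom.get(normalize_chrom(chrom))
        if entry is None:
            return False
        starts, prefix_max_end = entry
        k = int(np.searchsorted(starts, pos0, side="right"))
        return k > 0 and int(prefix_max_end[k - 1]) > pos0


def read_peak_track(
    path: str | Path,
    cell_type: str,
    assay_name: str,
    track_id: str | None = None,
) -> PeakTrack:
    """Parse a BED3/BED6 or ENCODE narrowPeak file into a :class:`PeakTrack`.

    narrowPeak signalValue (column 7) is retained as the interval score.
    Malformed coordinates or unexpected column counts raise with the
    offending line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 6, 10):
                raise ValueError(
                    f"{path}:{lineno}: expected 3 (BED3), 6 (BED6) or 10 "
                    f"(narrowPeak) columns, got {len(fields)}"
                )
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) >= 6 and fields[3] != "." else None
            score: float | None = None
            if len(fields) == 6 and fields[4] not in (".", ""):
                score = float(fields[4])
            elif len(fields) == 10:
                score = float(fields[6])  # signalValue
            intervals.append(GenomicInterval(chrom, start, end, name=name, score=score))
    return PeakTrack(
        track_id=track_id or f"{cell_type}_{assay_name}",
        cell_type=cell_type,
        assay_name=assay_name,
        intervals=intervals,
    )


def variant_overlaps_track(variant: VariantRecord, track: PeakTrack) -> bool:
    """True iff the variant base falls inside some peak of the track.

    The single place where 1-based VCF positions meet 0-based half-open
    BED intervals: overlap iff ``start <= variant.pos - 1 < end``.
    """
    return track.contains_point(variant.chrom, variant.pos - 1)


@dataclass
class AnnotationMatrix:
    """Boolean variants × tracks overlap table plus per-class summaries."""

    variants: list[VariantRecord]
    tracks: list[PeakTrack]
    hits: pd.DataFrame          # bool, index = variant ids, columns = track ids
    class_counts: pd.DataFrame  # int, index = variant ids, columns = assay classes


def build_annotation_matrix(
    variants: Sequence[VariantRecord], tracks: Sequence[PeakTrack]
) -> AnnotationMatrix:
    """Complete overlap matrix for every variant against every track."""
    if len(variants) == 0:
        raise ValueError("build_annotation_matrix requires at least one variant")
    vids = [v.id for v in variants]
    if len(set(vids)) != len(vids):
        dupes = sorted({v for v in vids if vids.count(v) > 1})
        raise ValueError(f"duplicate variant ids: {dupes}")
    tids = [t.track_id for t in tracks]
    if len(set(tids)) != len(tids):
        raise ValueError("duplicate track ids")
    data = {
        t.track_id: [variant_overlaps_track(v, t) for v in variants] for t in tracks
    }
    hits = pd.DataFrame(data, index=vids, dtype=bool, columns=tids)
    counts = pd.DataFrame(0, index=vids, columns=list(ASSAY_CLASS_ORDER), dtype=int)
    for t in tracks:
        counts[t.assay_class] += hits[t.track_id].astype(int)
    return AnnotationMatrix(
        variants=list(variants), tracks=list(tracks), hits=hits, class_counts=counts
    )


@dataclass
class PrioritizationReport:
    """Ranked candidates with their supporting evidence, plus funnel counts."""

    table: pd.DataFrame  # variant_id, candidate, n_open_chromatin, n_histone, n_tf_chip, supporting_tracks
    n_proxies: int
    n_candidates: int

    @property
    def candidates(self) -> list[str]:
        return list(self.table.loc[self.table["candidate"], "variant_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def funnel_summary(self) -> dict[str, int]:
        return {"n_proxies": self.n_proxies, "n_candidates": self.n_candidates}

    def write_funnel_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.funnel_summary(), indent=2) + "\n")


def prioritize(matrix: AnnotationMatrix, min_open_chromatin: int = 1) -> PrioritizationReport:
    """Call candidates and rank them by breadth of regulatory evidence.

    A variant is a candidate iff it has at least ``min_open_chromatin``
    open-chromatin (DNase/FAIRE) peak hits; histone marks and TF ChIP peaks
    contribute to ranking but not to candidacy. Ranking: open-chromatin
    count, then histone, then TF ChIP (all descending), then genomic
    position ascending — fully deterministic.
    """
    pos_by_id = {v.id: v.pos for v in matrix.variants}
    rows = []
    for v in matrix.variants:
        cc = matrix.class_counts.loc[v.id]
        supporting = [
            t.track_id for t in matrix.tracks if bool(matrix.hits.at[v.id, t.track_id])
        ]
        rows.append(
            {
                "variant_id": v.id,
                "candidate": bool(cc["open_chromatin"] >= min_open_chromatin),
                "n_open_chromatin": int(cc["open_chromatin"]),
                "n_histone": int(cc["histone_mark"]),
                "n_tf_chip": int(cc["tf_chip"]),
                "supporting_tracks": ",".join(supporting),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["candidate", "n_open_chromatin", "n_histone", "n_tf_chip", "variant_id"],
        ascending=[False, False, False, False, True],
        key=lambda col: col.map(pos_by_id) if col.name == "variant_id" else col,
    ).reset_index(drop=True)
    return PrioritizationReport(
        table=table,
        n_proxies=len(matrix.variants),
        n_candidates=int(table["candidate"].sum()),
    )
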