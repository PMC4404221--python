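"""Read routing, barcode demultiplexing, allele counting, and run QC.

Amplicon reads are recognized by an exact occurrence of the M13 tail; the
barcode is taken from the ``barcode_length`` bases immediately preceding the
tail's first occurrence and looked up exactly (no mismatch tolerance — any
sequencing error in barcode or target simply drops the read, which is the
trade-off exact matching makes for simplicity and specificity).  The payload
after the tail is assigned to a locus by which marker's allele target it
contains, and counted toward allele A, allele B, or unmatched.

Reads without the tail form the GBS background; their barcode and
restriction-site integrity is summarized as run-level QC, and the fraction
of M13-containing reads estimates the spiked fraction of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .errors import InputError
from .markers import BarcodeSet, ConstructParts, MarkerDefinition

COUNT_COLUMNS = ["sample_id", "locus_id", "count_a", "count_b", "count_unmatched"]

#: Routing categories for a single read.
AMPLICON = "amplicon"
GBS = "gbs"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RoutingDecision:
    """Where one read went: amplicon (with sample and payload), gbs, or
    unassigned (M13 tail present but no known barcode before it)."""

    category: str
    sample_id: str | None = None
    payload: str | None = None


@dataclass
class RunQC:
    """Run-level quality summary.

    ``spiked_fraction`` is the M13-count estimator of the amplicon spike:
    the fraction of all reads containing the M13 tail, i.e. demultiplexed
    amplicon reads plus unassigned reads (tail present, barcode unknown).
    GBS fractions are computed over the GBS-routed reads only; they are
    None when no GBS barcode set was supplied.
    """

    total_reads: int = 0
    amplicon_reads: int = 0
    gbs_reads: int = 0
    unassigned: int = 0
    amplicon_no_locus: int = 0
    gbs_good_barcode_fraction: float | None = None
    gbs_barcode_plus_cutsite_fraction: float | None = None

    @property
    def m13_reads(self) -> int:
        """Reads containing the M13 tail (demultiplexed or not)."""
        return self.amplicon_reads + self.unassigned

    @property
    def spiked_fraction(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return self.m13_reads / self.total_reads

    def as_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "amplicon_reads": self.amplicon_reads,
            "gbs_reads": self.gbs_reads,
            "unassigned": self.unassigned,
            "amplicon_no_locus": self.amplicon_no_locus,
            "m13_reads": self.m13_reads,
            "spiked_fraction": self.spiked_fraction,
            "gbs_good_barcode_fraction": self.gbs_good_barcode_fraction,
            "gbs_barcode_plus_cutsite_fraction": self.gbs_barcode_plus_cutsite_fraction,
        }


def classify_read(
    read: str, parts: ConstructParts, amplicon_barcodes: BarcodeSet
) -> RoutingDecision:
    """Route one read: amplicon, gbs, or unassigned.

    The first occurrence of the M13 tail wins; the construct places the
    barcode immediately before the tail, so the preceding
    ``barcode_length`` bases are looked up exactly.
    """
    idx = read.find(parts.m13_tail)
    if idx < 0:
        return RoutingDecision(GBS)
    start = idx - amplicon_barcodes.barcode_length
    if start < 0:
        return RoutingDecision(UNASSIGNED)
    sample = amplicon_barcodes.by_barcode.get(read[start:idx])
    if sample is None:
        return RoutingDecision(UNASSIGNED)
    return RoutingDecision(AMPLICON, sample_id=sample,
                           payload=read[idx + len(parts.m13_tail):])


def match_allele(payload: str, marker: MarkerDefinition) -> str:
    """Exact-match the payload against the marker's two allele targets.

    Returns 'A' or 'B' when exactly one target occurs as a substring, and
    'unmatched' when neither or both occur (ambiguity is never resolved by
    guessing).
    """
    a = marker.allele_a_target in payload
    b = marker.allele_b_target in payload
    if a and not b:
        return "A"
    if b and not a:
        return "B"
    return "unmatched"


def qc_gbs_rates(
    gbs_reads: Iterable[str | tuple[str, str]],
    gbs_barcodes: BarcodeSet,
    cut_site_remnant: str,
) -> tuple[float, float]:
    """Fractions of GBS reads with (a) an exact barcode prefix and (b) the
    barcode immediately followed by the restriction-site remnant."""
    known = set(gbs_barcodes.barcodes)
    length = gbs_barcodes.barcode_length
    total = good_bc = good_both = 0
    for read in gbs_reads:
        seq = read[1] if isinstance(read, tuple) else read
        total += 1
        if seq[:length] in known:
            good_bc += 1
            if seq[length:length + len(cut_site_remnant)] == cut_site_remnant:
                good_both += 1
    if total == 0:
        return 0.0, 0.0
    return good_bc / total, good_both / total


def _resolve_locus(payload: str, markers: list[MarkerDefinition]) -> tuple[str | None, str]:
    """Assign a payload to a locus by target content.

    After pooling, the allele targets are the only locus-identifying
    sequence, so the locus is the unique marker whose target(s) occur in the
    payload.  Returns (locus_id, allele) where allele may be 'unmatched';
    (None, 'unmatched') when no or several markers' targets occur.
    """
    hits = []
    for marker in markers:
        a = marker.allele_a_target in payload
        b = marker.allele_b_target in payload
        if a or b:
            hits.append((marker, a, b))
    if len(hits) != 1:
        return None, "unmatched"
    marker, a, b = hits[0]
    if a and b:
        return marker.locus_id, "unmatched"
    return marker.locus_id, "A" if a else "B"


@dataclass
class _Router:
    """Single-pass read router; accumulates counts and QC."""

    parts: ConstructParts
    barcodes: BarcodeSet
    markers: list[MarkerDefinition]
    gbs_barcodes: BarcodeSet | None = None
    cut_site_remnant: str | None = None
    counts: dict = field(default_factory=dict)
    qc: RunQC = field(default_factory=RunQC)
    _gbs_good_bc: int = 0
    _gbs_good_both: int = 0

    def consume(self, read_id: str, seq: str) -> RoutingDecision:
        decision = classify_read(seq, self.parts, self.barcodes)
        self.qc.total_reads += 1
        if decision.category == GBS:
            self.qc.gbs_reads += 1
            if self.gbs_barcodes is not None:
                length = self.gbs_barcodes.barcode_length
                if seq[:length] in set_cache(self.gbs_barcodes):
                    self._gbs_good_bc += 1
                    remnant = self.cut_site_remnant or ""
                    if remnant and seq[length:length + len(remnant)] == remnant:
                        self._gbs_good_both += 1
        elif decision.category == UNASSIGNED:
            self.qc.unassigned += 1
        else:
            self.qc.amplicon_reads += 1
            locus, allele = _resolve_locus(decision.payload, self.markers)
            if locus is None:
                self.qc.amplicon_no_locus += 1
            else:
                cell = self.counts.setdefault(
                    (decision.sample_id, locus), [0, 0, 0]
                )
                if allele == "A":
                    cell[0] += 1
                elif allele == "B":
                    cell[1] += 1
                else:
                    cell[2] += 1
        return decision

    def finish(self) -> tuple[pd.DataFrame, RunQC]:
        rows = [
            {
                "sample_id": sample,
                "locus_id": locus,
                "count_a": a,
                "count_b": b,
                "count_unmatched": u,
            }
            for (sample, locus), (a, b, u) in sorted(self.counts.items())
        ]
        table = pd.DataFrame(rows, columns=COUNT_COLUMNS)
        if self.gbs_barcodes is not None and self.qc.gbs_reads:
            self.qc.gbs_good_barcode_fraction = self._gbs_good_bc / self.qc.gbs_reads
            self.qc.gbs_barcode_plus_cutsite_fraction = (
                self._gbs_good_both / self.qc.gbs_reads
            )
        return table, self.qc


_barcode_set_cache: dict[int, frozenset] = {}


def set_cache(bset: BarcodeSet) -> frozenset:
    """Memoized frozenset of a BarcodeSet's barcodes (prefix lookup)."""
    key = id(bset)
    cached = _barcode_set_cache.get(key)
    if cached is None or len(cached) != len(bset.entries):
        cached = frozenset(bset.barcodes)
        _barcode_set_cache[key] = cached
    return cached


def count_alleles(
    reads: Iterable[tuple[str, str]],
    parts: ConstructParts,
    barcodes: BarcodeSet,
    markers: list[MarkerDefinition],
    gbs_barcodes: BarcodeSet | None = None,
    cut_site_remnant: str | None = None,
    routing_log=None,
) -> tuple[pd.DataFrame, RunQC]:
    """One pass over a read stream: route, demultiplex, count, and QC.

    Every read lands in exactly one of {amplicon, gbs, unassigned}; the
    returned allele-count table covers exactly the (sample, locus) cells
    with at least one routed read.  When a GBS barcode set (and cut-site
    remnant) is provided, GBS QC fractions are computed in the same pass.
    An optional *routing_log* file handle receives one TSV line per read.
    """
    router = _Router(parts, barcodes, markers, gbs_barcodes, cut_site_remnant)
    for read_id, seq in reads:
        decision = router.consume(read_id, seq)
        if routing_log is not None:
            routing_log.write(
                f"{read_id}\t{decision.category}\t{decision.sample_id or ''}\n"
            )
    return router.finish()


def counts_to_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=COUNT_COLUMNS)


def counts_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"allele count TSV {path} is missing columns {missing}")
    return df
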