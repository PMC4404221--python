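"""Markers, barcodes, and the spiked-amplicon construct.

The sGBS sequencing construct is, read in sequencing order::

    platform_forward_site | barcode | M13 tail | forward flank | allele target
                          | reverse flank | platform_reverse_site

A universal barcoded primer (platform forward site + sample barcode + M13
tail) is combined with locus-specific allele primers that carry the same M13
tail, so one set of barcode oligos serves every target locus.  The M13 tail
doubles as the parser's signature for amplicon (vs GBS background) reads.

This module models those parts, assembles primers and expected amplicons,
converts KASP allele-specific primer pairs to the single common forward
primer used here, and generates/validates barcode sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlphabetError,
    AmbiguityError,
    CapacityError,
    ConversionError,
    LengthError,
    MarkerDefinitionError,
    ValidationError,
)

DNA_ALPHABET = frozenset("ACGT")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Ion Torrent A adapter (forward sequencing priming site).
ION_A_ADAPTER = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"
#: Ion Torrent P1 adapter (reverse priming site).
ION_P1_ADAPTER = "CCTCTCTATGGGCAGTCGGTGAT"
#: Canonical M13 forward (-21) tail used as the universal linker.
M13_FORWARD_TAIL = "TGTAAAACGACGGCCAGT"
#: PstI restriction-site remnant left at the start of a GBS insert.
PSTI_REMNANT = "TGCAG"

#: Genotype class labels for a single-copy biallelic SNP.
BIALLELIC_LABELS = ("A", "Heterozygous", "B")
BIALLELIC_FRACTIONS = (1.0, 0.5, 0.0)


def check_dna(seq: str, name: str = "sequence", allow_empty: bool = False) -> str:
    """Validate that *seq* is an upper-case A/C/G/T string and return it."""
    if not isinstance(seq, str):
        raise AlphabetError(f"{name} must be a string, got {type(seq).__name__}")
    if not seq:
        if allow_empty:
            return seq
        raise ValidationError(f"{name} must be non-empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{name} contains non-ACGT characters: {sorted(bad)} in {seq!r}"
        )
    return seq


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise LengthError(f"hamming distance undefined for lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ClassModel:
    """Expected genotype classes for one locus.

    Each class is a label plus the allele-A read fraction it predicts.
    Fractions are strictly decreasing, so sorted cluster centroids can be
    paired with classes from the high-A end down.
    """

    labels: tuple[str, ...]
    fractions: tuple[float, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.fractions):
            raise ValidationError("class labels and fractions must align")
        if len(self.labels) < 2:
            raise ValidationError("a class model needs at least two classes")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(f"duplicate class labels: {self.labels}")
        for f in self.fractions:
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"class fraction {f} outside [0, 1]")
        if any(a <= b for a, b in zip(self.fractions, self.fractions[1:])):
            raise ValidationError(
                f"class fractions must be strictly decreasing, got {self.fractions}"
            )

    @classmethod
    def biallelic_3class(cls) -> "ClassModel":
        """A / Heterozygous / B with expected allele-A fractions 1, 0.5, 0."""
        return cls(BIALLELIC_LABELS, BIALLELIC_FRACTIONS)

    @classmethod
    def dosage_classes(cls, fractions, ploidy: int = 6) -> "ClassModel":
        """Allele-dosage classes for a polyploid locus.

        Labels are derived from the fractions: a fraction f maps to
        ``round(f * ploidy)`` copies of allele A, e.g. for a hexaploid,
        2/3 -> AAAABB.  Default ploidy 6 matches bread wheat.
        """
        fractions = tuple(float(f) for f in fractions)
        labels = []
        for f in fractions:
            copies = round(f * ploidy)
            if abs(f * ploidy - copies) > 0.05:
                raise ValidationError(
                    f"dosage fraction {f} is not close to a multiple of 1/{ploidy}"
                )
            labels.append("A" * copies + "B" * (ploidy - copies))
        return cls(tuple(labels), fractions)

    def fraction_of(self, label: str) -> float:
        try:
            return self.fractions[self.labels.index(label)]
        except ValueError:
            raise ValidationError(f"unknown class label {label!r}; model has {self.labels}")

    def __len__(self) -> int:
        return len(self.labels)

    def to_string(self) -> str:
        """Serialize for the marker TSV class_model column."""
        if (self.labels, self.fractions) == (BIALLELIC_LABELS, BIALLELIC_FRACTIONS):
            return "biallelic_3class"
        return "dosage:" + ",".join(repr(f) for f in self.fractions)

    @classmethod
    def from_string(cls, text: str) -> "ClassModel":
        text = text.strip()
        if text == "biallelic_3class":
            return cls.biallelic_3class()
        if text.startswith("dosage:"):
            fractions = [float(x) for x in text[len("dosage:"):].split(",")]
            return cls.dosage_classes(fractions)
        raise ValidationError(
            f"unrecognized class_model {text!r} "
            "(expected 'biallelic_3class' or 'dosage:f1,f2,...')"
        )


@dataclass(frozen=True)
class MarkerDefinition:
    """One target locus: flanking primers and the two allele target sequences.

    ``forward_flank`` is the locus-specific forward primer *without* the M13
    tail; ``reverse_flank`` the locus-specific reverse primer without the
    platform site.  Allele targets are the polymorphic sequences counted by
    exact matching, given in the same (forward-strand) orientation.
    """

    locus_id: str
    forward_flank: str
    reverse_flank: str
    allele_a_target: str
    allele_b_target: str
    class_model: ClassModel = field(default_factory=ClassModel.biallelic_3class)

    def __post_init__(self):
        if not self.locus_id:
            raise ValidationError("locus_id must be non-empty")
        check_dna(self.forward_flank, f"{self.locus_id} forward_flank")
        check_dna(self.reverse_flank, f"{self.locus_id} reverse_flank")
        check_dna(self.allele_a_target, f"{self.locus_id} allele_a_target")
        check_dna(self.allele_b_target, f"{self.locus_id} allele_b_target")
        if self.allele_a_target == self.allele_b_target:
            raise MarkerDefinitionError(
                f"{self.locus_id}: allele targets are identical"
            )
        # One target nested in the other would make exact-match counting
        # undecidable, so it is rejected at load time.
        if (self.allele_a_target in self.allele_b_target
                or self.allele_b_target in self.allele_a_target):
            raise MarkerDefinitionError(
                f"{self.locus_id}: one allele target contains the other; "
                "exact matching cannot distinguish them"
            )

    def target(self, allele: str) -> str:
        if allele == "A":
            return self.allele_a_target
        if allele == "B":
            return self.allele_b_target
        raise ValidationError(f"allele must be 'A' or 'B', got {allele!r}")


@dataclass(frozen=True)
class ConstructParts:
    """Platform-level construct components shared by all loci."""

    platform_forward_site: str = ION_A_ADAPTER
    platform_reverse_site: str = ION_P1_ADAPTER
    m13_tail: str = M13_FORWARD_TAIL

    def __post_init__(self):
        check_dna(self.platform_forward_site, "platform_forward_site")
        check_dna(self.platform_reverse_site, "platform_reverse_site")
        check_dna(self.m13_tail, "m13_tail")


@dataclass
class BarcodeSet:
    """Sample-to-barcode mapping with uniqueness and length guarantees.

    ``min_pairwise_hamming`` of 0 disables the distance check (suitable for
    user-supplied sets where only uniqueness matters under exact-match
    parsing); generated sets default to a minimum distance of 3.
    """

    entries: dict[str, str]
    barcode_length: int = 10
    min_pairwise_hamming: int = 0

    def __post_init__(self):
        self.entries = dict(self.entries)
        self._by_barcode: dict[str, str] | None = None

    @property
    def by_barcode(self) -> dict[str, str]:
        """Reverse lookup barcode -> sample_id (first sample wins on duplicates)."""
        if self._by_barcode is None:
            rev: dict[str, str] = {}
            for sample, bc in self.entries.items():
                rev.setdefault(bc, sample)
            self._by_barcode = rev
        return self._by_barcode

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    @property
    def barcodes(self) -> list[str]:
        return list(self.entries.values())


def assemble_barcode_primer(
    parts: ConstructParts, barcode: str, barcode_length: int = 10
) -> str:
    """Assemble the universal barcoded primer: platform site + barcode + M13 tail."""
    check_dna(barcode, "barcode")
    if len(barcode) != barcode_length:
        raise LengthError(
            f"barcode {barcode!r} has length {len(barcode)}, expected {barcode_length}"
        )
    return parts.platform_forward_site + barcode + parts.m13_tail


def assemble_allele_primers(
    parts: ConstructParts, marker: MarkerDefinition
) -> tuple[str, str]:
    """Locus-specific primer pair: (M13 tail + forward flank, platform reverse
    site + reverse flank), both written in construct (forward-strand) order."""
    forward = parts.m13_tail + marker.forward_flank
    reverse = parts.platform_reverse_site + marker.reverse_flank
    return forward, reverse


def convert_kasp_to_common_forward(primer_allele_a: str, primer_allele_b: str) -> str:
    """Convert a KASP allele-specific forward primer pair to one common primer.

    KASP primers differ only at the 3' selective base; dropping it yields a
    single forward primer that amplifies both alleles, which are then read
    directly from the sequence.
    """
    check_dna(primer_allele_a, "primer_allele_a")
    check_dna(primer_allele_b, "primer_allele_b")
    if len(primer_allele_a) != len(primer_allele_b) or len(primer_allele_a) < 2:
        raise ConversionError(
            "KASP primer pair must be two equal-length primers of length >= 2"
        )
    if primer_allele_a == primer_allele_b:
        raise ConversionError("primers are identical: no selective base to remove")
    if primer_allele_a[:-1] != primer_allele_b[:-1]:
        raise ConversionError(
            "primers differ at a non-terminal position: not a KASP allele-specific pair"
        )
    return primer_allele_a[:-1]


def expected_amplicon(
    parts: ConstructParts,
    barcode: str,
    marker: MarkerDefinition,
    allele: str,
    barcode_length: int | None = None,
) -> str:
    """The full expected amplicon sequence for one (barcode, marker, allele).

    Raises :class:`AmbiguityError` if the M13 tail's first occurrence in the
    assembled sequence is not at its designed offset (e.g. the barcode itself
    contains the tail), since such a construct cannot be parsed back.
    """
    if barcode_length is None:
        barcode_length = len(barcode)
    primer = assemble_barcode_primer(parts, barcode, barcode_length)
    seq = (
        primer
        + marker.forward_flank
        + marker.target(allele)
        + marker.reverse_flank
        + parts.platform_reverse_site
    )
    designed = len(parts.platform_forward_site) + len(barcode)
    if seq.find(parts.m13_tail) != designed:
        raise AmbiguityError(
            f"M13 tail first occurs at offset {seq.find(parts.m13_tail)}, "
            f"not the designed {designed}; construct is unparseable "
            f"(barcode {barcode!r})"
        )
    return seq


def generate_barcode_set(
    n: int,
    length: int = 10,
    min_hamming: int = 3,
    seed: int = 0,
    sample_prefix: str = "sample_",
    max_attempts: int | None = None,
) -> BarcodeSet:
    """Generate *n* unique random barcodes with a pairwise-distance guarantee.

    Uses seeded rejection sampling: candidates are drawn uniformly and kept if
    at least ``min_hamming`` away from every accepted barcode.  Deterministic
    for a fixed seed.  Raises :class:`CapacityError` when the bounded search
    cannot place *n* codes (e.g. more than 4 single-base barcodes).
    """
    if n < 1 or length < 1:
        raise ValidationError("need n >= 1 and length >= 1")
    if min_hamming > length:
        raise ValidationError(f"min_hamming {min_hamming} exceeds barcode length {length}")
    if max_attempts is None:
        max_attempts = max(20_000, 500 * n)

    rng = np.random.default_rng(seed)
    accepted = np.empty((n, length), dtype=np.uint8)
    n_acc = 0
    attempts = 0
    while n_acc < n:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not place {n} barcodes of length {length} with "
                f"min Hamming {min_hamming} within {max_attempts} attempts "
                f"({n_acc} placed)"
            )
        attempts += 1
        cand = _BASES[rng.integers(0, 4, size=length)]
        if n_acc:
            dists = (accepted[:n_acc] != cand).sum(axis=1)
            if dists.min() < max(min_hamming, 1):
                continue
        accepted[n_acc] = cand
        n_acc += 1

    width = max(3, len(str(n)))
    entries = {
        f"{sample_prefix}{i + 1:0{width}d}": accepted[i].tobytes().decode("ascii")
        for i in range(n)
    }
    return BarcodeSet(entries, barcode_length=length, min_pairwise_hamming=min_hamming)


def validate_barcode_set(
    bset: BarcodeSet, parts: ConstructParts | None = None
) -> list[str]:
    """Report-only validation; returns a list of violation descriptions.

    Checks uniqueness, length, alphabet, the pairwise minimum Hamming
    distance (when the set declares one), and — when *parts* is given — that
    the M13 tail does not occur inside any barcode, which would make the
    barcode/tail boundary ambiguous.
    """
    report: list[str] = []
    seen: dict[str, str] = {}
    for sample, bc in bset.entries.items():
        if bc in seen:
            report.append(
                f"duplicate barcode {bc!r} shared by samples "
                f"{seen[bc]!r} and {sample!r}"
            )
        else:
            seen[bc] = sample
        if len(bc) != bset.barcode_length:
            report.append(
                f"barcode {bc!r} of sample {sample!r} has length {len(bc)}, "
                f"expected {bset.barcode_length}"
            )
        bad = set(bc) - DNA_ALPHABET
        if bad:
            report.append(
                f"barcode {bc!r} of sample {sample!r} contains non-ACGT "
                f"characters {sorted(bad)}"
            )
        if parts is not None and parts.m13_tail in bc:
            report.append(
                f"barcode {bc!r} of sample {sample!r} contains the M13 tail"
            )
    if bset.min_pairwise_hamming > 0:
        items = list(bset.entries.items())
        for (s1, b1), (s2, b2) in itertools.combinations(items, 2):
            if len(b1) == len(b2) and hamming(b1, b2) < bset.min_pairwise_hamming:
                report.append(
                    f"barcodes of samples {s1!r} and {s2!r} are at Hamming "
                    f"distance {hamming(b1, b2)} < {bset.min_pairwise_hamming}"
                )
    return report


# ---------------------------------------------------------------------------
# TSV interfaces

MARKER_COLUMNS = [
    "locus_id", "forward_flank", "reverse_flank",
    "allele_a_target", "allele_b_target", "class_model",
]


def load_markers_tsv(path) -> list[MarkerDefinition]:
    """Load marker definitions from a TSV with the documented columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"marker TSV {path} is missing columns {missing}")
    markers = []
    for row in df.itertuples(index=False):
        markers.append(
            MarkerDefinition(
                locus_id=row.locus_id,
                forward_flank=row.forward_flank,
                reverse_flank=row.reverse_flank,
                allele_a_target=row.allele_a_target,
                allele_b_target=row.allele_b_target,
                class_model=ClassModel.from_string(row.class_model),
            )
        )
    ids = [m.locus_id for m in markers]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"marker TSV {path} contains duplicate locus_ids")
    return markers


def write_markers_tsv(markers: list[MarkerDefinition], path) -> None:
    df = pd.DataFrame(
        [
            {
                "locus_id": m.locus_id,
                "forward_flank": m.forward_flank,
                "reverse_flank": m.reverse_flank,
                "allele_a_target": m.allele_a_target,
                "allele_b_target": m.allele_b_target,
                "class_model": m.class_model.to_string(),
            }
            for m in markers
        ],
        columns=MARKER_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_barcodes_tsv(
    path, min_pairwise_hamming: int = 0, parts: ConstructParts | None = None
) -> BarcodeSet:
    """Load a sample_id/barcode TSV; raises on any validation violation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "barcode"):
        if col not in df.columns:
            raise ValidationError(f"barcode TSV {path} is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"barcode TSV {path} has duplicate sample_ids {dupes}")
    lengths = df["barcode"].str.len()
    bset = BarcodeSet(
        dict(zip(df["sample_id"], df["barcode"])),
        barcode_length=int(lengths.mode().iat[0]),
        min_pairwise_hamming=min_pairwise_hamming,
    )
    report = validate_barcode_set(bset, parts)
    if report:
        raise ValidationError(
            f"barcode TSV {path} failed validation:\n" + "\n".join(report)
        )
    return bset


def write_barcodes_tsv(bset: BarcodeSet, path) -> None:
    pd.DataFrame(
        {"sample_id": bset.samples, "barcode": bset.barcodes}
    ).to_csv(path, sep="\t", index=False)
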