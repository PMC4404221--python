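"""Synthetic sequencing-run simulator for the spiked-GBS design.

A simulated run mixes two read populations:

* **GBS background** — reads that start with an in-line sample barcode and a
  restriction-site remnant followed by a random insert, with lengths drawn
  from a truncated normal (defaults centered near the read-length means
  observed on Ion Proton GBS libraries).  A configurable fraction of reads
  carries a corrupted barcode or cut site, emulating real library QC rates.
* **Spiked amplicons** — full constructs (platform site + barcode + M13 tail
  + flank + allele target + flank + platform site), one target locus per
  sample library, at a small configurable fraction of the run (~1–3%).

Every read's identity (sample, locus, emitted allele) is recorded in the
read id and aggregated into an audit count table, and genotype truth is kept
in a truth table, so demultiplexing and genotype calling can be tested
end-to-end with no external data.

All randomness flows from a single integer seed; no global state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import write_fastq
from .markers import (
    BarcodeSet,
    ConstructParts,
    MarkerDefinition,
    _BASES,
    expected_amplicon,
    generate_barcode_set,
)

TRUTH_COLUMNS = ["sample_id", "locus_id", "true_class", "expected_fraction"]
AUDIT_COLUMNS = ["sample_id", "locus_id", "count_a", "count_b"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute each given position with a uniformly chosen different base."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def add_substitution_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Apply iid per-base substitution errors at the given rate."""
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    return _mutate(seq, positions, rng)


@dataclass(frozen=True)
class DepthModel:
    """Per-(sample, locus) read-depth distribution.

    ``negbin`` draws overdispersed counts (variance mean + mean^2/dispersion);
    ``fixed`` always returns round(mean).  Defaults span the per-marker
    average depths seen in practice for spiked amplicons (roughly 100–1600).
    """

    kind: str = "negbin"
    mean: float = 300.0
    dispersion: float = 5.0

    def __post_init__(self):
        if self.kind not in ("negbin", "fixed"):
            raise ConfigError(f"unknown depth model kind {self.kind!r}")
        if self.mean < 0:
            raise ConfigError("depth mean must be >= 0")
        if self.kind == "negbin" and self.dispersion <= 0:
            raise ConfigError("negative-binomial dispersion must be > 0")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, int(round(self.mean)), dtype=np.int64)
        p = self.dispersion / (self.dispersion + self.mean)
        return rng.negative_binomial(self.dispersion, p, size=size).astype(np.int64)


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings.

    Defaults emulate the conditions of a spiked Ion Proton GBS run: a ~1%
    amplicon spike, background read lengths centered at 145 bp, and GBS
    barcode / barcode-plus-cut-site integrity rates of 83.6% / 81.3%.
    """

    n_samples: int = 96
    spike_fraction: float = 0.01
    depth: DepthModel = field(default_factory=DepthModel)
    error_rate: float = 0.01
    gbs_length_mean: float = 145.0
    gbs_length_sd: float = 30.0
    good_barcode_rate: float = 0.836
    good_cutsite_rate: float = 0.813
    cut_site_remnant: str = "TGCAG"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.spike_fraction < 1:
            raise ConfigError(f"spike_fraction {self.spike_fraction} outside (0, 1)")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigError(f"error_rate {self.error_rate} outside [0, 0.5)")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.good_cutsite_rate > self.good_barcode_rate:
            raise ConfigError(
                "good_cutsite_rate cannot exceed good_barcode_rate "
                "(a cut site is only scored after an intact barcode)"
            )


def simulate_truth(
    samples: list[str],
    markers: list[MarkerDefinition],
    class_frequencies: dict[str, dict[str, float]] | None,
    seed,
) -> pd.DataFrame:
    """Draw a genotype truth table: one class per (sample, locus).

    *class_frequencies* maps locus_id -> {class label: probability}; omitted
    loci (or a None argument) default to the uniform distribution over the
    marker's classes.  Deterministic given the seed.
    """
    rng = _rng(seed)
    class_frequencies = class_frequencies or {}
    rows = []
    for marker in markers:
        model = marker.class_model
        freqs = class_frequencies.get(marker.locus_id)
        if freqs is None:
            labels = list(model.labels)
            probs = np.full(len(labels), 1.0 / len(labels))
        else:
            unknown = set(freqs) - set(model.labels)
            if unknown:
                raise ConfigError(
                    f"{marker.locus_id}: class frequencies name unknown classes {sorted(unknown)}"
                )
            labels = list(freqs)
            probs = np.array([freqs[c] for c in labels], dtype=float)
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"{marker.locus_id}: class frequencies sum to {probs.sum()}, not 1"
                )
        draws = rng.choice(len(labels), size=len(samples), p=probs)
        for sample, idx in zip(samples, draws):
            label = labels[idx]
            rows.append(
                {
                    "sample_id": sample,
                    "locus_id": marker.locus_id,
                    "true_class": label,
                    "expected_fraction": model.fraction_of(label),
                }
            )
    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return df.sort_values(["locus_id", "sample_id"], kind="stable").reset_index(drop=True)


def simulate_amplicon_reads(
    truth: pd.DataFrame,
    markers: list[MarkerDefinition],
    barcodes: BarcodeSet,
    parts: ConstructParts,
    depth_model: DepthModel,
    error_rate: float,
    seed,
    depths: np.ndarray | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate spiked amplicon reads for every truth cell.

    Depth per (sample, locus) is drawn from *depth_model* (or taken from the
    explicit *depths* array aligned with truth rows); the allele of each read
    is Bernoulli in the cell's expected allele-A fraction; substitution
    errors are applied per base.  Returns the reads and an audit table of
    emitted (pre-error) allele counts.
    """
    rng = _rng(seed)
    marker_by_id = {m.locus_id: m for m in markers}
    missing = set(truth["sample_id"]) - set(barcodes.samples)
    if missing:
        raise ConfigError(f"truth samples without a barcode: {sorted(missing)}")
    if depths is None:
        depths = depth_model.draw(rng, len(truth))
    elif len(depths) != len(truth):
        raise ConfigError("explicit depths must align with truth rows")

    reads: list[tuple[str, str]] = []
    audit_rows = []
    for (row, d) in zip(truth.itertuples(index=False), depths):
        marker = marker_by_id[row.locus_id]
        barcode = barcodes.entries[row.sample_id]
        d = int(d)
        k_a = int(rng.binomial(d, row.expected_fraction)) if d else 0
        amp = {
            "A": expected_amplicon(parts, barcode, marker, "A"),
            "B": expected_amplicon(parts, barcode, marker, "B"),
        }
        for j, allele in enumerate(["A"] * k_a + ["B"] * (d - k_a)):
            seq = add_substitution_errors(amp[allele], error_rate, rng)
            read_id = f"amp:{row.sample_id}:{row.locus_id}:{allele}:{j}"
            reads.append((read_id, seq))
        audit_rows.append(
            {
                "sample_id": row.sample_id,
                "locus_id": row.locus_id,
                "count_a": k_a,
                "count_b": d - k_a,
            }
        )
    return reads, pd.DataFrame(audit_rows, columns=AUDIT_COLUMNS)


def simulate_gbs_background(
    n_reads: int,
    gbs_barcodes: BarcodeSet,
    cut_site_remnant: str,
    length_mean: float,
    length_sd: float,
    good_barcode_rate: float,
    good_cutsite_rate: float,
    seed,
    forbidden: str | None = None,
) -> list[tuple[str, str]]:
    """Generate GBS-style background reads.

    Each read is barcode + cut-site remnant + random insert.  The barcode is
    intact with probability *good_barcode_rate* (else one base is mutated so
    it matches no barcode in the set); given an intact barcode, the remnant
    is intact with probability good_cutsite_rate / good_barcode_rate.  Reads
    containing *forbidden* (the M13 tail) are rejected and redrawn so the
    background never mimics an amplicon.
    """
    if good_cutsite_rate > good_barcode_rate:
        raise ConfigError("good_cutsite_rate cannot exceed good_barcode_rate")
    rng = _rng(seed)
    if n_reads == 0:
        return []
    bc_list = gbs_barcodes.barcodes
    known = set(bc_list)
    p_cut_given_bc = good_cutsite_rate / good_barcode_rate if good_barcode_rate else 0.0

    reads = []
    for i in range(n_reads):
        barcode = bc_list[rng.integers(0, len(bc_list))]
        bc_ok = rng.random() < good_barcode_rate
        if not bc_ok:
            corrupted = barcode
            while corrupted in known:
                corrupted = _mutate(barcode, [rng.integers(0, len(barcode))], rng)
            barcode = corrupted
        remnant = cut_site_remnant
        if bc_ok and rng.random() >= p_cut_given_bc:
            remnant = _mutate(remnant, [rng.integers(0, len(remnant))], rng)
        elif not bc_ok:
            # barcode already fails QC; remnant state is irrelevant
            pass
        length = max(30, int(round(rng.normal(length_mean, length_sd))))
        insert_len = max(0, length - len(barcode) - len(remnant))
        while True:
            seq = barcode + remnant + _random_dna(rng, insert_len)
            if forbidden is None or forbidden not in seq:
                break
        reads.append((f"gbs:{i}", seq))
    return reads


@dataclass
class SimResult:
    """Everything a simulated run produced, for downstream audits."""

    truth: pd.DataFrame
    audit_counts: pd.DataFrame
    reads: list[tuple[str, str]]
    n_amplicon: int
    n_background: int
    config: SimConfig
    amplicon_barcodes: BarcodeSet
    gbs_barcodes: BarcodeSet
    fastq_path: str | None = None


def simulate_run(
    config: SimConfig,
    markers: list[MarkerDefinition],
    barcodes: BarcodeSet | None = None,
    parts: ConstructParts | None = None,
    class_frequencies: dict[str, dict[str, float]] | None = None,
    truth: pd.DataFrame | None = None,
    n_reads: int | None = None,
    fastq_path=None,
    gbs_barcodes: BarcodeSet | None = None,
) -> SimResult:
    """Simulate a full spiked sequencing run.

    When *n_reads* is given, the number of amplicon reads is binomial
    (n_reads, spike_fraction) and is allocated across (sample, locus) cells
    proportionally to per-cell depth-model draws; otherwise per-cell depths
    are taken directly from the depth model and enough background reads are
    added to hit the configured spike fraction in expectation.  Read order is
    shuffled deterministically; the same seed yields byte-identical output.
    """
    parts = parts or ConstructParts()
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=6)

    if barcodes is None:
        barcodes = generate_barcode_set(
            config.n_samples, length=10, min_hamming=3, seed=int(seeds[0])
        )
    samples = barcodes.samples[: config.n_samples]
    if truth is None:
        truth = simulate_truth(samples, markers, class_frequencies, int(seeds[1]))

    depth_rng = _rng(int(seeds[2]))
    raw_depths = config.depth.draw(depth_rng, len(truth)).astype(np.int64)
    if n_reads is None:
        depths = raw_depths
        n_amplicon = int(depths.sum())
        n_background = int(round(n_amplicon * (1 - config.spike_fraction)
                                 / config.spike_fraction))
    else:
        n_amplicon = int(depth_rng.binomial(n_reads, config.spike_fraction))
        n_background = n_reads - n_amplicon
        weights = raw_depths.astype(float)
        if weights.sum() == 0:
            weights = np.ones(len(truth))
        depths = depth_rng.multinomial(n_amplicon, weights / weights.sum())

    amp_reads, audit = simulate_amplicon_reads(
        truth, markers, barcodes, parts,
        config.depth, config.error_rate, int(seeds[3]), depths=depths,
    )

    if gbs_barcodes is None:
        # GBS libraries use their own in-line barcode set (shorter than the
        # M13 tail, so it can never contain it).
        gbs_barcodes = generate_barcode_set(
            config.n_samples, length=8, min_hamming=3,
            seed=int(seeds[4]), sample_prefix="gbs_",
        )
    bg_reads = simulate_gbs_background(
        n_background, gbs_barcodes, config.cut_site_remnant,
        config.gbs_length_mean, config.gbs_length_sd,
        config.good_barcode_rate, config.good_cutsite_rate,
        int(seeds[5]), forbidden=parts.m13_tail,
    )

    all_reads = amp_reads + bg_reads
    order = np.random.default_rng(int(seeds[0]) ^ 0x5EED).permutation(len(all_reads))
    shuffled = [all_reads[i] for i in order]

    if fastq_path is not None:
        write_fastq(shuffled, fastq_path)

    return SimResult(
        truth=truth,
        audit_counts=audit,
        reads=shuffled,
        n_amplicon=len(amp_reads),
        n_background=len(bg_reads),
        config=config,
        amplicon_barcodes=barcodes,
        gbs_barcodes=gbs_barcodes,
        fastq_path=str(fastq_path) if fastq_path is not None else None,
    )


def simulate_allele_counts(
    truth: pd.DataFrame,
    depth_model: DepthModel,
    seed,
    error_rate: float = 0.0,
    effective_length: int = 40,
) -> pd.DataFrame:
    """Counts-level shortcut: draw an allele count table directly from truth.

    Equivalent in distribution to simulating reads and exact-match counting:
    per cell, depth ~ depth model, a read survives exact matching with
    probability (1 - error_rate)^effective_length (any substitution in the
    matched region drops the read), and surviving reads split binomially by
    the expected allele-A fraction.  Used where only counts are needed
    (e.g. clustering studies), avoiding per-read string work.
    """
    rng = _rng(seed)
    if not 0 <= error_rate < 0.5:
        raise ConfigError(f"error_rate {error_rate} outside [0, 0.5)")
    n = len(truth)
    depths = depth_model.draw(rng, n)
    keep_p = (1.0 - error_rate) ** effective_length
    kept = rng.binomial(depths, keep_p)
    count_a = rng.binomial(kept, truth["expected_fraction"].to_numpy(dtype=float))
    out = truth[["sample_id", "locus_id"]].copy()
    out["count_a"] = count_a
    out["count_b"] = kept - count_a
    out["count_unmatched"] = depths - kept
    return out


def random_markers(
    n_loci: int,
    seed,
    parts: ConstructParts | None = None,
    class_models=None,
    flank_length: int = 18,
    target_length: int = 12,
    locus_prefix: str = "locus_",
) -> list[MarkerDefinition]:
    """Generate synthetic marker definitions safe for exact-match counting.

    Targets are random *target_length*-mers differing at one central base
    (a SNP); rejection sampling guarantees that no allele target occurs
    anywhere in another locus's amplicon or in the construct parts, so a
    noise-free read always resolves to exactly one (locus, allele).
    *class_models* may be a single :class:`~spikegbs.markers.ClassModel`
    or a list per locus; default is the biallelic 3-class model.
    """
    from .markers import ClassModel

    parts = parts or ConstructParts()
    rng = _rng(seed)
    if class_models is None:
        class_models = [ClassModel.biallelic_3class()] * n_loci
    elif not isinstance(class_models, list):
        class_models = [class_models] * n_loci

    markers: list[MarkerDefinition] = []
    context = parts.platform_forward_site + parts.m13_tail + parts.platform_reverse_site

    def clashes(target: str) -> bool:
        if target in context:
            return True
        for m in markers:
            other = m.forward_flank + m.allele_a_target + m.reverse_flank
            other_b = m.forward_flank + m.allele_b_target + m.reverse_flank
            if target in other or target in other_b:
                return True
            if m.allele_a_target in target or m.allele_b_target in target:
                return True
        return False

    for i in range(n_loci):
        for _ in range(1000):
            fwd = _random_dna(rng, flank_length)
            rev = _random_dna(rng, flank_length)
            a = _random_dna(rng, target_length)
            pos = target_length // 2
            alt = _BASES[_BASES != ord(a[pos])]
            b = a[:pos] + chr(alt[rng.integers(0, 3)]) + a[pos + 1:]
            payload_a = fwd + a + rev
            payload_b = fwd + b + rev
            if clashes(a) or clashes(b):
                continue
            if a in payload_b or b in payload_a:
                continue
            if any(
                t in payload_a or t in payload_b
                for m in markers
                for t in (m.allele_a_target, m.allele_b_target)
            ):
                continue
            width = max(3, len(str(n_loci)))
            markers.append(
                MarkerDefinition(
                    locus_id=f"{locus_prefix}{i + 1:0{width}d}",
                    forward_flank=fwd,
                    reverse_flank=rev,
                    allele_a_target=a,
                    allele_b_target=b,
                    class_model=class_models[i],
                )
            )
            break
        else:
            raise ConfigError("could not place non-clashing synthetic markers")
    return markers


def truth_to_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def truth_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"truth TSV {path} is missing columns {missing}")
    return df
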