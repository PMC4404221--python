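"""Cluster-based genotype calling from allele read counts.

Per locus, samples passing a minimum-depth filter are placed on the
1-D relative-read-frequency axis (freq_a = count_a / (count_a + count_b);
freq_b is redundant since freq_b = 1 - freq_a) and grouped by either
k-means (k = number of expected classes; every sample is assigned) or
DBSCAN (reachability distance eps, default 0.1; outliers stay
unclassified).  Clusters are then labeled by matching their centroid
frequency to the nearest expected class fraction — 1 / 0.5 / 0 for a
single-copy biallelic SNP, or declared dosage fractions (e.g. 1, 2/3,
1/3, 0 for a hexaploid) — with an injectivity guarantee: two clusters
claiming the same class is an error flagged for manual curation rather
than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans

from .errors import InputError, LabelingError, ValidationError
from .markers import BarcodeSet, ClassModel, MarkerDefinition

#: Sentinel cluster id for DBSCAN noise points.
UNCLASSIFIED = -1
#: Genotype label for filtered or unclassified cells.
MISSING = "MISSING"

FREQ_COLUMNS = ["sample_id", "locus_id", "depth", "freq_a", "freq_b"]
GENOTYPE_COLUMNS = ["sample_id", "locus_id", "label", "method", "cluster_id"]


def depth_filter(table: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Convert allele counts to frequency points, dropping low-depth cells.

    A cell is retained when count_a + count_b >= min_depth (a cell with
    total 10 passes; 9 does not).  Unmatched reads do not contribute to
    depth: only reads assigned to an allele are informative for frequency.
    """
    if min_depth < 1:
        raise ValidationError("min_depth must be >= 1")
    depth = table["count_a"] + table["count_b"]
    kept = table.loc[depth >= min_depth].copy()
    kept["depth"] = depth[depth >= min_depth]
    kept["freq_a"] = kept["count_a"] / kept["depth"]
    kept["freq_b"] = 1.0 - kept["freq_a"]
    return kept[FREQ_COLUMNS].reset_index(drop=True)


@dataclass
class ClusterAssignment:
    """Per-sample cluster ids for one locus, plus ordered centroids.

    Cluster ids are renumbered 0..n-1 by ascending centroid freq_a, so ids
    are deterministic and independent of the backend's internal labeling;
    ``UNCLASSIFIED`` (-1) marks DBSCAN noise points.
    """

    locus_id: str
    method: str
    sample_ids: list[str]
    cluster_ids: np.ndarray
    centroids: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def _renumber_by_centroid(labels: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Renumber non-noise clusters by ascending mean freq_a."""
    ids = sorted(set(labels[labels >= 0]))
    centroids = np.array([freqs[labels == i].mean() for i in ids])
    order = np.argsort(centroids, kind="stable")
    remap = {ids[old]: new for new, old in enumerate(order)}
    out = np.array([remap.get(l, UNCLASSIFIED) for l in labels], dtype=int)
    return out, centroids[order]


def call_kmeans(points: pd.DataFrame, k: int, seed: int = 0) -> ClusterAssignment:
    """k-means on the 1-D allele-A frequencies of one locus.

    k-means++ initialization with 10 restarts and a fixed seed; the best
    inertia wins, so results are reproducible.  Every point is assigned.
    """
    locus = _single_locus(points)
    n = len(points)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} must satisfy 1 <= k <= n points ({n})")
    x = points["freq_a"].to_numpy(dtype=float).reshape(-1, 1)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    labels, centroids = _renumber_by_centroid(labels, x.ravel())
    return ClusterAssignment(
        locus_id=locus, method="kmeans",
        sample_ids=points["sample_id"].tolist(),
        cluster_ids=labels, centroids=centroids,
        params={"k": k, "seed": seed},
    )


def call_dbscan(
    points: pd.DataFrame, eps: float = 0.1, min_pts: int = 5
) -> ClusterAssignment:
    """DBSCAN on the 1-D allele-A frequencies of one locus.

    *eps* is the reachability distance on the frequency axis (default 0.1;
    some loci need a tighter value, e.g. 0.06, chosen per locus).  Points
    outside any dense cluster become UNCLASSIFIED.
    """
    if eps <= 0:
        raise ValidationError(f"eps must be > 0, got {eps}")
    if min_pts < 1:
        raise ValidationError(f"min_pts must be >= 1, got {min_pts}")
    locus = _single_locus(points)
    x = points["freq_a"].to_numpy(dtype=float).reshape(-1, 1)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(x)
    labels, centroids = _renumber_by_centroid(labels, x.ravel())
    return ClusterAssignment(
        locus_id=locus, method="dbscan",
        sample_ids=points["sample_id"].tolist(),
        cluster_ids=labels, centroids=centroids,
        params={"eps": eps, "min_pts": min_pts},
    )


def _single_locus(points: pd.DataFrame) -> str:
    loci = points["locus_id"].unique()
    if len(loci) != 1:
        raise InputError(f"expected points from exactly one locus, got {list(loci)}")
    if points.empty:
        raise InputError("no points to cluster")
    return loci[0]


def label_clusters(
    assignment: ClusterAssignment, marker: MarkerDefinition
) -> pd.DataFrame:
    """Map clusters to genotype classes by nearest expected allele fraction.

    The mapping must be injective: if two cluster centroids are both nearest
    to the same class fraction the locus cannot be labeled automatically and
    a :class:`LabelingError` is raised (such loci need manual curation).
    UNCLASSIFIED points become MISSING.
    """
    model = assignment_model(marker)
    if assignment.n_clusters > len(model):
        raise LabelingError(
            f"{assignment.locus_id}: {assignment.n_clusters} clusters exceed "
            f"the {len(model)} classes of the marker's model"
        )
    fractions = np.asarray(model.fractions)
    mapping: dict[int, str] = {}
    claimed: dict[int, int] = {}
    for cid, centroid in enumerate(assignment.centroids):
        nearest = int(np.argmin(np.abs(fractions - centroid)))
        if nearest in claimed:
            raise LabelingError(
                f"{assignment.locus_id}: clusters {claimed[nearest]} and {cid} "
                f"(centroids {assignment.centroids[claimed[nearest]]:.3f}, "
                f"{centroid:.3f}) both map to class {model.labels[nearest]!r}; "
                "locus flagged for manual curation"
            )
        claimed[nearest] = cid
        mapping[cid] = model.labels[nearest]
    rows = []
    for sample, cid in zip(assignment.sample_ids, assignment.cluster_ids):
        rows.append(
            {
                "sample_id": sample,
                "locus_id": assignment.locus_id,
                "label": mapping.get(int(cid), MISSING),
                "method": assignment.method,
                "cluster_id": int(cid),
            }
        )
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def assignment_model(marker: MarkerDefinition) -> ClassModel:
    return marker.class_model


def call_genotypes(
    table: pd.DataFrame,
    markers: list[MarkerDefinition],
    method: str = "kmeans",
    min_depth: int = 10,
    k: dict[str, int] | int | None = None,
    eps: float = 0.1,
    eps_per_locus: dict[str, float] | None = None,
    min_pts: int = 5,
    seed: int = 0,
    samples: list[str] | None = None,
    on_labeling_error: str = "raise",
) -> pd.DataFrame:
    """Full calling pass: depth filter, cluster, label, fill MISSING.

    Returns a long-format genotype matrix with one row per (sample, locus)
    over the full sample x marker domain; samples that fail the depth filter
    or are left unclassified get MISSING.  *k* may be a per-locus dict or a
    single integer; by default it is the number of classes in each marker's
    model.  *eps_per_locus* overrides *eps* for named loci.

    With ``on_labeling_error="flag"``, loci whose clusters cannot be labeled
    injectively are set to all-MISSING and listed in the result's
    ``attrs["flagged_loci"]`` instead of raising, mirroring the manual
    curation such loci need.
    """
    if method not in ("kmeans", "dbscan"):
        raise ValidationError(f"unknown method {method!r}")
    if on_labeling_error not in ("raise", "flag"):
        raise ValidationError("on_labeling_error must be 'raise' or 'flag'")
    if samples is None:
        samples = sorted(table["sample_id"].unique())
    points = depth_filter(table, min_depth=min_depth)
    eps_per_locus = eps_per_locus or {}

    frames = []
    flagged: list[str] = []
    for marker in markers:
        locus_pts = points[points["locus_id"] == marker.locus_id]
        if locus_pts.empty:
            continue
        if method == "kmeans":
            if isinstance(k, dict):
                k_locus = k.get(marker.locus_id, len(marker.class_model))
            else:
                k_locus = k if k is not None else len(marker.class_model)
            assignment = call_kmeans(locus_pts, k=k_locus, seed=seed)
        else:
            assignment = call_dbscan(
                locus_pts,
                eps=eps_per_locus.get(marker.locus_id, eps),
                min_pts=min_pts,
            )
        try:
            frames.append(label_clusters(assignment, marker))
        except LabelingError:
            if on_labeling_error == "raise":
                raise
            flagged.append(marker.locus_id)

    called = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=GENOTYPE_COLUMNS)
    )
    domain = pd.MultiIndex.from_product(
        [samples, [m.locus_id for m in markers]], names=["sample_id", "locus_id"]
    ).to_frame(index=False)
    gm = domain.merge(called, on=["sample_id", "locus_id"], how="left")
    gm["label"] = gm["label"].fillna(MISSING)
    gm["method"] = gm["method"].fillna(method)
    gm["cluster_id"] = (
        pd.to_numeric(gm["cluster_id"], errors="coerce")
        .fillna(UNCLASSIFIED).astype(int)
    )
    gm = gm[GENOTYPE_COLUMNS]
    gm.attrs["flagged_loci"] = flagged
    return gm


def concordance(g1: pd.DataFrame, g2: pd.DataFrame) -> tuple[float, float, int]:
    """Agreement between two genotype matrices over the same domain.

    Returns (overall_agreement, co_classified_agreement, n_co_classified):
    overall divides agreeing cells (non-MISSING in both) by cells
    non-MISSING in at least one; co_classified divides by cells non-MISSING
    in both.  The two readings bracket how unclassified cells are treated.
    """
    key = ["sample_id", "locus_id"]
    d1 = g1.set_index(key)["label"].sort_index()
    d2 = g2.set_index(key)["label"].sort_index()
    if not d1.index.equals(d2.index):
        raise InputError("genotype matrices cover different (sample, locus) domains")
    both = (d1 != MISSING) & (d2 != MISSING)
    either = (d1 != MISSING) | (d2 != MISSING)
    agree = int(((d1 == d2) & both).sum())
    n_both = int(both.sum())
    n_either = int(either.sum())
    overall = agree / n_either if n_either else 1.0
    co = agree / n_both if n_both else 1.0
    return overall, co, n_both


def marker_summary(
    gm: pd.DataFrame,
    table: pd.DataFrame,
    min_depth: int = 10,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Per-locus call rate and average depth.

    call_rate = non-MISSING calls / total samples assayed (low-depth samples
    count against it); avg_depth averages count_a + count_b over samples
    passing the depth filter, NaN when none do.
    """
    loci = gm["locus_id"].unique()
    if n_samples is None:
        n_samples = gm["sample_id"].nunique()
    depth = table.assign(depth=table["count_a"] + table["count_b"])
    rows = []
    for locus in loci:
        calls = gm[gm["locus_id"] == locus]
        called = int((calls["label"] != MISSING).sum())
        d = depth.loc[(depth["locus_id"] == locus) & (depth["depth"] >= min_depth), "depth"]
        rows.append(
            {
                "locus_id": locus,
                "call_rate": called / n_samples if n_samples else 0.0,
                "avg_depth": float(d.mean()) if len(d) else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["locus_id", "call_rate", "avg_depth"])


# ---------------------------------------------------------------------------
# Writers

def genotype_matrix_to_tsv(gm: pd.DataFrame, path) -> None:
    """Wide samples x loci TSV; MISSING is written as NA."""
    wide = gm.pivot(index="sample_id", columns="locus_id", values="label")
    wide = wide.replace(MISSING, "NA").sort_index()
    wide.to_csv(path, sep="\t", na_rep="NA")


def scatter_to_tsv(points: pd.DataFrame, gm: pd.DataFrame, path) -> None:
    """Per-sample frequency/depth/label TSV for external plotting."""
    merged = points.merge(
        gm[["sample_id", "locus_id", "label"]], on=["sample_id", "locus_id"], how="left"
    )
    merged["label"] = merged["label"].fillna(MISSING)
    merged.to_csv(path, sep="\t", index=False,
                  columns=["sample_id", "locus_id", "freq_a", "depth", "label"])


def summary_to_tsv(summary: pd.DataFrame, path) -> None:
    out = summary.copy()
    out["call_rate"] = (out["call_rate"] * 100).map(lambda v: f"{v:.1f}%")
    out["avg_depth"] = out["avg_depth"].map(
        lambda v: "NA" if pd.isna(v) else str(int(round(v)))
    )
    out.to_csv(path, sep="\t", index=False)


def _snp_alleles(marker: MarkerDefinition) -> tuple[int, str, str]:
    """(0-based position, REF, ALT) for the VCF record of one marker.

    When the two targets are equal-length and differ at exactly one base the
    record is that SNP; otherwise the full targets are written as alleles.
    """
    a, b = marker.allele_a_target, marker.allele_b_target
    if len(a) == len(b):
        diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        if len(diffs) == 1:
            i = diffs[0]
            return i, a[i], b[i]
    return 0, a, b


def write_vcf(
    gm: pd.DataFrame,
    markers: list[MarkerDefinition],
    path,
    sample_order: list[str] | None = None,
) -> None:
    """Write genotype calls as VCF 4.2 (one record per locus).

    Biallelic loci get conventional GT (allele A is REF: A -> 0/0,
    Heterozygous -> 0/1, B -> 1/1, MISSING -> ./.).  Dosage-model loci
    cannot be expressed as a diploid GT, so GT is missing and the class
    label is carried in the CL FORMAT field.
    """
    import pysam

    if sample_order is None:
        sample_order = sorted(gm["sample_id"].unique())
    header = pysam.VariantHeader()
    header.add_meta("source", "spikegbs")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("CL", 1, "String", "Genotype class label (dosage models)")
    for marker in markers:
        length = max(len(marker.allele_a_target), len(marker.allele_b_target)) + 1
        header.contigs.add(marker.locus_id, length=length)
    for sample in sample_order:
        header.add_sample(sample)

    by_cell = gm.set_index(["sample_id", "locus_id"])["label"]
    gt_map = {"A": (0, 0), "Heterozygous": (0, 1), "B": (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for marker in markers:
            pos0, ref, alt = _snp_alleles(marker)
            record = vcf.new_record(
                contig=marker.locus_id, start=pos0, alleles=(ref, alt),
                id=marker.locus_id,
            )
            biallelic = marker.class_model.labels == ("A", "Heterozygous", "B")
            for sample in sample_order:
                label = by_cell.get((sample, marker.locus_id), MISSING)
                if biallelic:
                    record.samples[sample]["GT"] = gt_map.get(label, (None, None))
                else:
                    record.samples[sample]["GT"] = (None, None)
                    if label != MISSING:
                        record.samples[sample]["CL"] = label.replace(":", "_")
            vcf.write(record)
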