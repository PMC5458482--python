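"""Tabular I/O and probe annotation for 450K-style methylation data.

The on-disk formats are deliberately plain:

* beta matrix — TSV, probe rows, header row of sample IDs, missing values
  as empty cells or ``NA``;
* manifest — TSV with one row per probe carrying coordinates, gene
  assignments (``;``-separated, Illumina style), the nearest CpG island as
  ``chrom:start-end``, and QC flags;
* TSS table — TSV of (gene, tss_pos);
* sample sheet — CSV with group labels and clinical covariates.

Coordinates are 1-based inclusive, the Illumina manifest convention.
Distances are absolute base-pair differences; strand is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Illumina gene-feature vocabulary.
GENE_FEATURES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")

#: Features counted as "promoter" when summarising gene-level methylation.
PROMOTER_FEATURES = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})

#: Sample group labels, ordered by disease stage.
GROUPS = ("nevus", "primary", "metastasis")

#: CpG-context classes.  Shores flank islands by up to 2 kb, shelves lie
#: 2–4 kb out, everything farther is open sea.
SHORE_BP = 2000
SHELF_BP = 4000

#: Detection p-value above which a data point is masked as missing.
DETECTION_P_MAX = 0.01


@dataclass
class BetaMatrix:
    """Probes × samples matrix of methylation beta values in [0, 1].

    Missing values (e.g. masked by detection p-value) are ``NaN`` in
    ``values``; ``mask`` exposes them as a boolean frame.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated probe IDs: {list(dup[:5])}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicated sample IDs")
        v = self.values.to_numpy(dtype=float)
        bad = (v < -1e-9) | (v > 1 + 1e-9)
        if np.any(bad & ~np.isnan(v)):
            r, c = np.argwhere(bad & ~np.isnan(v))[0]
            raise ValueError(
                f"beta value outside [0,1] at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}: {v[r, c]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """True where the value is missing."""
        return self.values.isna()

    def subset_probes(self, probes) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[probes])

    def subset_samples(self, samples) -> "BetaMatrix":
        return BetaMatrix(self.values[list(samples)])


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation plus the gene TSS table.

    ``probes`` is indexed by probe_id with columns: chrom, pos, strand,
    gene_symbols, gene_features (``;``-separated, parallel), island_start,
    island_end (nearest island; NaN when the genome has none),
    snp_overlap, is_genotyping.  ``tss`` maps gene -> tss_pos.
    """

    probes: pd.DataFrame
    tss: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["gene", "tss_pos"]))

    def __post_init__(self) -> None:
        ok = self.probes[["island_start", "island_end"]].dropna()
        if (ok["island_start"] > ok["island_end"]).any():
            raise ValueError("island_start > island_end in annotation")

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    def gene_assignments(self, probe_id: str) -> dict[str, str]:
        """Return {gene: feature} for one probe (possibly empty)."""
        row = self.probes.loc[probe_id]
        return _parse_gene_fields(row["gene_symbols"], row["gene_features"])

    def exploded(self) -> pd.DataFrame:
        """(probe_id, gene, feature) triples for all gene-assigned probes."""
        rows = []
        for pid, row in self.probes.iterrows():
            for gene, feat in _parse_gene_fields(row["gene_symbols"], row["gene_features"]).items():
                rows.append((pid, gene, feat))
        return pd.DataFrame(rows, columns=["probe_id", "gene", "feature"])

    def tss_positions(self, probe_id: str) -> np.ndarray:
        """TSS coordinates of the genes assigned to a probe."""
        genes = list(self.gene_assignments(probe_id))
        if not genes or self.tss.empty:
            return np.array([], dtype=float)
        sub = self.tss[self.tss["gene"].isin(genes)]
        return sub["tss_pos"].to_numpy(dtype=float)


def _parse_gene_fields(symbols, features) -> dict[str, str]:
    if pd.isna(symbols) or symbols == "":
        return {}
    syms = str(symbols).split(";")
    feats = str(features).split(";")
    if len(syms) != len(feats):
        raise ValueError(f"gene_symbols/gene_features length mismatch: {symbols!r} vs {features!r}")
    out: dict[str, str] = {}
    for g, f in zip(syms, feats):
        if f not in GENE_FEATURES:
            raise ValueError(f"unknown gene feature token {f!r}")
        out[g] = f
    return out


# ---------------------------------------------------------------------------
# beta matrix I/O


def read_beta_matrix(path, detection_path=None) -> BetaMatrix:
    """Read a beta-value TSV; optionally mask low-confidence data points.

    When a detection p-value table (same layout) is supplied, entries with
    detection p > 0.01 are set missing so that every downstream statistic
    shares one mask.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicated probe IDs in {path}: {list(dup[:5])}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric beta value at probe {df.index[bad.argmax()]!r}, sample {col!r}"
            )
        df[col] = coerced
    bm = BetaMatrix(df.astype(float))
    if detection_path is not None:
        det = pd.read_csv(detection_path, sep="\t", index_col=0, na_values=["NA", ""])
        if not det.empty:
            det = det.reindex(index=bm.probe_ids, columns=bm.sample_ids)
            n_before = int(bm.values.isna().sum().sum())
            bm.values[det.to_numpy(dtype=float) > DETECTION_P_MAX] = np.nan
            n_masked = int(bm.values.isna().sum().sum()) - n_before
            logger.info("detection-p masking: %d data points set missing", n_masked)
    return bm


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    bm.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


# ---------------------------------------------------------------------------
# manifest / sample sheet I/O

_MANIFEST_COLS = [
    "probe_id",
    "chrom",
    "pos",
    "strand",
    "gene_symbols",
    "gene_features",
    "island",
    "snp_overlap",
    "is_genotyping",
]


def read_manifest(path, tss_path=None) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbols": str, "gene_features": str})
    missing = set(_MANIFEST_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df = df.set_index("probe_id")
    island = df["island"].fillna("")
    starts, ends = [], []
    for s in island:
        if s:
            rng = s.split(":", 1)[1]
            a, b = rng.split("-")
            starts.append(int(a))
            ends.append(int(b))
        else:
            starts.append(np.nan)
            ends.append(np.nan)
    df["island_start"] = starts
    df["island_end"] = ends
    df["gene_symbols"] = df["gene_symbols"].fillna("")
    df["gene_features"] = df["gene_features"].fillna("")
    tss = pd.DataFrame(columns=["gene", "tss_pos"])
    if tss_path is not None:
        tss = pd.read_csv(tss_path, sep="\t")
    return ProbeAnnotation(df.drop(columns=["island"]), tss)


def write_manifest(ann: ProbeAnnotation, path, tss_path=None) -> None:
    df = ann.probes.copy()
    island = []
    for _, row in df.iterrows():
        if pd.isna(row["island_start"]):
            island.append("")
        else:
            island.append(f"{row['chrom']}:{int(row['island_start'])}-{int(row['island_end'])}")
    df["island"] = island
    df = df.drop(columns=["island_start", "island_end"]).reset_index()
    df = df.rename(columns={df.columns[0]: "probe_id"})
    df[_MANIFEST_COLS].to_csv(path, sep="\t", index=False)
    if tss_path is not None:
        ann.tss.to_csv(tss_path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet CSV and validate the closed vocabularies."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError("sample sheet needs at least sample_id and group columns")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if "survival_months" in df.columns:
        t = pd.to_numeric(df["survival_months"], errors="raise")
        if (t.dropna() < 0).any():
            raise ValueError("negative survival_months")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# probe QC


def qc_filter_probes(bm: BetaMatrix, ann: ProbeAnnotation) -> BetaMatrix:
    """Drop genotyping probes and probes overlapping known SNPs.

    Every probe in the matrix must be annotated; offenders are listed in
    the error.  Idempotent: filtering a filtered matrix is a no-op.
    """
    unknown = bm.probe_ids.difference(ann.probe_ids)
    if len(unknown) > 0:
        raise ValueError(f"probes absent from annotation: {list(unknown[:10])}")
    sub = ann.probes.loc[bm.probe_ids]
    flagged = (sub["snp_overlap"].astype(int) == 1) | (sub["is_genotyping"].astype(int) == 1)
    n_snp = int((sub["snp_overlap"].astype(int) == 1).sum())
    n_geno = int((sub["is_genotyping"].astype(int) == 1).sum())
    logger.info(
        "QC: removing %d probes (%d SNP-overlapping, %d genotyping) of %d",
        int(flagged.sum()), n_snp, n_geno, len(bm.probe_ids),
    )
    return bm.subset_probes(bm.probe_ids[~flagged.to_numpy()])


# ---------------------------------------------------------------------------
# compartment classification


def _island_distance(pos: float, start: float, end: float) -> float:
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0.0


def classify_island_context(probe_id: str, ann: ProbeAnnotation) -> str:
    """Classify a probe as island / shore / shelf / open_sea.

    Distance is to the nearest island edge: 0 inside the island, ≤ 2 kb is
    shore, 2–4 kb is shelf, farther (or no island at all) is open sea.
    """
    row = ann.probes.loc[probe_id]
    if pd.isna(row["island_start"]):
        return "open_sea"
    d = _island_distance(float(row["pos"]), float(row["island_start"]), float(row["island_end"]))
    if d == 0:
        return "island"
    if d <= SHORE_BP:
        return "shore"
    if d <= SHELF_BP:
        return "shelf"
    return "open_sea"


def island_context_series(ann: ProbeAnnotation) -> pd.Series:
    """Vectorised island-context class per probe."""
    pos = ann.probes["pos"].to_numpy(dtype=float)
    start = ann.probes["island_start"].to_numpy(dtype=float)
    end = ann.probes["island_end"].to_numpy(dtype=float)
    d = np.where(pos < start, start - pos, np.where(pos > end, pos - end, 0.0))
    out = np.full(len(pos), "open_sea", dtype=object)
    has = ~np.isnan(start)
    out[has & (d <= SHELF_BP)] = "shelf"
    out[has & (d <= SHORE_BP)] = "shore"
    out[has & (d == 0)] = "island"
    return pd.Series(out, index=ann.probe_ids, name="island_context")


def classify_promoter_island(probe_id: str, ann: ProbeAnnotation) -> bool:
    """Promoter-island rule: inside a CpG island AND < 2000 bp from a TSS."""
    if classify_island_context(probe_id, ann) != "island":
        return False
    tss = ann.tss_positions(probe_id)
    if tss.size == 0:
        return False
    pos = float(ann.probes.loc[probe_id, "pos"])
    return bool(np.min(np.abs(tss - pos)) < 2000)


def classify_gene_feature(probe_id: str, ann: ProbeAnnotation) -> dict[str, str]:
    """Return {gene: feature} assignments for a probe; validates tokens."""
    return ann.gene_assignments(probe_id)


def is_promoter_feature(feature: str) -> bool:
    if feature not in GENE_FEATURES:
        raise ValueError(f"unknown gene feature token {feature!r}")
    return feature in PROMOTER_FEATURES
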