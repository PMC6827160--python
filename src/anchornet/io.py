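"""Readers/writers for every external format the pipeline touches.

Formats
-------
* expression / gene-level CNV matrices: TSV, first column gene ids, header
  row sample ids, missing values written as ``NA``
* copy-number segments: SEG (sample, chromosome, start, end, segment mean),
  1-based inclusive coordinates
* gene annotation: BED-like TSV (gene, chrom, start, end, strand),
  1-based inclusive
* gene-set signatures: GMT
* networks: SIF plus a 3-column TSV edge list carrying edge frequencies
* survival tables: TSV (sample_id, time, event[, endpoint])
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "ExpressionMatrix",
    "GeneCNVMatrix",
    "CNVSegmentSet",
    "GeneAnnotation",
    "Signature",
    "read_expression",
    "write_expression",
    "read_cnv",
    "write_cnv",
    "read_seg",
    "read_annotation",
    "write_annotation",
    "map_segments_to_genes",
    "read_gmt",
    "write_gmt",
    "write_network",
    "read_network",
    "read_survival",
    "write_survival",
    "validate_survival",
]

NA_SENTINEL = "NA"


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """A gene x sample matrix of real values; NaN marks missing entries.

    Invariants: unique gene and sample ids, value shape matches the id
    lists, every non-missing entry finite.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {label} id: {dup!r}")
        nonmissing = self.values[~np.isnan(self.values)]
        if not np.all(np.isfinite(nonmissing)):
            raise ValueError("non-missing values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OmicsMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset(self, genes=None, samples=None) -> "OmicsMatrix":
        """Return a copy restricted/reordered to the given id lists."""
        df = self.to_frame()
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise KeyError(f"unknown gene ids: {missing[:5]}")
            df = df.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise KeyError(f"unknown sample ids: {missing[:5]}")
            df = df[list(samples)]
        return type(self).from_frame(df)

    def copy(self) -> "OmicsMatrix":
        return type(self)(list(self.gene_ids), list(self.sample_ids), self.values.copy())

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


class ExpressionMatrix(OmicsMatrix):
    """log2-scale expression, genes x samples."""


class GeneCNVMatrix(OmicsMatrix):
    """Gene-level copy-number log-ratios, genes x samples."""


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _read_matrix(path, cls):
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_SENTINEL],
                     keep_default_na=False, dtype=str)
    if df.columns.size == 0:
        raise ValueError(f"{path}: malformed header (no sample columns)")
    dup = _first_duplicate(list(df.index))
    if dup is not None:
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    dup = _first_duplicate(list(df.columns))
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    try:
        values = df.to_numpy(dtype=object)
        values = np.where(pd.isna(values), np.nan, values).astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix: {exc}") from exc
    return cls(list(df.index), list(df.columns), values)


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x sample expression TSV (``NA`` = missing)."""
    return _read_matrix(path, ExpressionMatrix)


def read_cnv(path) -> GeneCNVMatrix:
    """Read a gene x sample gene-level CNV TSV (``NA`` = missing)."""
    return _read_matrix(path, GeneCNVMatrix)


def _write_matrix(mat: OmicsMatrix, path, index_name: str = "gene_id") -> None:
    df = mat.to_frame()
    df.index.name = index_name
    # shortest-roundtrip float formatting keeps write/read bit-identical
    df.to_csv(path, sep="\t", na_rep=NA_SENTINEL,
              float_format=lambda v: repr(float(v)))


def write_expression(mat: OmicsMatrix, path) -> None:
    _write_matrix(mat, path)


def write_cnv(mat: OmicsMatrix, path) -> None:
    _write_matrix(mat, path)


# ---------------------------------------------------------------------------
# copy-number segments and gene annotation
# ---------------------------------------------------------------------------

_SEG_ALIASES = {
    "sample": {"sample", "id", "sample_id"},
    "chrom": {"chrom", "chromosome", "chr"},
    "start": {"start", "loc.start", "loc_start"},
    "end": {"end", "loc.end", "loc_end"},
    "logr": {"logr", "seg.mean", "seg_mean", "log2ratio"},
}


@dataclass
class CNVSegmentSet:
    """Per-sample CBS segments with 1-based inclusive coordinates.

    ``segments`` maps sample id -> DataFrame(chrom, start, end, logR),
    sorted by (chrom, start); segments within a sample/chromosome must not
    overlap and all logR values must be finite.
    """

    segments: dict = field(default_factory=dict)

    def __post_init__(self):
        for sample, df in self.segments.items():
            df = df.reset_index(drop=True)
            if (df["start"] > df["end"]).any():
                raise ValueError(f"sample {sample}: segment with start > end")
            if not np.all(np.isfinite(df["logR"].to_numpy(dtype=float))):
                raise ValueError(f"sample {sample}: non-finite logR")
            df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
            for chrom, grp in df.groupby("chrom", sort=False):
                starts = grp["start"].to_numpy()
                ends = grp["end"].to_numpy()
                if np.any(starts[1:] <= ends[:-1]):
                    raise ValueError(
                        f"sample {sample}, chromosome {chrom}: overlapping segments"
                    )
            self.segments[sample] = df

    @property
    def sample_ids(self) -> list:
        return list(self.segments)


def read_seg(path) -> CNVSegmentSet:
    """Read a SEG file. Column names are matched case-insensitively against
    common aliases (``ID/chrom/loc.start/loc.end/seg.mean`` etc.)."""
    df = pd.read_csv(path, sep="\t")
    colmap = {}
    for canon, aliases in _SEG_ALIASES.items():
        for col in df.columns:
            if col.strip().lower() in aliases:
                colmap[canon] = col
                break
        else:
            raise ValueError(f"{path}: missing SEG column for {canon!r}")
    out = pd.DataFrame(
        {
            "sample": df[colmap["sample"]].astype(str),
            "chrom": df[colmap["chrom"]].astype(str),
            "start": df[colmap["start"]].astype(int),
            "end": df[colmap["end"]].astype(int),
            "logR": df[colmap["logr"]].astype(float),
        }
    )
    segs = {
        sample: grp[["chrom", "start", "end", "logR"]].reset_index(drop=True)
        for sample, grp in out.groupby("sample", sort=False)
    }
    return CNVSegmentSet(segs)


@dataclass
class GeneAnnotation:
    """Gene coordinates (1-based inclusive) with one row per gene."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self):
        required = ["gene_id", "chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        t = self.table.copy()
        t["gene_id"] = t["gene_id"].astype(str)
        t["chrom"] = t["chrom"].astype(str)
        dup = _first_duplicate(list(t["gene_id"]))
        if dup is not None:
            raise ValueError(f"duplicate gene id in annotation: {dup!r}")
        if (t["start"] > t["end"]).any():
            raise ValueError("annotation row with start > end")
        self.table = t.reset_index(drop=True)

    @property
    def gene_ids(self) -> list:
        return list(self.table["gene_id"])

    def chrom_of(self) -> dict:
        return dict(zip(self.table["gene_id"], self.table["chrom"]))


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t")
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def map_segments_to_genes(segs: CNVSegmentSet, ann: GeneAnnotation,
                          sample_ids=None) -> GeneCNVMatrix:
    """Summarize segment-level copy number to gene level.

    Each gene's value per sample is the segment-length-weighted mean logR of
    all segments overlapping the gene body (1-based inclusive overlap).
    Genes with no overlapping segment are missing (NaN); a listed sample with
    no segments at all yields a missing column with a warning. Strand is
    ignored: copy number is strand-agnostic.
    """
    if ann.table.empty:
        raise ValueError("annotation contains no genes")
    samples = list(sample_ids) if sample_ids is not None else segs.sample_ids
    genes = ann.gene_ids
    out = np.full((len(genes), len(samples)), np.nan)
    gene_rows = ann.table
    for j, sample in enumerate(samples):
        df = segs.segments.get(sample)
        if df is None or df.empty:
            warnings.warn(f"sample {sample!r} has no segments; gene CNV left missing")
            continue
        by_chrom = {
            chrom: (grp["start"].to_numpy(), grp["end"].to_numpy(),
                    grp["logR"].to_numpy())
            for chrom, grp in df.groupby("chrom", sort=False)
        }
        for i, (chrom, gstart, gend) in enumerate(
            zip(gene_rows["chrom"], gene_rows["start"], gene_rows["end"])
        ):
            hit = by_chrom.get(chrom)
            if hit is None:
                continue
            starts, ends, logr = hit
            lo = np.searchsorted(ends, gstart, side="left")
            hi = np.searchsorted(starts, gend, side="right")
            if hi <= lo:
                continue
            ov = (np.minimum(ends[lo:hi], gend)
                  - np.maximum(starts[lo:hi], gstart) + 1)
            keep = ov > 0
            if not keep.any():
                continue
            w = ov[keep].astype(float)
            out[i, j] = float(np.dot(w, logr[lo:hi][keep]) / w.sum())
    return GeneCNVMatrix(genes, samples, out)


# ---------------------------------------------------------------------------
# signatures (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Signature:
    """A named gene set with optional per-gene weights."""

    name: str
    genes: frozenset
    description: str = ""
    weights: tuple = ()  # ((gene, weight), ...) when provided

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_genes(cls, name, genes, description="", weights=None) -> "Signature":
        genes = [str(g) for g in genes]
        w = tuple(sorted((weights or {}).items()))
        return cls(name=name, genes=frozenset(genes), description=description, weights=w)


def read_gmt(path) -> list:
    """Read a GMT file (``name<TAB>description<TAB>gene...`` per line).

    Duplicate genes within a line are collapsed; a line with no genes is an
    error naming the line number.
    """
    sigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise ValueError(f"{path}: line {lineno}: GMT entry with no genes")
            genes = [p.strip() for p in parts[2:] if p.strip()]
            sigs.append(Signature.from_genes(parts[0], genes, description=parts[1]))
    return sigs


def write_gmt(signatures, path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            genes = "\t".join(sorted(sig.genes))
            fh.write(f"{sig.name}\t{sig.description}\t{genes}\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(net, sif_path, tsv_path=None) -> None:
    """Write a consensus network as SIF, and optionally as a 3-column TSV
    edge list (source, target, frequency). Rows are in stable lexicographic
    (source, target) order."""
    edges = sorted(net.edges.items())
    with open(sif_path, "w") as fh:
        for (src, dst), _f in edges:
            fh.write(f"{src}\tregulates\t{dst}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("source\ttarget\tfrequency\n")
            for (src, dst), f in edges:
                fh.write(f"{src}\t{dst}\t{repr(float(f))}\n")


def read_network(tsv_path):
    """Read a 3-column TSV edge list back into a ConsensusNetwork."""
    from .bn import ConsensusNetwork

    df = pd.read_csv(tsv_path, sep="\t")
    edges = {
        (str(r.source), str(r.target)): float(r.frequency)
        for r in df.itertuples(index=False)
    }
    return ConsensusNetwork(edges=edges, threshold=0.0, n_runs=0, seeds=())


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table: sample_id / time / event (+ endpoint)."""
    required = ["sample_id", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"survival table missing columns: {missing}")
    out = df.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(int)
    if "endpoint" not in out.columns:
        out["endpoint"] = "OS"
    if (out["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not out["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    if out.duplicated(["sample_id", "endpoint"]).any():
        raise ValueError("duplicate (sample, endpoint) rows in survival table")
    return out.reset_index(drop=True)


def read_survival(path) -> pd.DataFrame:
    return validate_survival(pd.read_csv(path, sep="\t"))


def write_survival(df: pd.DataFrame, path) -> None:
    validate_survival(df).to_csv(path, sep="\t", index=False)
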