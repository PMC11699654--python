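"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate convention: every interval in memory is 0-based, half-open
``[start, end)``. Formats that use other conventions (GTF: 1-based
inclusive; variant tables: 1-based positions) are converted at the
boundary by the readers here, and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("epinteg")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name (non-empty).
    start, end : int
        0-based; ``start`` inclusive, ``end`` exclusive; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-``, ``.``.
    id : str
        Identifier, unique within a set.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS anchor.

    ``tss`` is the 0-based position of the transcription start site; for a
    minus-strand gene this is the rightmost base of the gene body.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class VariantRecord:
    """A point variant with its GWAS association p-value (0-based position)."""

    rsid: str
    chrom: str
    pos: int
    assoc_p: float

    def __post_init__(self):
        if not (0.0 <= self.assoc_p <= 1.0):
            raise ValueError(f"assoc_p must be in [0,1], got {self.assoc_p}")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


@dataclass
class CountMatrix:
    """features x samples non-negative integer counts with sample metadata.

    ``counts`` is a pandas DataFrame (index = feature ids, columns = sample
    names, dtype integer). ``conditions`` / ``replicates`` map sample name
    to its condition label and replicate index.
    """

    counts: pd.DataFrame
    conditions: dict[str, str]
    replicates: dict[str, int]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]

    def condition_levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.conditions[s], None)
        return list(seen)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style); members are unique within a set."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class DrugTargetNetwork:
    """Bipartite drug-target edges plus flat drug metadata."""

    edges: list[tuple[str, str]]
    drug_meta: pd.DataFrame  # index drug_id; columns phase, class (free-form)

    def targets_of(self, drug_id: str) -> set[str]:
        return {g for d, g in self.edges if d == drug_id}

    def drugs_targeting(self, gene_id: str) -> set[str]:
        return {d for d, g in self.edges if g == gene_id}

    @property
    def target_genes(self) -> set[str]:
        return {g for _, g in self.edges}


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample, condition, replicate."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample"].duplicated().any():
        dup = sheet.loc[sheet["sample"].duplicated(), "sample"].iloc[0]
        raise FormatError(f"duplicate sample in sheet: {dup!r}")
    return sheet


def load_counts(path: str | Path, sample_sheet: pd.DataFrame | str | Path) -> CountMatrix:
    """Load a feature x sample count TSV against a mandatory sample sheet.

    The first column holds feature ids; remaining columns are samples.
    Every sample in the sheet must be present in the file; columns not in
    the sheet are dropped. Non-integer or negative entries are format
    errors. Conditions with fewer than 2 replicates are flagged with a
    warning (they cannot be tested downstream).
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = load_sample_sheet(sample_sheet)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty counts file") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: counts file has no data")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature ID {dup!r}")
    for sample in sample_sheet["sample"]:
        if sample not in df.columns:
            raise FormatError(f"{path}: sample {sample!r} from sheet missing in counts file")
    df = df[list(sample_sheet["sample"])]
    values = df.to_numpy()
    import numpy as np

    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries in counts")
    if np.any(values < 0):
        raise FormatError(f"{path}: negative counts")
    if not np.allclose(values, np.round(values)):
        raise FormatError(f"{path}: non-integer counts")
    df = df.astype("int64")

    conditions = dict(zip(sample_sheet["sample"], sample_sheet["condition"]))
    replicates = {
        s: int(r) for s, r in zip(sample_sheet["sample"], sample_sheet["replicate"])
    }
    counts_per_cond = sample_sheet.groupby("condition").size()
    for cond, n in counts_per_cond.items():
        if n < 2:
            logger.warning("condition %r has %d replicate(s); cannot be tested", cond, n)
    return CountMatrix(counts=df, conditions=conditions, replicates=replicates)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature_id")


def write_sample_sheet(cm: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": cm.samples,
            "condition": [cm.conditions[s] for s in cm.samples],
            "replicate": [cm.replicates[s] for s in cm.samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intervals (BED)
# ---------------------------------------------------------------------------


def load_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals; column 4 (if present) becomes the id.

    BED is already 0-based half-open, so coordinates pass through
    unchanged. Lines with ``start >= end`` raise with the line number.
    """
    intervals: list[GenomicInterval] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else (
                f"{chrom}:{start}-{end}"
            )
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            if name in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate interval id {name!r}")
            seen_ids.add(name)
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    return intervals


def write_intervals_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part.split(None, 1)[1].strip().strip('"')
    return None


def extract_tss_from_gtf(path: str | Path) -> list[GeneModel]:
    """Extract one TSS per gene from ``gene`` features of a GTF.

    GTF coordinates are 1-based inclusive; the TSS is converted to a
    0-based position: ``start - 1`` on the + strand, ``end - 1`` on the -
    strand. The first record per gene_id wins; later duplicates are logged
    and dropped.
    """
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: GTF line has < 9 fields")
            if fields[2] != "gene":
                continue
            chrom, start_s, end_s, strand, attrs = (
                fields[0],
                fields[3],
                fields[4],
                fields[6],
                fields[8],
            )
            gene_id = _gtf_attribute(attrs, "gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: gene strand must be + or -")
            start, end = int(start_s), int(end_s)
            tss = start - 1 if strand == "+" else end - 1
            if gene_id in models:
                logger.warning("%s:%d: duplicate gene_id %r; keeping first", path, lineno, gene_id)
                continue
            models[gene_id] = GeneModel(gene_id, chrom, tss, strand)
    return list(models.values())


def write_gene_models_gtf(models: Iterable[GeneModel], path: str | Path, gene_length: int = 1000) -> None:
    """Write minimal single-feature GTF gene lines reproducing each TSS."""
    with open(path, "w") as fh:
        for m in models:
            if m.strand == "+":
                start, end = m.tss + 1, m.tss + gene_length  # 1-based inclusive
            else:
                end = m.tss + 1
                start = max(1, end - gene_length + 1)
            fh.write(
                f"{m.chrom}\tepinteg\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f'gene_id "{m.gene_id}";\n'
            )


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def load_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then members, tab-separated."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in coll.sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning("%s:%d: duplicate members in set %r deduplicated", path, lineno, name)
            coll.sets[name] = unique
            coll.descriptions[name] = desc
    return coll


def write_gene_sets_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Regulons, variants, drug targets, enhancer links (flat TSVs)
# ---------------------------------------------------------------------------


def load_regulons(path: str | Path) -> pd.DataFrame:
    """Read a regulon TSV with columns tf, target, mode_sign (+-1), weight."""
    df = pd.read_csv(path, sep="\t")
    required = {"tf", "target", "mode_sign", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: regulon table missing columns {sorted(missing)}")
    if not df["mode_sign"].isin([-1, 1]).all():
        raise FormatError(f"{path}: mode_sign must be -1 or +1")
    if (df["weight"] < 0).any():
        raise FormatError(f"{path}: negative regulon weight")
    if df.duplicated(subset=["tf", "target"]).any():
        raise FormatError(f"{path}: duplicate (tf, target) pair")
    return df


def load_variants(path: str | Path, one_based: bool = False) -> list[VariantRecord]:
    """Read a variant TSV (rsid, chrom, pos, assoc_p).

    ``one_based=True`` converts 1-based source positions to the internal
    0-based convention by subtracting 1.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"rsid", "chrom", "pos", "assoc_p"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: variant table missing columns {sorted(missing)}")
    if df["rsid"].duplicated().any():
        dup = df.loc[df["rsid"].duplicated(), "rsid"].iloc[0]
        raise FormatError(f"{path}: duplicate rsid {dup!r}")
    offset = 1 if one_based else 0
    return [
        VariantRecord(str(r.rsid), str(r.chrom), int(r.pos) - offset, float(r.assoc_p))
        for r in df.itertuples()
    ]


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(v.rsid, v.chrom, v.pos, v.assoc_p) for v in variants],
        columns=["rsid", "chrom", "pos", "assoc_p"],
    ).to_csv(path, sep="\t", index=False)


def load_drug_targets(path: str | Path) -> DrugTargetNetwork:
    """Read drug-target edges (drug_id, gene_id, phase, class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug_id", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: drug-target table missing columns {sorted(missing)}")
    if df.duplicated(subset=["drug_id", "gene_id"]).any():
        raise FormatError(f"{path}: duplicate drug-target edge")
    edges = list(zip(df["drug_id"], df["gene_id"]))
    meta_cols = [c for c in ("phase", "class") if c in df.columns]
    drug_meta = (
        df[["drug_id", *meta_cols]].drop_duplicates("drug_id").set_index("drug_id")
    )
    return DrugTargetNetwork(edges=edges, drug_meta=drug_meta)


def load_enhancer_links(path: str | Path) -> pd.DataFrame:
    """Read an enhancer-gene link TSV (enhancer_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"enhancer_id", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: link table missing columns {sorted(missing)}")
    return df.drop_duplicates()
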