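"""Domain types and on-disk formats for the methylation/expression pipeline.

Single source of truth for coordinate conventions:

* All coordinates are stored internally as **0-based half-open** intervals.
* Array-manifest CpG positions are 1-based on disk and converted on read
  (``pos - 1``); BED input is taken as-is; GTF input (1-based inclusive) has
  its start shifted by -1.
* A CpG is treated as the 1-bp interval ``[pos, pos + 1)``.
* Gene TSS is strand-aware: ``start`` on '+', ``end - 1`` on '-'.

Probe strand is carried but ignored in overlap and distance computations,
since CpG methylation is symmetric across strands on bisulfite arrays.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


#: biotypes treated as noncoding-RNA gene classes
NCRNA_BIOTYPES = frozenset({"lncRNA", "antisense", "lincRNA", "other_ncRNA"})

#: controlled vocabulary for gene biotypes
BIOTYPES = frozenset({"protein_coding"}) | NCRNA_BIOTYPES

# Common annotation biotype spellings mapped onto the controlled vocabulary.
_BIOTYPE_ALIASES = {
    "protein_coding": "protein_coding",
    "lncrna": "lncRNA",
    "lincrna": "lincRNA",
    "antisense": "antisense",
    "antisense_rna": "antisense",
}


def normalize_biotype(raw: str) -> str:
    """Map an annotation biotype string onto the controlled vocabulary.

    Unrecognised non-coding biotypes (miRNA, snoRNA, pseudogene, ...) fall
    into ``other_ncRNA``.
    """
    key = raw.strip().lower()
    return _BIOTYPE_ALIASES.get(key, "other_ncRNA")


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Normalise a chromosome name to ``'chr'`` or ``'plain'`` style."""
    if style not in ("chr", "plain"):
        raise ValueError(f"unknown chromosome style: {style!r}")
    base = name[3:] if name.lower().startswith("chr") else name
    return f"chr{base}" if style == "chr" else base


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeRecord:
    """A 450K-style CpG probe.

    ``pos`` is the internal 0-based coordinate of the interrogated cytosine
    (converted from the manifest's 1-based convention on read).
    ``manifest_genes`` holds the array vendor's gene assignments as
    ``(gene_name, claimed_biotype)`` pairs; it may be empty.
    """

    probe_id: str
    chrom: str
    pos: int
    strand: str = "unknown"
    manifest_genes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"probe {self.probe_id}: negative position")
        if not self.chrom:
            raise ValidationError(f"probe {self.probe_id}: empty chromosome")
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(
                f"probe {self.probe_id}: bad strand {self.strand!r}"
            )

    def has_coding_assignment(self) -> bool:
        return any(bt == "protein_coding" for _, bt in self.manifest_genes)


@dataclass(frozen=True)
class GeneModel:
    """A gene with 0-based half-open coordinates and a controlled biotype."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand")
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"gene {self.gene_id}: biotype {self.biotype!r} not in vocabulary"
            )

    def tss(self) -> int:
        """Strand-aware transcription start site; always in [start, end)."""
        return self.start if self.strand == "+" else self.end - 1

    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: two-level group label, age and cohort strata."""

    sample_id: str
    group: str
    age: float
    er_status: str = "neg"
    cohort: str = "discovery"


@dataclass(frozen=True)
class RegulatoryTrack:
    """A named set of genomic intervals (0-based half-open)."""

    name: str
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValidationError(
                    f"track {self.name}: interval {chrom}:{start}-{end} empty"
                )


class _Matrix:
    """Base for id-indexed numeric matrices backed by a DataFrame."""

    _row_name = "id"

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate row ids: {dups[:5]}")
        if values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        self.values = values

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        r, c = self.values.shape
        return f"{type(self).__name__}({r} {self._row_name}s x {c} samples)"


class BetaMatrix(_Matrix):
    """Probes x samples methylation fractions; values in [0,1] or NaN."""

    _row_name = "probe"

    def __init__(self, values: pd.DataFrame):
        super().__init__(values.astype(float))
        bad = (self.values < 0) | (self.values > 1)
        if bad.any().any():
            probe = bad.any(axis=1).idxmax()
            sample = bad.loc[probe].idxmax()
            raise ValidationError(
                f"beta value {self.values.at[probe, sample]} outside [0,1] "
                f"at probe {probe!r}, sample {sample!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return self.row_ids


class CountsMatrix(_Matrix):
    """Genes x samples non-negative integer read counts."""

    _row_name = "gene"

    def __init__(self, values: pd.DataFrame):
        arr = values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("counts contain missing values")
        if np.any(arr < 0):
            gene = values.index[(arr < 0).any(axis=1).argmax()]
            raise ValidationError(f"negative count at gene {gene!r}")
        if np.any(arr != np.round(arr)):
            gene = values.index[(arr != np.round(arr)).any(axis=1).argmax()]
            raise ValidationError(f"non-integer count at gene {gene!r}")
        super().__init__(values.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return self.row_ids


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ("probe_id", "chrom", "pos", "strand", "genes")


def _parse_manifest_genes(raw: str) -> tuple[tuple[str, str], ...]:
    """Parse a semicolon-delimited assignment string.

    Entries are ``NAME`` or ``NAME:biotype``; a bare name claims
    protein_coding, the manifest's default for RefSeq assignments.
    """
    out = []
    for entry in raw.split(";"):
        entry = entry.strip()
        if not entry:
            continue
        if ":" in entry:
            name, bt = entry.split(":", 1)
            out.append((name.strip(), normalize_biotype(bt)))
        else:
            out.append((entry, "protein_coding"))
    return tuple(out)


def read_manifest(path: str | Path, chrom_style: str = "chr") -> list[ProbeRecord]:
    """Read a probe manifest CSV into :class:`ProbeRecord` objects.

    Required columns: probe_id, chrom, pos (1-based), strand, genes.
    Positions are converted to internal 0-based coordinates.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _MANIFEST_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"manifest {path}: missing required column(s) {missing}"
            )
        records: list[ProbeRecord] = []
        seen: set[str] = set()
        for row in reader:
            pid = row["probe_id"].strip()
            if pid in seen:
                raise FormatError(f"manifest {path}: duplicate probe_id {pid!r}")
            seen.add(pid)
            pos1 = int(row["pos"])
            if pos1 < 1:
                raise ValidationError(f"probe {pid}: 1-based position {pos1} < 1")
            strand = row["strand"].strip() or "unknown"
            records.append(
                ProbeRecord(
                    probe_id=pid,
                    chrom=normalize_chrom(row["chrom"].strip(), chrom_style),
                    pos=pos1 - 1,
                    strand=strand if strand in ("+", "-") else "unknown",
                    manifest_genes=_parse_manifest_genes(row["genes"] or ""),
                )
            )
    return records


def write_manifest(records: Iterable[ProbeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for r in records:
            genes = ";".join(f"{n}:{bt}" for n, bt in r.manifest_genes)
            writer.writerow([r.probe_id, r.chrom, r.pos + 1, r.strand, genes])


def read_gene_annotation(
    path: str | Path, dialect: str = "bed6+biotype", chrom_style: str = "chr"
) -> list[GeneModel]:
    """Read a gene annotation in BED6+biotype or GTF-genes dialect.

    BED is 0-based half-open and used verbatim; GTF is 1-based inclusive and
    normalised by shifting start by -1.
    """
    if dialect == "bed6+biotype":
        return _read_bed_genes(path, chrom_style)
    if dialect == "gtf-genes":
        return _read_gtf_genes(path, chrom_style)
    raise FormatError(f"unknown annotation dialect: {dialect!r}")


def _read_bed_genes(path: str | Path, chrom_style: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise FormatError(
                    f"{path}:{ln}: expected 7 BED6+biotype fields, got {len(parts)}"
                )
            chrom, start, end, name, _score, strand, biotype = parts[:7]
            genes.append(
                GeneModel(
                    gene_id=name,
                    name=name,
                    chrom=normalize_chrom(chrom, chrom_style),
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    biotype=normalize_biotype(biotype),
                )
            )
    return genes


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for item in raw.strip().rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def _read_gtf_genes(path: str | Path, chrom_style: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GTF fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = parts
            if feature != "gene":
                continue
            attrs = _gtf_attributes(attr)
            gid = attrs.get("gene_id", f"gene_{ln}")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    name=attrs.get("gene_name", gid),
                    chrom=normalize_chrom(chrom, chrom_style),
                    start=int(start) - 1,  # 1-based inclusive -> 0-based half-open
                    end=int(end),
                    strand=strand,
                    biotype=normalize_biotype(attrs.get("gene_biotype", "")),
                )
            )
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write genes as BED6+biotype (deterministic column order)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\t{g.biotype}\n"
            )


def read_matrix(path: str | Path, kind: str) -> BetaMatrix | CountsMatrix:
    """Read a TSV matrix (first column row ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if kind == "beta":
        return BetaMatrix(df)
    if kind == "counts":
        return CountsMatrix(df)
    raise FormatError(f"unknown matrix kind: {kind!r}")


def write_matrix(matrix: _Matrix | pd.DataFrame, path: str | Path) -> None:
    df = matrix.values if isinstance(matrix, _Matrix) else matrix
    # %.17g guarantees read(write(x)) == x bit-for-bit on float64 values
    df.to_csv(path, sep="\t", float_format="%.17g",
              index_label=getattr(matrix, "_row_name", "id"))


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    required = {"sample_id", "group", "age"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample metadata {path}: missing column(s) {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            group=str(r.group),
            age=float(r.age),
            er_status=str(getattr(r, "er_status", "neg")),
            cohort=str(getattr(r, "cohort", "discovery")),
        )
        for r in df.itertuples()
    ]


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "group": [m.group for m in meta],
            "age": [m.age for m in meta],
            "er_status": [m.er_status for m in meta],
            "cohort": [m.cohort for m in meta],
        }
    ).to_csv(path, index=False)


def group_levels(meta: Sequence[SampleMeta]) -> tuple[str, str]:
    """The two group levels, sorted; errors if not exactly two."""
    levels = sorted({m.group for m in meta})
    if len(levels) != 2:
        raise ValidationError(f"expected exactly two group levels, got {levels}")
    return levels[0], levels[1]


def read_tracks(path: str | Path, chrom_style: str = "chr") -> list[RegulatoryTrack]:
    """Read BED3/BED4 intervals into named tracks.

    BED4 groups intervals by the name column (one track per label); BED3
    yields a single track named after the file stem.
    """
    by_name: dict[str, list[tuple[str, int, int]]] = {}
    stem = Path(path).stem
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 BED fields")
            chrom = normalize_chrom(parts[0], chrom_style)
            name = parts[3] if len(parts) >= 4 else stem
            by_name.setdefault(name, []).append((chrom, int(parts[1]), int(parts[2])))
    return [RegulatoryTrack(name, tuple(iv)) for name, iv in sorted(by_name.items())]


def write_tracks(tracks: Iterable[RegulatoryTrack], path: str | Path) -> None:
    """Write tracks as BED4 (name column = track label)."""
    with open(path, "w") as fh:
        for t in tracks:
            for chrom, start, end in t.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{t.name}\n")
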