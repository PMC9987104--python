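"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are centralized here: bedGraph and BED are
0-based half-open; GTF is 1-based closed and converted on read (via
pyranges); internally everything is 0-based half-open and coverage is
stored in transcript orientation (minus-strand tracks are reversed on
load so offset 0 is always the 3'UTR's 5' end).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pdui import CoverageProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_bed6",
    "write_bed6",
    "read_gtf_utrs",
    "read_annotation",
    "read_coverage",
    "write_coverage",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "read_gene_list",
    "write_gene_list",
    "write_json",
    "read_json",
]


class ParseError(ValueError):
    """Malformed input file; the message carries the path and line number."""


def _fail(path: Path | str, lineno: int, msg: str) -> None:
    raise ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# bedGraph / BED / GTF
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Parse a bedGraph (0-based half-open) into chrom/start/end/value."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                _fail(path, lineno, f"expected 4 tab-separated fields, got {len(parts)}")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                _fail(path, lineno, f"non-numeric coordinates/value: {line!r}")
            if end <= start or start < 0:
                _fail(path, lineno, f"invalid interval [{start},{end})")
            if value < 0:
                _fail(path, lineno, "negative coverage value")
            rows.append((parts[0], start, end, value))
    if not rows:
        raise ParseError(f"{path}: empty bedGraph")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(profiles: Iterable[CoverageProfile], path: str | Path) -> None:
    """Write profiles as a bedGraph in genome order (runs of equal depth
    merged, zero-depth runs omitted)."""
    with open(path, "w") as fh:
        for p in profiles:
            depth = p.depth if p.strand == "+" else p.depth[::-1]
            pos = p.utr_start
            i = 0
            while i < depth.size:
                j = i
                while j < depth.size and depth[j] == depth[i]:
                    j += 1
                if depth[i] > 0:
                    v = depth[i]
                    val = f"{int(v)}" if float(v).is_integer() else f"{v:.6g}"
                    fh.write(f"{p.chrom}\t{pos + i}\t{pos + j}\t{val}\n")
                i = j


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Parse a BED6 annotation into chrom/start/end/name/score/strand."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                _fail(path, lineno, f"expected >=6 tab-separated fields, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates: {line!r}")
            if end <= start or start < 0:
                _fail(path, lineno, f"invalid interval [{start},{end})")
            if parts[5] not in ("+", "-"):
                _fail(path, lineno, f"strand must be + or -, got {parts[5]!r}")
            rows.append((parts[0], start, end, parts[3], parts[4], parts[5]))
    if not rows:
        raise ParseError(f"{path}: empty BED file")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed6(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(
        path,
        sep="\t",
        header=False,
        index=False,
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def read_gtf_utrs(path: str | Path, feature: str = "three_prime_utr") -> pd.DataFrame:
    """Extract 3'UTR intervals from a GTF (1-based closed on disk,
    0-based half-open in the returned frame, courtesy of pyranges)."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    utr = df[df["Feature"] == feature]
    if utr.empty:
        raise ParseError(f"{path}: no {feature!r} features found")
    name = "gene_id" if "gene_id" in utr.columns else "transcript_id"
    out = pd.DataFrame(
        {
            "chrom": utr["Chromosome"].astype(str),
            "start": utr["Start"].astype(int),
            "end": utr["End"].astype(int),
            "name": utr[name].astype(str),
            "score": ".",
            "strand": utr["Strand"].astype(str),
        }
    )
    return out.reset_index(drop=True)


def read_annotation(path: str | Path) -> pd.DataFrame:
    suffix = Path(path).suffix.lower()
    if suffix in (".gtf", ".gff"):
        return read_gtf_utrs(path)
    return read_bed6(path)


def read_coverage(
    bedgraph_path: str | Path, annotation_path: str | Path
) -> list[CoverageProfile]:
    """Intersect bedGraph coverage with each annotated 3'UTR.

    Gaps are zero-filled; minus-strand profiles are reversed into
    transcript orientation.  UTRs on chromosomes absent from the
    coverage track are reported with a warning and zero depth.
    """
    cov = read_bedgraph(bedgraph_path)
    anno = read_annotation(annotation_path)
    by_chrom = {c: g for c, g in cov.groupby("chrom", sort=False)}
    profiles = []
    for row in anno.itertuples(index=False):
        length = row.end - row.start
        depth = np.zeros(length)
        chrom_cov = by_chrom.get(row.chrom)
        if chrom_cov is None:
            logger.warning(
                "%s: chromosome %r not present in coverage track", row.name, row.chrom
            )
        else:
            sel = chrom_cov[(chrom_cov["end"] > row.start) & (chrom_cov["start"] < row.end)]
            for iv in sel.itertuples(index=False):
                lo = max(iv.start, row.start) - row.start
                hi = min(iv.end, row.end) - row.start
                depth[lo:hi] = iv.value
        if row.strand == "-":
            depth = depth[::-1]
        profiles.append(
            CoverageProfile(
                gene_id=row.name,
                depth=depth,
                chrom=row.chrom,
                strand=row.strand,
                utr_start=row.start,
                utr_end=row.end,
            )
        )
    return profiles


def write_coverage(
    profiles: Sequence[CoverageProfile],
    bedgraph_path: str | Path,
    bed_path: str | Path,
) -> None:
    """Write a coverage track and its matching 3'UTR annotation."""
    write_bedgraph(profiles, bedgraph_path)
    anno = pd.DataFrame(
        {
            "chrom": [p.chrom for p in profiles],
            "start": [p.utr_start for p in profiles],
            "end": [p.utr_end for p in profiles],
            "name": [p.gene_id for p in profiles],
            "score": ".",
            "strand": [p.strand for p in profiles],
        }
    )
    write_bed6(anno, bed_path)


# ---------------------------------------------------------------------------
# matrices / gene sets / sequences / lists
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample TSV (header row of sample ids, genes as rows).

    "NA" and empty cells become NaN; duplicate gene ids and ragged rows
    are rejected.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: empty or header-only matrix")
    width = len(lines[0].split("\t"))
    for lineno, line in enumerate(lines[1:], 2):
        if len(line.split("\t")) != width:
            _fail(path, lineno, f"ragged row: expected {width} fields")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA", ""], keep_default_na=False
    )
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ParseError(f"{path}: duplicate gene ids: {dupes[:5]}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, na_rep="NA")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: one line per set (name, description, members)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _fail(path, lineno, "GMT lines need name, description and >=1 gene")
            name = parts[0]
            if name in sets:
                _fail(path, lineno, f"duplicate gene-set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    if not sets:
        raise ParseError(f"{path}: empty GMT file")
    return sets


def write_gmt(genesets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in genesets.items():
            fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA sequences keyed by id (taken to the first whitespace)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ParseError(f"{path}: empty FASTA file")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not genes:
        raise ParseError(f"{path}: empty gene list")
    seen, out = set(), []
    for g in genes:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    """Serialize (possibly nested dataclass) truth/config objects."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)
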