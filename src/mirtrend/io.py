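"""Readers and writers for the package's interchange formats.

Expression matrices travel as TSV (feature ID column, one column per age
label, optional ``#totals`` comment line carrying per-sample read depths);
reads and annotations as BED3/BED6 (0-based half-open); miRNA annotations
alternatively as GFF3 with a configurable ID attribute; Ct tables as
long-format CSV. All writers prepend a commented provenance line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .loci import Locus, ReadInterval
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

_PROVENANCE = f"# written by mirtrend {__version__}"


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_PROVENANCE + "\n")
        if matrix.totals is not None:
            fh.write("#totals\t" + "\t".join(repr(float(t)) for t in matrix.totals) + "\n")
        matrix.values.rename_axis("feature").to_csv(fh, sep="\t")


def read_expression_tsv(path: str | Path,
                        ages: list[float] | None = None) -> ExpressionMatrix:
    """Read a feature x age TSV; column headers are the age labels in months."""
    path = Path(path)
    totals = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#totals"):
            totals = np.array([float(v) for v in line.rstrip("\n").split("\t")[1:]])
        elif not line.startswith("#"):
            body.append(line)
    if not body:
        raise ValidationError(f"{path}: no header row of age labels")
    from io import StringIO
    df = pd.read_csv(StringIO("".join(body)), sep="\t", index_col=0)
    if ages is None:
        try:
            ages = [float(c) for c in df.columns]
        except ValueError as exc:
            raise ValidationError(
                f"{path}: column headers are not numeric age labels; "
                f"pass ages= explicitly") from exc
    non_numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce")).isna() & df.notna()
    if non_numeric.any().any():
        r, c = np.argwhere(non_numeric.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at feature {df.index[r]!r}, column {df.columns[c]!r}")
    return ExpressionMatrix(values=df.astype(float), ages=ages, totals=totals)


def read_bed(path: str | Path) -> list[ReadInterval]:
    """Read BED3/BED6 intervals; strand '.' becomes unstranded (None)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates")
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end <= start")
            strand = None
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            out.append(ReadInterval(chrom, start, end, strand))
    return out


def write_bed(reads: list[ReadInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread\t0\t{r.strand or '.'}\n")


def read_annotation_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED6 annotation: the name column carries the miRNA ID."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(
                    f"{path}:{lineno}: annotation BED needs a name column")
            out.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return out


def read_annotation_gff3(path: str | Path,
                         id_attr: str = "Name") -> list[tuple[str, int, int, str]]:
    """GFF3 annotation (1-based inclusive -> converted to 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out = []
    for feat in db.all_features():
        ids = feat.attributes.get(id_attr) or feat.attributes.get("ID")
        if not ids:
            raise ValidationError(
                f"{path}: feature at {feat.seqid}:{feat.start} lacks attribute {id_attr!r}")
        out.append((feat.seqid, feat.start - 1, feat.end, ids[0]))
    return out


def write_loci_bed(loci: list[Locus], path: str | Path) -> None:
    """BED6 plus read_count and coverage columns."""
    with open(path, "w") as fh:
        fh.write(_PROVENANCE + "\n")
        for l in loci:
            name = l.annotation_id or "locus"
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{name}\t0\t"
                     f"{l.strand or '.'}\t{l.read_count}\t{l.coverage:.6g}\n")


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    from .qpcr import REQUIRED_COLUMNS
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: Ct table missing columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_PROVENANCE + "\n")
        df.to_csv(fh, sep="\t", index=index)
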