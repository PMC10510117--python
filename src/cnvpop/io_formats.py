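"""Readers and writers for every external representation the pipeline touches.

Internal convention is 0-based half-open everywhere, so interval lengths are
exact subtractions; coordinate conversion happens only at I/O boundaries.
The read-depth caller dialect ("cnvnator") uses 1-based inclusive
``chrom:start-end`` strings and is converted on the way in and out.  All
readers and writers are gzip-transparent (a ``.gz`` suffix selects gzip).
"""

from __future__ import annotations

import gzip
import os
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

SVTYPES = ("DEL", "DUP")

#: tokens accepted for the svtype column, by dialect
_CNVNATOR_TYPES = {"deletion": "DEL", "duplication": "DUP"}


class CnvFormatError(ValueError):
    """Malformed input; carries the offending path and line number."""

    def __init__(self, message: str, path: str | os.PathLike = "", line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.path = str(path)
        self.line = line


@dataclass(frozen=True)
class CNVCall:
    """One CNV event in one sample (internal 0-based half-open coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    svtype: str  # "DEL" or "DUP"
    norm_rd: float = 1.0  # normalized read depth, ~1.0 for diploid background
    pval: float = 0.0
    q0: float = 0.0  # fraction of zero-mapping-quality reads

    def __post_init__(self):
        if self.svtype not in SVTYPES:
            raise ValueError(f"svtype must be one of {SVTYPES}, got {self.svtype!r}")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError(f"q0 must be in [0,1], got {self.q0}")
        if not 0.0 <= self.pval <= 1.0:
            raise ValueError(f"pval must be in [0,1], got {self.pval}")
        if self.norm_rd < 0:
            raise ValueError(f"norm_rd must be >= 0, got {self.norm_rd}")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicFeature:
    """A gene or QTL interval (internal coordinates)."""

    feature_id: str
    kind: str  # "gene" or "qtl"
    chrom: str
    start: int
    end: int
    name: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("gene", "qtl"):
            raise ValueError(f"kind must be 'gene' or 'qtl', got {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name for cross-source matching.

    Strips a leading ``chr`` prefix (case-insensitive) and lowercases the
    rest, so ``chr1``, ``Chr1`` and ``1`` all compare equal.
    """
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.lower()


def chrom_sort_key(chrom: str):
    """Genome ordering: numeric chromosome suffix when present, then name."""
    m = re.match(r"(?:chr)?(\d+)$", chrom, flags=re.IGNORECASE)
    return (0, int(m.group(1)), "") if m else (1, 0, chrom.lower())


def _open_text(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_cnvnator_coords(token: str, path, lineno: int) -> tuple[str, int, int]:
    """``chr1:1001-2000`` (1-based inclusive) -> ('chr1', 1000, 2000)."""
    try:
        chrom, rng = token.rsplit(":", 1)
        lo, hi = rng.split("-", 1)
        start1, end1 = int(lo), int(hi)
    except ValueError:
        raise CnvFormatError(f"unparseable coordinate string {token!r}", path, lineno) from None
    if start1 < 1 or end1 < start1:
        raise CnvFormatError(f"invalid 1-based range {token!r}", path, lineno)
    return chrom, start1 - 1, end1


# CNVnator text output columns:
#   type  coordinates  size  normalized_RD  e-val1  e-val2  e-val3  e-val4  q0
_TSV_COLUMNS = ["sample", "chrom", "start", "end", "svtype", "norm_rd", "pval", "q0"]


def read_cnv_calls(
    path,
    dialect: str = "cnvnator",
    sample_id: str | None = None,
    pval_column: int = 0,
) -> list[CNVCall]:
    """Read per-sample CNV calls into internal coordinates.

    Parameters
    ----------
    dialect:
        ``"cnvnator"`` — 9-column caller output, tab/space separated, with
        1-based inclusive ``chrom:start-end`` coordinates; the filterable
        p-value is taken from e-val column ``pval_column`` (0..3, default the
        first).  ``"tsv"`` — headered table already in internal 0-based
        half-open coordinates with a ``sample`` column.
    sample_id:
        Sample for cnvnator-dialect files (one sample per file); defaults to
        the file's base name without extensions.
    """
    if dialect not in ("cnvnator", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = set(_TSV_COLUMNS) - set(df.columns)
        if missing:
            raise CnvFormatError(f"missing columns: {sorted(missing)}", path)
        return [
            CNVCall(
                sample_id=str(r["sample"]), chrom=str(r["chrom"]),
                start=int(r["start"]), end=int(r["end"]), svtype=str(r["svtype"]),
                norm_rd=float(r["norm_rd"]), pval=float(r["pval"]), q0=float(r["q0"]),
            )
            for r in df.to_dict("records")
        ]

    if not 0 <= pval_column <= 3:
        raise ValueError("pval_column must be in 0..3")
    if sample_id is None:
        base = os.path.basename(str(path))
        sample_id = base.split(".")[0]
    calls: list[CNVCall] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 9:
                raise CnvFormatError(
                    f"expected 9 columns, got {len(fields)}", path, lineno)
            typ = fields[0].lower()
            if typ not in _CNVNATOR_TYPES:
                raise CnvFormatError(f"unknown svtype token {fields[0]!r}", path, lineno)
            chrom, start, end = _parse_cnvnator_coords(fields[1], path, lineno)
            try:
                norm_rd = float(fields[3])
                pval = float(fields[4 + pval_column])
                q0 = float(fields[8])
            except ValueError as exc:
                raise CnvFormatError(f"non-numeric field: {exc}", path, lineno) from None
            calls.append(CNVCall(
                sample_id=sample_id, chrom=chrom, start=start, end=end,
                svtype=_CNVNATOR_TYPES[typ], norm_rd=norm_rd,
                pval=min(max(pval, 0.0), 1.0), q0=q0,
            ))
    return calls


def write_cnv_calls(calls: Iterable[CNVCall], path, dialect: str = "cnvnator") -> None:
    """Write calls; inverse of :func:`read_cnv_calls` for each dialect.

    The cnvnator dialect emits the filter p-value in all four e-val columns
    (the caller's four tests are not distinguished here), so a round trip
    preserves ``pval`` for any ``pval_column`` choice.
    """
    if dialect == "tsv":
        df = pd.DataFrame(
            [
                (c.sample_id, c.chrom, c.start, c.end, c.svtype, c.norm_rd, c.pval, c.q0)
                for c in calls
            ],
            columns=_TSV_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)
        return
    if dialect != "cnvnator":
        raise ValueError(f"unknown dialect {dialect!r}")
    inv_types = {v: k for k, v in _CNVNATOR_TYPES.items()}
    with _open_text(path, "wt") as fh:
        for c in calls:
            coords = f"{c.chrom}:{c.start + 1}-{c.end}"
            fh.write(
                f"{inv_types[c.svtype]}\t{coords}\t{c.size}\t{c.norm_rd:.6g}\t"
                f"{c.pval:.6g}\t{c.pval:.6g}\t{c.pval:.6g}\t{c.pval:.6g}\t{c.q0:.6g}\n"
            )


def read_features(path, kind: str, dialect: str | None = None) -> list[GenomicFeature]:
    """Read gene or QTL annotations from GFF3 (1-based inclusive) or BED
    (already 0-based half-open); the dialect defaults from the extension."""
    if kind not in ("gene", "qtl"):
        raise ValueError(f"kind must be 'gene' or 'qtl', got {kind!r}")
    name = str(path)
    stripped = name[:-3] if name.endswith(".gz") else name
    if dialect is None:
        ext = os.path.splitext(stripped)[1].lower()
        dialect = "bed" if ext == ".bed" else "gff3"
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")

    feats: list[GenomicFeature] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                if len(fields) < 3:
                    raise CnvFormatError("BED needs >= 3 columns", path, lineno)
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                fid = fields[3] if len(fields) > 3 else f"{kind}_{lineno}"
                attrs = {}
                if len(fields) > 4:
                    attrs["score"] = fields[4]
                feats.append(GenomicFeature(
                    feature_id=fid, kind=kind, chrom=chrom,
                    start=start, end=end, name=fid, attributes=attrs))
            else:
                if len(fields) < 9:
                    raise CnvFormatError("GFF3 needs 9 columns", path, lineno)
                chrom = fields[0]
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError:
                    raise CnvFormatError("non-integer GFF3 coordinates", path, lineno) from None
                attrs = {}
                for token in fields[8].split(";"):
                    token = token.strip()
                    if token and "=" in token:
                        k, v = token.split("=", 1)
                        attrs[k] = v
                fid = attrs.get("ID") or attrs.get("Name") or f"{kind}_{lineno}"
                feats.append(GenomicFeature(
                    feature_id=fid, kind=kind, chrom=chrom,
                    start=start1 - 1, end=end1,
                    name=attrs.get("Name", fid), attributes=attrs))
    return feats


def write_features_gff3(features: Iterable[GenomicFeature], path) -> None:
    """Write features as GFF3 (1-based inclusive), inverse of read_features."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            attrs.setdefault("ID", f.feature_id)
            attrs.setdefault("Name", f.name or f.feature_id)
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{f.chrom}\t.\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t.\t.\t{attr_str}\n"
            )


def write_cnvr_bed(regions, path) -> None:
    """Write merged regions as BED5: chrom, start, end, svtype, carrier count.

    Expects regions sorted by (chrom, start); unsorted input is sorted with a
    warning.
    """
    regions = list(regions)
    keys = [(chrom_sort_key(r.chrom), r.start) for r in regions]
    if keys != sorted(keys):
        warnings.warn("regions were not sorted by (chrom, start); sorting")
        regions = sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start))
    with _open_text(path, "wt") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.svtype}\t{r.n_carriers}\n")


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a regions x samples matrix as TSV (header = sample ids, first
    column = region ids)."""
    matrix.to_csv(path, sep="\t", index_label="region_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="region_id")
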