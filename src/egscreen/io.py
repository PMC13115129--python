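"""File formats and core containers for low-input genomic screening.

Genotypes live in a :class:`GenotypeMatrix` (samples x loci, alt-allele
dosage codes 0/1/2 with -1 for missing); binned read depth lives in a
validated pandas DataFrame with columns ``chrom, start, end, depth``
(0-based half-open coordinates, per the BED convention). Loci use 1-based
positions, per the VCF convention.

Supported on-disk formats: VCF v4.2 (via pysam), a TSV genotype table
(header row = locus ids, first column = sample id, cells in {0,1,2,NA}),
a 4-column BED-like depth TSV, and TSV/JSON result reports.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

MISSING: int = -1  # internal code for a missing call

#: codes are alt-allele counts: 0 = hom_ref, 1 = het, 2 = hom_alt
HOM_REF, HET, HOM_ALT = 0, 1, 2

DEPTH_COLUMNS = ("chrom", "start", "end", "depth")


class FormatError(ValueError):
    """A file violates its declared format or a container invariant."""


class EmptyInputError(FormatError):
    """An input file contains no usable records."""


@dataclass(frozen=True)
class LocusMeta:
    """Identity of one biallelic locus."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str = "A"
    alt_allele: str = "B"
    id: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise FormatError("locus chrom must be non-empty")
        if self.pos < 1:
            raise FormatError(f"locus position must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """Diploid biallelic calls for a set of samples over a shared locus set.

    ``calls`` is an int8 array of shape (n_samples, n_loci) holding alt-allele
    dosages 0/1/2, or -1 for a missing call.
    """

    samples: list[str]
    loci: list[LocusMeta]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        valid = np.isin(self.calls, (MISSING, HOM_REF, HET, HOM_ALT))
        if not valid.all():
            bad = self.calls[~valid][0]
            raise FormatError(f"invalid genotype code {bad}; expected -1/0/1/2")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample ids")
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate locus ids")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def row(self, sample: str) -> np.ndarray:
        return self.calls[self.samples.index(sample)]

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {l.id: i for i, l in enumerate(self.loci)}
        missing = [i for i in locus_ids if i not in index]
        if missing:
            raise KeyError(f"unknown locus id(s): {missing[:5]}")
        cols = [index[i] for i in locus_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[c] for c in cols],
            calls=self.calls[:, cols].copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            loci=list(self.loci),
            calls=self.calls[rows].copy(),
        )

    def dosages(self) -> np.ndarray:
        """Calls as float dosages with NaN for missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------


def _detect_format(path: Path) -> str:
    return "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "table"


def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or a TSV genotype table.

    VCF genotypes map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing;
    phased separators are accepted and ignored. Multiallelic or non-diploid
    records are rejected with the offending record named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "table":
        return _read_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse as VCF: {exc}") from exc
    samples = list(vf.header.samples)
    loci: list[LocusMeta] = []
    columns: list[np.ndarray] = []
    for n, rec in enumerate(vf, start=1):
        alts = rec.alts or ()
        if len(alts) != 1:
            raise FormatError(
                f"{path}: record {n} ({rec.chrom}:{rec.pos}) is not biallelic"
            )
        loci.append(
            LocusMeta(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=alts[0],
                id=rec.id or f"{rec.chrom}:{rec.pos}",
            )
        )
        col = np.empty(len(samples), dtype=np.int8)
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                col[j] = MISSING
                continue
            if len(gt) != 2 or any(a is None for a in gt):
                raise FormatError(
                    f"{path}: record {n} sample {s}: non-diploid call {gt}"
                )
            if any(a not in (0, 1) for a in gt):
                raise FormatError(
                    f"{path}: record {n} sample {s}: allele index out of range"
                )
            col[j] = gt[0] + gt[1]
        columns.append(col)
    vf.close()
    if not loci:
        raise EmptyInputError(f"{path}: VCF contains no variant records")
    calls = np.stack(columns, axis=1)
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


def _read_table(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty genotype table") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise EmptyInputError(f"{path}: genotype table has no data cells")
    values = df.to_numpy(dtype=object)
    values[pd.isna(values)] = "NA"
    values = values.astype(str)
    legal = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
    bad = ~np.isin(values, list(legal))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"{path}: row {df.index[i]!r}, column {df.columns[j]!r}: "
            f"invalid cell {values[i, j]!r} (expected 0/1/2/NA)"
        )
    calls = np.vectorize(legal.get, otypes=[np.int8])(values)
    loci = [LocusMeta(chrom="1", pos=j + 1, id=str(c)) for j, c in enumerate(df.columns)]
    return GenotypeMatrix(samples=[str(s) for s in df.index], loci=loci, calls=calls)


def write_genotypes(gm: GenotypeMatrix, path: str | Path, format: str = "auto") -> None:
    """Write a genotype matrix as VCF or as the TSV genotype table."""
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "vcf":
        _write_vcf(gm, path)
    elif fmt == "table":
        _write_table(gm, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


_GT_STRINGS = {MISSING: (None, None), HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    chrom_max: dict[str, int] = {}
    for l in gm.loci:
        chrom_max[l.chrom] = max(chrom_max.get(l.chrom, 0), l.pos)
    for chrom, mx in chrom_max.items():
        header.add_line(f"##contig=<ID={chrom},length={mx + 1}>")
    for s in gm.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, locus in enumerate(gm.loci):
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                stop=locus.pos,
                alleles=(locus.ref_allele, locus.alt_allele),
                id=locus.id or None,
            )
            for i, s in enumerate(gm.samples):
                rec.samples[s]["GT"] = _GT_STRINGS[int(gm.calls[i, j])]
            out.write(rec)


def _write_table(gm: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame(
        gm.calls.astype(object), index=gm.samples, columns=gm.locus_ids
    )
    df = df.where(gm.calls != MISSING, "NA")
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------


def validate_depth_track(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a binned depth table.

    Bins are sorted within each chromosome and must be non-overlapping with
    start < end and depth >= 0.
    """
    missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"depth track missing column(s) {missing}")
    df = df.loc[:, list(DEPTH_COLUMNS)].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["depth"] = df["depth"].astype(float)
    if df.empty:
        raise EmptyInputError("depth track has no bins")
    bad = df["start"] >= df["end"]
    if bad.any():
        r = df[bad].iloc[0]
        raise FormatError(f"bin {r.chrom}:{r.start}-{r.end} has start >= end")
    if (df["depth"] < 0).any():
        r = df[df["depth"] < 0].iloc[0]
        raise FormatError(f"bin {r.chrom}:{r.start}-{r.end} has negative depth")
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    overlap = same & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])
    if overlap.any():
        k = int(np.flatnonzero(overlap)[0]) + 1
        r = df.iloc[k]
        raise FormatError(f"overlapping bins on {r.chrom} at {r.start}")
    return df


def read_depth_track(path: str | Path) -> pd.DataFrame:
    """Read a BED-like depth TSV (chrom, start, end, depth)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty depth track") from exc
    if list(df.columns[:4]) != list(DEPTH_COLUMNS):
        # headerless 4-column file is also accepted
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 4:
            raise FormatError(f"{path}: expected 4 columns chrom,start,end,depth")
        df.columns = list(DEPTH_COLUMNS) + [f"extra{i}" for i in range(df.shape[1] - 4)]
    try:
        return validate_depth_track(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_depth_track(df: pd.DataFrame, path: str | Path) -> None:
    validate_depth_track(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _sig6(x):
    """Serialize floats to 6 significant digits, recursively."""
    if isinstance(x, float):
        if math.isnan(x):
            return None
        if x == 0 or not math.isfinite(x):
            return x
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _sig6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_sig6(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return _sig6(float(x))
    return x


def _as_records(summary) -> list[dict]:
    if dataclasses.is_dataclass(summary) and not isinstance(summary, type):
        return [dataclasses.asdict(summary)]
    if isinstance(summary, dict):
        return [summary]
    if isinstance(summary, pd.DataFrame):
        return summary.to_dict(orient="records")
    if isinstance(summary, Iterable):
        out = []
        for item in summary:
            out.extend(_as_records(item))
        return out
    raise TypeError(f"cannot serialize report of type {type(summary).__name__}")


def write_report(summary, path: str | Path, format: str = "auto") -> None:
    """Write a result summary as TSV (one row per record) or JSON.

    Field order is the declaration order of the record type; floats are
    serialized with 6 significant digits.
    """
    path = Path(path)
    fmt = ({"tsv": "tsv", "json": "json"}.get(path.suffix.lstrip("."), "json")
           if format == "auto" else format)
    records = [_sig6(r) for r in _as_records(summary)]
    if fmt == "json":
        payload = records[0] if (
            dataclasses.is_dataclass(summary) and not isinstance(summary, type)
        ) or isinstance(summary, dict) else records
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    elif fmt == "tsv":
        pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: str | Path):
    return json.loads(Path(path).read_text())
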