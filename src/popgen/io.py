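"""Readers and writers for CSV, GenePop and STRUCTURE genotype files.

Conventions
-----------
CSV
    One row per individual, two columns per locus named ``<locus>_1`` /
    ``<locus>_2``; empty cells are missing.  Metadata travels in a sidecar
    ``<stem>.meta.csv`` keyed by ``sample_id``.
GenePop
    Title line, one locus name per line (or comma-separated), ``POP``
    separators; alleles as zero-padded 2- or 3-digit codes, ``00``/``000``
    missing.  Numeric allele labels survive a round trip (codes are
    normalised by stripping leading zeros); non-numeric labels are assigned
    sequential codes on write.
STRUCTURE
    First line lists locus names; two rows per individual (one allele per
    locus per row), ``-9`` missing.
"""

from __future__ import annotations

import csv as _csv
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeError, GenotypeMatrix, SampleMetadata

FORMATS = ("csv", "genepop", "structure")


class ParseError(GenotypeError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# CSV

def _read_csv(path: Path) -> tuple[GenotypeMatrix, SampleMetadata | None]:
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    allele_cols = [c for c in df.columns if c.endswith(("_1", "_2")) and c != "sample_id"]
    loci: list[str] = []
    for c in allele_cols:
        base = c[:-2]
        if base not in loci:
            loci.append(base)
    for base in loci:
        for suf in ("_1", "_2"):
            if base + suf not in df.columns:
                raise ParseError(f"{path}: locus {base!r} lacks column {base + suf!r}")
    sample_ids = df["sample_id"].tolist()
    calls = []
    for _, row in df.iterrows():
        rowcalls = []
        for base in loci:
            a, b = row[base + "_1"], row[base + "_2"]
            a_missing = pd.isna(a) or str(a).strip() == ""
            b_missing = pd.isna(b) or str(b).strip() == ""
            if a_missing != b_missing:
                raise ParseError(f"{path}: half-missing call for {row['sample_id']!r} at {base!r}")
            rowcalls.append(None if a_missing else (str(a).strip(), str(b).strip()))
        calls.append(rowcalls)
    gm = GenotypeMatrix.from_calls(sample_ids, loci, calls)
    meta_path = path.parent / (path.stem + ".meta.csv")
    meta = None
    if meta_path.exists():
        mdf = pd.read_csv(meta_path, dtype={"sample_id": str}).set_index("sample_id")
        meta = SampleMetadata(mdf)
    return gm, meta


def _write_csv(gm: GenotypeMatrix, path: Path, metadata: SampleMetadata | None) -> None:
    cols: dict[str, list[str]] = {"sample_id": list(gm.sample_ids)}
    for l, lid in enumerate(gm.locus_ids):
        a1, a2 = [], []
        for i in range(gm.n_samples):
            c = gm.codes[i, l]
            if c[0] == MISSING:
                a1.append("")
                a2.append("")
            else:
                a1.append(gm.alleles[l][c[0]])
                a2.append(gm.alleles[l][c[1]])
        cols[lid + "_1"] = a1
        cols[lid + "_2"] = a2
    pd.DataFrame(cols).to_csv(path, index=False)
    if metadata is not None:
        metadata.table.to_csv(path.parent / (path.stem + ".meta.csv"), index_label="sample_id")


# ---------------------------------------------------------------------------
# GenePop

def _normalize_code(code: str) -> str | None:
    if int(code) == 0:
        return None
    return str(int(code))


def _read_genepop(path: Path) -> tuple[GenotypeMatrix, None]:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    loci: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().upper() != "POP":
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no POP separator found")
    sample_ids: list[str] = []
    calls: list[list[tuple[str, str] | None]] = []
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            continue
        if "," not in line:
            raise ParseError(f"{path}:{lineno}: expected 'id , genotypes'")
        sid, rest = line.split(",", 1)
        sid = sid.strip()
        if sid in sample_ids:
            raise ParseError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        fields = rest.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"{path}:{lineno}: {len(fields)} genotypes for {len(loci)} loci")
        row: list[tuple[str, str] | None] = []
        for f in fields:
            if len(f) not in (4, 6) or not f.isdigit():
                raise ParseError(f"{path}:{lineno}: bad genotype field {f!r}")
            w = len(f) // 2
            a, b = _normalize_code(f[:w]), _normalize_code(f[w:])
            if (a is None) != (b is None):
                raise ParseError(f"{path}:{lineno}: half-missing genotype {f!r}")
            row.append(None if a is None else (a, b))
        sample_ids.append(sid)
        calls.append(row)
    return GenotypeMatrix.from_calls(sample_ids, loci, calls), None


def _genepop_codes(gm: GenotypeMatrix) -> list[dict[str, str]]:
    """Per-locus label -> 3-digit code mapping (numeric labels kept)."""
    maps = []
    for labels in gm.alleles:
        numeric = all(lab.isdigit() and 0 < int(lab) <= 999 for lab in labels)
        if numeric:
            maps.append({lab: f"{int(lab):03d}" for lab in labels})
        else:
            maps.append({lab: f"{j + 1:03d}" for j, lab in enumerate(labels)})
    return maps


def _write_genepop(gm: GenotypeMatrix, path: Path, metadata=None) -> None:
    maps = _genepop_codes(gm)
    out = ["genotypes exported by popgen"]
    out.extend(gm.locus_ids)
    out.append("POP")
    for i, sid in enumerate(gm.sample_ids):
        fields = []
        for l in range(gm.n_loci):
            c = gm.codes[i, l]
            if c[0] == MISSING:
                fields.append("000000")
            else:
                fields.append(maps[l][gm.alleles[l][c[0]]] + maps[l][gm.alleles[l][c[1]]])
        out.append(f"{sid} , " + " ".join(fields))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE (two rows per individual)

def _read_structure(path: Path) -> tuple[GenotypeMatrix, None]:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    loci = lines[0].split()
    body = lines[1:]
    if len(body) % 2:
        raise ParseError(f"{path}: odd number of genotype rows")
    sample_ids: list[str] = []
    calls: list[list[tuple[str, str] | None]] = []
    for r in range(0, len(body), 2):
        f1, f2 = body[r].split(), body[r + 1].split()
        if len(f1) != len(loci) + 1 or len(f2) != len(loci) + 1:
            raise ParseError(f"{path}: row {r + 2}: expected {len(loci) + 1} fields")
        if f1[0] != f2[0]:
            raise ParseError(f"{path}: row {r + 2}: paired rows disagree on id "
                             f"({f1[0]!r} vs {f2[0]!r})")
        sid = f1[0]
        if sid in sample_ids:
            raise ParseError(f"{path}: duplicate sample id {sid!r}")
        row: list[tuple[str, str] | None] = []
        for a, b in zip(f1[1:], f2[1:]):
            if a == "-9" or b == "-9":
                if a != b:
                    raise ParseError(f"{path}: half-missing call for {sid!r}")
                row.append(None)
            else:
                row.append((a, b))
        sample_ids.append(sid)
        calls.append(row)
    return GenotypeMatrix.from_calls(sample_ids, loci, calls), None


def _write_structure(gm: GenotypeMatrix, path: Path, metadata=None) -> None:
    out = [" ".join(gm.locus_ids)]
    for i, sid in enumerate(gm.sample_ids):
        for copy in range(2):
            fields = [sid]
            for l in range(gm.n_loci):
                c = gm.codes[i, l]
                fields.append("-9" if c[0] == MISSING else gm.alleles[l][c[copy]])
            out.append(" ".join(fields))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------

_READERS = {"csv": _read_csv, "genepop": _read_genepop, "structure": _read_structure}
_WRITERS = {"csv": _write_csv, "genepop": _write_genepop, "structure": _write_structure}


def read_genotypes(path, format: str) -> tuple[GenotypeMatrix, SampleMetadata | None]:
    """Read a genotype file; returns (matrix, metadata-or-None)."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _READERS[format](path)


def write_genotypes(gm: GenotypeMatrix, path, format: str,
                    metadata: SampleMetadata | None = None) -> None:
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    _WRITERS[format](gm, Path(path), metadata)
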