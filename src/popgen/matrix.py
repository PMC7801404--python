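"""Core data model for diploid multilocus codominant genotypes.

A :class:`GenotypeMatrix` stores, for every (individual, locus) pair, an
unordered pair of allele labels or a missing call.  Internally calls are
integer-coded per locus for fast vectorised work; allele labels are opaque
strings (microsatellite fragment lengths carry no ordering information for
any analysis implemented here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel integer for a missing allele call.
MISSING = -1


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype data."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for ``n`` individuals at ``L`` loci.

    Parameters
    ----------
    sample_ids:
        Ordered unique individual identifiers.
    locus_ids:
        Ordered unique locus identifiers.
    codes:
        Integer array of shape ``(n, L, 2)``; ``codes[i, l, :]`` are indices
        into ``alleles[l]`` or :data:`MISSING`.  A call is either fully
        missing or fully observed.
    alleles:
        Per-locus list of allele labels; ``alleles[l][c]`` is the label of
        code ``c`` at locus ``l``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    codes: np.ndarray
    alleles: list[list[str]]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.shape != (len(self.sample_ids), len(self.locus_ids), 2):
            raise GenotypeError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise GenotypeError("duplicate locus ids")
        half_missing = (self.codes == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise GenotypeError("half-missing call: both alleles or neither must be missing")

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        sample_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: Mapping[tuple[str, str], tuple[str, str] | None]
        | Sequence[Sequence[tuple[str, str] | None]],
    ) -> "GenotypeMatrix":
        """Build a matrix from label-pair calls.

        ``calls`` is either a dense nested sequence ``calls[i][l]`` or a
        mapping keyed by ``(sample_id, locus_id)``; values are 2-tuples of
        allele labels or ``None`` for missing.
        """
        n, L = len(sample_ids), len(locus_ids)
        codes = np.full((n, L, 2), MISSING, dtype=np.int32)
        alleles: list[dict[str, int]] = [dict() for _ in range(L)]

        def encode(l: int, label: str) -> int:
            table = alleles[l]
            if label not in table:
                table[label] = len(table)
            return table[label]

        for i, sid in enumerate(sample_ids):
            for l, lid in enumerate(locus_ids):
                if isinstance(calls, Mapping):
                    call = calls.get((sid, lid))
                else:
                    call = calls[i][l]
                if call is None:
                    continue
                a, b = call
                codes[i, l, 0] = encode(l, str(a))
                codes[i, l, 1] = encode(l, str(b))
        allele_lists = [[lab for lab, _ in sorted(t.items(), key=lambda kv: kv[1])] for t in alleles]
        return cls(list(sample_ids), list(locus_ids), codes, allele_lists)

    # -- basic properties ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, ids: Iterable[str] | None = None) -> np.ndarray:
        """Integer row indices for ``ids`` (all samples when ``None``)."""
        if ids is None:
            return np.arange(self.n_samples)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise GenotypeError(f"unknown sample id {e.args[0]!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array, True where the call is missing."""
        return self.codes[:, :, 0] == MISSING

    def call(self, sample_id: str, locus_id: str) -> tuple[str, str] | None:
        i = self.sample_ids.index(sample_id)
        l = self.locus_ids.index(locus_id)
        c = self.codes[i, l]
        if c[0] == MISSING:
            return None
        return (self.alleles[l][c[0]], self.alleles[l][c[1]])

    def n_alleles_per_locus(self, subset: Iterable[str] | None = None) -> np.ndarray:
        """Distinct alleles actually observed per locus in ``subset``."""
        rows = self.sample_index(subset)
        out = np.zeros(self.n_loci, dtype=int)
        for l in range(self.n_loci):
            c = self.codes[rows, l, :].ravel()
            out[l] = len(np.unique(c[c != MISSING]))
        return out

    def het_mask(self) -> np.ndarray:
        """Boolean ``(n, L)``: True where call observed and heterozygous."""
        obs = ~self.missing_mask()
        return obs & (self.codes[:, :, 0] != self.codes[:, :, 1])

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        rows = self.sample_index(ids)
        return GenotypeMatrix(list(ids), list(self.locus_ids), self.codes[rows].copy(),
                              [list(a) for a in self.alleles])

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        cols = [pos[l] for l in locus_ids]
        return GenotypeMatrix(list(self.sample_ids), list(locus_ids),
                              self.codes[:, cols].copy(), [list(self.alleles[j]) for j in cols])

    def dosage_matrix(self, subset: Iterable[str] | None = None) -> tuple[np.ndarray, list[tuple[str, str]]]:
        """Individual allele-frequency matrix ``X`` and its column labels.

        ``X[i, c]`` is the frequency of allele column ``c`` within individual
        ``i``: 0, 0.5 or 1; ``nan`` where the locus call is missing.  Columns
        are labelled ``(locus_id, allele_label)`` in locus order.
        """
        rows = self.sample_index(subset)
        cols: list[tuple[str, str]] = []
        blocks: list[np.ndarray] = []
        for l, lid in enumerate(self.locus_ids):
            k = len(self.alleles[l])
            if k == 0:
                continue
            c = self.codes[rows, l, :]  # (m, 2)
            block = np.zeros((len(rows), k))
            obs = c[:, 0] != MISSING
            for copy in range(2):
                cc = c[obs, copy]
                block[np.nonzero(obs)[0], cc] += 0.5
            block[~obs, :] = np.nan
            blocks.append(block)
            cols.extend((lid, a) for a in self.alleles[l])
        X = np.concatenate(blocks, axis=1) if blocks else np.empty((len(rows), 0))
        return X, cols

    def __eq__(self, other: object) -> bool:  # label-level equality
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.sample_ids != other.sample_ids or self.locus_ids != other.locus_ids:
            return False
        for i, s in enumerate(self.sample_ids):
            for l, loc in enumerate(self.locus_ids):
                a = self.call(s, loc)
                b = other.call(s, loc)
                if a is None or b is None:
                    if a is not b:
                        return False
                elif tuple(sorted(a)) != tuple(sorted(b)):
                    return False
        return True


@dataclass
class SampleMetadata:
    """Per-sample covariates: sex, age class, coordinates, region, year."""

    table: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("sex", "age_class", "latitude", "longitude", "region", "year")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                self.table[col] = np.nan
        lat = pd.to_numeric(self.table["latitude"], errors="coerce")
        lon = pd.to_numeric(self.table["longitude"], errors="coerce")
        if ((lat < -90) | (lat > 90)).any():
            raise GenotypeError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise GenotypeError("longitude outside [-180, 180]")
        self.table["latitude"] = lat
        self.table["longitude"] = lon

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "SampleMetadata":
        df = pd.DataFrame.from_records(list(records)).set_index("sample_id")
        return cls(df)

    def coords(self, ids: Sequence[str] | None = None) -> np.ndarray:
        t = self.table if ids is None else self.table.loc[list(ids)]
        return t[["latitude", "longitude"]].to_numpy(dtype=float)

    def subset(self, ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(ids)].copy())


@dataclass
class AlleleFrequencies:
    """Sample allele frequencies per locus with the number of typed individuals."""

    freqs: dict[str, dict[str, float]]
    n_typed: dict[str, int]
    empty_loci: list[str] = field(default_factory=list)

    def loci(self) -> list[str]:
        return list(self.freqs)

    def as_arrays(self, gm: GenotypeMatrix) -> list[np.ndarray]:
        """Frequency vectors aligned with ``gm``'s per-locus allele coding."""
        out = []
        for l, lid in enumerate(gm.locus_ids):
            f = self.freqs.get(lid, {})
            out.append(np.array([f.get(a, 0.0) for a in gm.alleles[l]]))
        return out


def allele_frequencies(gm: GenotypeMatrix, subset: Iterable[str] | None = None) -> AlleleFrequencies:
    """Observed allele frequencies over non-missing calls, per locus.

    Loci with zero typed individuals in the subset get an empty frequency
    map and are listed in ``empty_loci``.
    """
    rows = gm.sample_index(subset)
    freqs: dict[str, dict[str, float]] = {}
    n_typed: dict[str, int] = {}
    empty: list[str] = []
    for l, lid in enumerate(gm.locus_ids):
        c = gm.codes[rows, l, :]
        obs = c[c != MISSING]
        n_typed[lid] = int((c[:, 0] != MISSING).sum())
        if obs.size == 0:
            freqs[lid] = {}
            empty.append(lid)
            continue
        counts = np.bincount(obs, minlength=len(gm.alleles[l])).astype(float)
        p = counts / counts.sum()
        freqs[lid] = {a: float(p[j]) for j, a in enumerate(gm.alleles[l]) if counts[j] > 0 or True}
    return AlleleFrequencies(freqs, n_typed, empty)


def filter_monomorphic(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Drop loci with at most one observed allele, preserving locus order."""
    keep = [lid for lid, k in zip(gm.locus_ids, gm.n_alleles_per_locus()) if k > 1]
    if not keep:
        raise GenotypeError("no informative loci: all loci monomorphic")
    if len(keep) == gm.n_loci:
        return gm
    return gm.subset_loci(keep)
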