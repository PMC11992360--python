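"""Shared in-memory containers for genotype data.

Genotypes are unordered pairs of allele indices into a per-locus allele
catalog.  The sentinel :data:`MISSING` (-1) marks uncalled cells; depth
arrays are optional and carried alongside when genotypes come from read
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel allele index for a missing genotype.
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x loci unordered-pair genotype matrix.

    Parameters
    ----------
    sample_ids, locus_ids
        Row and column labels.
    a1, a2
        Integer allele-index arrays of shape ``(n_samples, n_loci)``;
        canonical form has ``a1 <= a2`` and both equal to ``MISSING``
        for uncalled cells.
    allele_labels
        Optional per-locus lists of allele names (haplotype strings);
        used for TSV round trips.  When absent, indices are serialized
        as decimal strings.
    groups
        Optional sample -> group (sample collection) labels.
    depth_total, depth_a1, depth_a2
        Optional read-depth arrays with the same shape as ``a1``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    a1: np.ndarray
    a2: np.ndarray
    allele_labels: list[list[str]] | None = None
    groups: dict[str, str] | None = None
    depth_total: np.ndarray | None = None
    depth_a1: np.ndarray | None = None
    depth_a2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a1 = np.asarray(self.a1, dtype=np.int32)
        self.a2 = np.asarray(self.a2, dtype=np.int32)
        shape = (len(self.sample_ids), len(self.locus_ids))
        if self.a1.shape != shape or self.a2.shape != shape:
            raise ValueError(
                f"genotype arrays have shape {self.a1.shape}, expected {shape}"
            )
        # canonicalize: a1 <= a2, missing in both slots
        swap = (self.a1 > self.a2) & (self.a2 != MISSING)
        if swap.any():
            lo = np.where(swap, self.a2, self.a1)
            hi = np.where(swap, self.a1, self.a2)
            self.a1, self.a2 = lo, hi
        miss = (self.a1 == MISSING) | (self.a2 == MISSING)
        self.a1 = np.where(miss, MISSING, self.a1)
        self.a2 = np.where(miss, MISSING, self.a2)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        return self.a1 == MISSING

    def missing_fraction_per_sample(self) -> pd.Series:
        if self.n_loci == 0:
            frac = np.zeros(self.n_samples)
        else:
            frac = self.missing_mask().mean(axis=1)
        return pd.Series(frac, index=self.sample_ids, name="missing_fraction")

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def locus_index(self, locus_id: str) -> int:
        return self.locus_ids.index(locus_id)

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            locus_ids=list(self.locus_ids),
            a1=self.a1.copy(),
            a2=self.a2.copy(),
            allele_labels=(
                [list(x) for x in self.allele_labels]
                if self.allele_labels is not None
                else None
            ),
            groups=dict(self.groups) if self.groups is not None else None,
            depth_total=None if self.depth_total is None else self.depth_total.copy(),
            depth_a1=None if self.depth_a1 is None else self.depth_a1.copy(),
            depth_a2=None if self.depth_a2 is None else self.depth_a2.copy(),
        )

    def subset(
        self,
        samples: list[str] | None = None,
        loci: list[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given samples/loci (order kept)."""
        rows = (
            np.arange(self.n_samples)
            if samples is None
            else np.array([self.sample_index(s) for s in samples], dtype=int)
        )
        cols = (
            np.arange(self.n_loci)
            if loci is None
            else np.array([self.locus_index(l) for l in loci], dtype=int)
        )

        def take(arr: np.ndarray | None) -> np.ndarray | None:
            return None if arr is None else arr[np.ix_(rows, cols)]

        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            locus_ids=[self.locus_ids[j] for j in cols],
            a1=self.a1[np.ix_(rows, cols)],
            a2=self.a2[np.ix_(rows, cols)],
            allele_labels=(
                None
                if self.allele_labels is None
                else [self.allele_labels[j] for j in cols]
            ),
            groups=(
                None
                if self.groups is None
                else {s: self.groups[s] for s in (self.sample_ids[i] for i in rows)}
            ),
            depth_total=take(self.depth_total),
            depth_a1=take(self.depth_a1),
            depth_a2=take(self.depth_a2),
        )

    # -- serialization ---------------------------------------------------
    def _label(self, locus_j: int, allele: int) -> str:
        if allele == MISSING:
            return "."
        if self.allele_labels is not None:
            return self.allele_labels[locus_j][allele]
        return str(allele)

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sample_ids):
            for j, l in enumerate(self.locus_ids):
                def depth(arr):
                    return "." if arr is None else int(arr[i, j])
                rows.append(
                    {
                        "sample_id": s,
                        "locus_id": l,
                        "allele1": self._label(j, self.a1[i, j]),
                        "allele2": self._label(j, self.a2[i, j]),
                        "depth_total": depth(self.depth_total),
                        "depth_allele1": depth(self.depth_a1),
                        "depth_allele2": depth(self.depth_a2),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_long_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path,
        allele_labels: dict[str, list[str]] | None = None,
        groups: dict[str, str] | None = None,
    ) -> "GenotypeMatrix":
        """Read the long genotype TSV written by :meth:`to_tsv`.

        ``allele_labels`` maps locus id -> ordered allele names; when
        omitted, labels are collected from the file in sorted order.
        """
        df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
        sample_ids = list(dict.fromkeys(df["sample_id"]))
        locus_ids = list(dict.fromkeys(df["locus_id"]))
        if allele_labels is None:
            allele_labels = {}
            for l, sub in df.groupby("locus_id", sort=False):
                seen = set(sub["allele1"]) | set(sub["allele2"])
                seen.discard(".")
                allele_labels[l] = sorted(seen)
        labels = [allele_labels[l] for l in locus_ids]
        index = {
            l: {a: k for k, a in enumerate(lab)} for l, lab in zip(locus_ids, labels)
        }
        shape = (len(sample_ids), len(locus_ids))
        a1 = np.full(shape, MISSING, dtype=np.int32)
        a2 = np.full(shape, MISSING, dtype=np.int32)
        dt = np.zeros(shape, dtype=np.int32)
        d1 = np.zeros(shape, dtype=np.int32)
        d2 = np.zeros(shape, dtype=np.int32)
        srow = {s: i for i, s in enumerate(sample_ids)}
        lcol = {l: j for j, l in enumerate(locus_ids)}
        have_depth = False
        for rec in df.itertuples(index=False):
            i, j = srow[rec.sample_id], lcol[rec.locus_id]
            if rec.allele1 != "." and rec.allele2 != ".":
                a1[i, j] = index[rec.locus_id][rec.allele1]
                a2[i, j] = index[rec.locus_id][rec.allele2]
            for arr, val in ((dt, rec.depth_total), (d1, rec.depth_allele1), (d2, rec.depth_allele2)):
                if val != ".":
                    arr[i, j] = int(val)
                    have_depth = True
        return cls(
            sample_ids=sample_ids,
            locus_ids=locus_ids,
            a1=a1,
            a2=a2,
            allele_labels=labels,
            groups=groups,
            depth_total=dt if have_depth else None,
            depth_a1=d1 if have_depth else None,
            depth_a2=d2 if have_depth else None,
        )


def read_group_labels(path) -> dict[str, str]:
    """Read a two-column sample_id/group TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
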