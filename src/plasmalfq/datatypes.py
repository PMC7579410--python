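"""Core in-memory containers for the pipeline.

The central object is :class:`AbundanceTensor`, a protein x sample matrix of
label-free quantification (LFQ) intensities with an explicit observation mask.
Samples are keyed by (individual, day) so the two-factor longitudinal design
(fish x sampling day) is always recoverable from the container itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ProteinRecord", "SampleKey", "AbundanceTensor"]

#: the 20 canonical amino acids plus X for unknown residues
CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_AA = CANONICAL_AA | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its database metadata.

    ``is_contaminant`` / ``is_decoy`` mirror the flags a search engine attaches
    to contaminant and reversed-decoy entries; flagged records are excluded
    from digestion and quantification downstream.
    """

    accession: str
    sequence: str
    gene_id: str | None = None
    chromosome: str | None = None
    is_contaminant: bool = False
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - ALLOWED_AA
        if bad:
            raise ValueError(f"{self.accession}: non-amino-acid letters {sorted(bad)!r}")


@dataclass(frozen=True, order=True)
class SampleKey:
    """One plasma sample: which fish, and how many days post-immunization."""

    individual: str
    day: int

    @property
    def label(self) -> str:
        return f"{self.individual}_d{self.day}"

    @classmethod
    def from_label(cls, label: str) -> "SampleKey":
        ind, sep, day = label.rpartition("_d")
        if not sep or not ind:
            raise ValueError(f"sample label {label!r} is not of the form <individual>_d<day>")
        try:
            day_i = int(day)
        except ValueError as exc:
            raise ValueError(f"sample label {label!r}: day token {day!r} is not an integer") from exc
        return cls(ind, day_i)


@dataclass
class AbundanceTensor:
    """Protein x sample abundance matrix with an explicit missingness mask.

    ``values[i, j]`` is the abundance of ``proteins[i]`` in ``samples[j]``;
    ``mask[i, j]`` is True where the value was observed.  ``scale`` records
    whether values are linear LFQ intensities or log2-transformed.  After
    imputation ``imputed`` flags the entries that were filled in.
    """

    proteins: list[str]
    samples: list[SampleKey]
    values: np.ndarray
    mask: np.ndarray
    scale: str = "linear"
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n_p, n_s = len(self.proteins), len(self.samples)
        if self.values.shape != (n_p, n_s):
            raise ValueError(f"values shape {self.values.shape} != ({n_p}, {n_s})")
        if self.mask.shape != (n_p, n_s):
            raise ValueError(f"mask shape {self.mask.shape} != ({n_p}, {n_s})")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if len(set(self.proteins)) != n_p:
            raise ValueError("duplicate protein accessions")
        if len(set(self.samples)) != n_s:
            raise ValueError("duplicate (individual, day) sample keys")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite value at an observed entry")

    # ---- design helpers -------------------------------------------------
    @property
    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.individual, None)
        return list(seen)

    @property
    def days(self) -> list[int]:
        return sorted({s.day for s in self.samples})

    @property
    def n_missing(self) -> int:
        return int((~self.mask).sum())

    @property
    def missing_fraction(self) -> float:
        return float((~self.mask).mean())

    def sample_index(self, individual: str, day: int) -> int:
        key = SampleKey(individual, day)
        try:
            return self.samples.index(key)
        except ValueError as exc:
            raise KeyError(f"no sample for {key.label}") from exc

    def column_labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def protein_index(self, accession: str) -> int:
        try:
            return self.proteins.index(accession)
        except ValueError as exc:
            raise KeyError(f"unknown protein {accession!r}") from exc

    def is_complete_design(self) -> bool:
        """True when every (individual, day) combination has a sample."""
        have = {(s.individual, s.day) for s in self.samples}
        want = {(f, d) for f in self.individuals for d in self.days}
        return have == want

    def copy(self) -> "AbundanceTensor":
        return AbundanceTensor(
            proteins=list(self.proteins),
            samples=list(self.samples),
            values=self.values.copy(),
            mask=self.mask.copy(),
            scale=self.scale,
            imputed=None if self.imputed is None else self.imputed.copy(),
        )

    def subset(self, proteins: Sequence[str]) -> "AbundanceTensor":
        idx = [self.protein_index(p) for p in proteins]
        return AbundanceTensor(
            proteins=[self.proteins[i] for i in idx],
            samples=list(self.samples),
            values=self.values[idx],
            mask=self.mask[idx],
            scale=self.scale,
            imputed=None if self.imputed is None else self.imputed[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view (proteins x sample labels) with NaN at masked entries."""
        vals = np.where(self.mask, self.values, np.nan)
        return pd.DataFrame(vals, index=self.proteins, columns=self.column_labels())

    def by_day(self, protein: str) -> dict[int, np.ndarray]:
        """Observed values of one protein grouped by sampling day."""
        i = self.protein_index(protein)
        out: dict[int, list[float]] = {d: [] for d in self.days}
        for j, s in enumerate(self.samples):
            if self.mask[i, j]:
                out[s.day].append(self.values[i, j])
        return {d: np.asarray(v) for d, v in out.items()}
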