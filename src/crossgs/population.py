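"""In-memory container for a phased diploid population."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Population"]

MALE, FEMALE = 0, 1


@dataclass
class Population:
    """A cohort of diploid individuals with phased biallelic haplotypes.

    Attributes
    ----------
    haplotypes
        ``uint8`` array of shape ``(n, 2, n_loci)`` with allele codes 0/1.
    sex
        ``0`` = male, ``1`` = female.
    ids, sire, dam
        Integer individual identifiers and parent identifiers (``-1`` for
        founders with unrecorded parents).
    breed, generation
        Cohort labels, e.g. ``breed="A"``, ``generation="EG8"``.
    """

    haplotypes: np.ndarray
    sex: np.ndarray
    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    breed: str = "historical"
    generation: str = ""

    def __post_init__(self) -> None:
        h = self.haplotypes
        if h.ndim != 3 or h.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        n = h.shape[0]
        for name in ("sex", "ids", "sire", "dam"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match haplotypes")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def gametes(self, loci: np.ndarray | None = None) -> np.ndarray:
        """All 2n haplotypes stacked into a ``(2n, n_loci)`` matrix."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.reshape(h.shape[0] * 2, -1)

    def dosage(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Counts of allele 1 per individual and locus, values in {0,1,2}."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.sum(axis=1, dtype=np.int8)

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele 1 per locus."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.mean(axis=(0, 1))

    def subset(self, idx: np.ndarray, generation: str | None = None) -> "Population":
        return Population(
            haplotypes=self.haplotypes[idx],
            sex=self.sex[idx],
            ids=self.ids[idx],
            sire=self.sire[idx],
            dam=self.dam[idx],
            breed=self.breed,
            generation=self.generation if generation is None else generation,
        )
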