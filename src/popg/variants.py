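"""Core genotype containers: the all-sites variant table and the dosage matrix.

Genotype encoding (diploid, bi-allelic):

===== =================
code  meaning
===== =================
0     homozygous ref
1     heterozygous
2     homozygous alt
-1    missing
===== =================

The same code doubles as the alt-allele dosage for non-missing calls, so
``to_genotype_matrix`` is a masked subset of the table's genotype array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

__all__ = ["MISSING", "VariantTable", "GenotypeMatrix", "to_genotype_matrix"]


class ValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


@dataclass
class VariantTable:
    """All-sites table of diploid genotypes with optional depth/quality fields.

    Sites are rows; samples are columns.  Invariant (monomorphic) sites carry
    an empty-string ALT and ``is_variant() == False``.

    Parameters
    ----------
    samples
        Sample identifiers, one per genotype column.
    contigs
        Ordered mapping of contig name to contig length in bp.
    contig_idx
        Per-site index into ``contigs`` (int32).
    pos
        1-based position per site; strictly increasing within a contig.
    ref, alt
        Allele strings; ``alt[i] == ""`` marks an invariant site.
    qual
        Site quality (float; NaN when absent).
    gt
        ``(n_sites, n_samples)`` int8 genotype codes (see module docstring).
    dp, ad_ref, ad_alt
        Optional per-genotype depth fields (``-1`` = absent).
    truth_gt
        Optional clean genotypes retained by the artifact simulator so that
        downstream filters can be scored against the truth.
    """

    samples: list[str]
    contigs: dict[str, int]
    contig_idx: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    gt: np.ndarray
    dp: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    truth_gt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.contig_idx = np.asarray(self.contig_idx, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.qual = np.asarray(self.qual, dtype=np.float64)

    # ------------------------------------------------------------------ basic
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def contig_names(self) -> list[str]:
        return list(self.contigs)

    def is_variant(self) -> np.ndarray:
        """Boolean mask of bi-allelic variant sites (ALT present)."""
        return np.asarray(self.alt) != ""

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError`."""
        n = self.n_sites
        if self.gt.shape != (n, self.n_samples):
            raise ValidationError(
                f"genotype array shape {self.gt.shape} does not match "
                f"{n} sites x {self.n_samples} samples"
            )
        if not np.all((self.gt >= -1) & (self.gt <= 2)):
            raise ValidationError("genotype codes must be in {-1, 0, 1, 2}")
        for ci in np.unique(self.contig_idx):
            p = self.pos[self.contig_idx == ci]
            if np.any(np.diff(p) <= 0):
                name = self.contig_names[ci]
                raise ValidationError(
                    f"positions not strictly increasing on contig {name!r}"
                )
        bad = (self.gt.max(axis=1) > 0) & ~self.is_variant()
        if bad.any():
            i = int(np.argmax(bad))
            raise ValidationError(
                f"invariant site #{i} carries non-reference genotypes"
            )

    # --------------------------------------------------------------- slicing
    def take_sites(self, index: np.ndarray) -> "VariantTable":
        """Return a new table restricted to the given site mask/indices."""
        def _t(a):
            return None if a is None else a[index]

        return VariantTable(
            samples=list(self.samples),
            contigs=dict(self.contigs),
            contig_idx=self.contig_idx[index],
            pos=self.pos[index],
            ref=np.asarray(self.ref)[index],
            alt=np.asarray(self.alt)[index],
            qual=self.qual[index],
            gt=self.gt[index],
            dp=_t(self.dp),
            ad_ref=_t(self.ad_ref),
            ad_alt=_t(self.ad_alt),
            truth_gt=_t(self.truth_gt),
        )

    def copy(self) -> "VariantTable":
        def _c(a):
            return None if a is None else a.copy()

        return VariantTable(
            samples=list(self.samples),
            contigs=dict(self.contigs),
            contig_idx=self.contig_idx.copy(),
            pos=self.pos.copy(),
            ref=np.asarray(self.ref).copy(),
            alt=np.asarray(self.alt).copy(),
            qual=self.qual.copy(),
            gt=self.gt.copy(),
            dp=_c(self.dp),
            ad_ref=_c(self.ad_ref),
            ad_alt=_c(self.ad_alt),
            truth_gt=_c(self.truth_gt),
        )

    # ------------------------------------------------------------ population
    def sample_index(self, names: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in table") from None

    def allele_counts(self, sample_idx: np.ndarray | None = None):
        """Per-site (alt_count, allele_number) over the given samples.

        ``allele_number`` counts non-missing alleles (2 per called genotype).
        """
        g = self.gt if sample_idx is None else self.gt[:, sample_idx]
        called = g >= 0
        an = 2 * called.sum(axis=1)
        ac = np.where(called, g, 0).sum(axis=1)
        return ac.astype(np.int64), an.astype(np.int64)


@dataclass
class GenotypeMatrix:
    """Samples x variant-sites alt-allele dosage matrix.

    ``dosage`` is int8 with ``-1`` for missing; columns correspond to the
    retained variant sites, with their contig names and 1-based positions.
    """

    samples: list[str]
    dosage: np.ndarray
    contig: np.ndarray = field(default=None)
    pos: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def site_ids(self) -> list[str]:
        if self.contig is None or self.pos is None:
            return [f"site_{j}" for j in range(self.n_sites)]
        return [f"{c}:{p}" for c, p in zip(self.contig, self.pos)]


def to_genotype_matrix(table: VariantTable) -> GenotypeMatrix:
    """Extract the dosage matrix over variant sites only.

    Dosage equals the count of alt alleles (0/1/2), missing stays missing.
    An empty matrix is returned when the table has no variant sites.
    """
    keep = table.is_variant()
    contig_names = np.asarray(table.contig_names, dtype=object)
    return GenotypeMatrix(
        samples=list(table.samples),
        dosage=table.gt[keep].T.copy(),
        contig=contig_names[table.contig_idx[keep]],
        pos=table.pos[keep],
    )
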