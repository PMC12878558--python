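"""Runs of homozygosity and the F_ROH inbreeding proxy.

A run is a maximal stretch of consecutive homozygous variant genotypes on
one contig (missing genotypes are skipped; up to ``max_het_in_run``
heterozygotes are tolerated).  A run is reported when it contains at least
``min_snps`` SNPs, spans at least ``min_length_bp`` and has density no
sparser than one SNP per ``max_bp_per_snp``.  Span is last - first + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from popg.variants import GenotypeMatrix, MISSING

__all__ = ["ROHParams", "detect_roh", "froh", "roh_table"]


@dataclass
class ROHParams:
    min_snps: int = 100
    min_length_bp: int = 100_000
    max_bp_per_snp: int = 50_000  # density: at least one SNP per this span
    max_het_in_run: int = 0

    def validate(self) -> None:
        if min(self.min_snps, self.min_length_bp, self.max_bp_per_snp) <= 0:
            raise ValueError("ROH parameters must be positive")
        if self.max_het_in_run < 0:
            raise ValueError("max_het_in_run must be >= 0")


def _qualifies(pos, i, j, n_hom, params: ROHParams) -> bool:
    span = pos[j] - pos[i] + 1
    return (
        n_hom >= params.min_snps
        and span >= params.min_length_bp
        and span / n_hom <= params.max_bp_per_snp
    )


def detect_roh(
    genotypes: np.ndarray, positions: np.ndarray, params: ROHParams | None = None
) -> list[tuple[int, int, int]]:
    """Detect ROH in one sample on one contig.

    ``genotypes`` are dosage codes (0/1/2, -1 missing) at sorted
    ``positions``.  Returns ``(start, end, n_snps)`` tuples (1-based
    inclusive; n_snps counts homozygous genotypes in the run), sorted and
    non-overlapping.
    """
    params = params or ROHParams()
    params.validate()
    positions = np.asarray(positions)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    g = np.asarray(genotypes)
    keep = g != MISSING
    g = g[keep]
    pos = positions[keep]

    out: list[tuple[int, int, int]] = []
    n = len(g)
    i = 0
    while i < n:
        if g[i] == 1:
            i += 1
            continue
        # grow a run starting at hom index i, spending the het budget
        hets = 0
        n_hom = 0
        last_hom = -1
        j = i
        while j < n:
            if g[j] == 1:
                hets += 1
                if hets > params.max_het_in_run:
                    break
            else:
                n_hom += 1
                last_hom = j
            j += 1
        if last_hom >= i and _qualifies(pos, i, last_hom, n_hom, params):
            out.append((int(pos[i]), int(pos[last_hom]), int(n_hom)))
            i = j  # runs cannot overlap: restart past the break point
        else:
            # advance past the first het inside the attempted run, or one hom
            nxt = i + 1
            for k in range(i, min(j + 1, n)):
                if g[k] == 1:
                    nxt = k + 1
                    break
            else:
                nxt = j if j > i else i + 1
            i = max(nxt, i + 1)
    return out


def froh(intervals: list[tuple[int, int, int]], genome_size: int) -> float:
    """Total ROH span divided by genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    total = sum(end - start + 1 for start, end, _ in intervals)
    return total / genome_size


def roh_table(
    matrix: GenotypeMatrix,
    genome_size: int,
    params: ROHParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROH intervals and per-sample F_ROH for every sample in a matrix.

    Returns ``(intervals, summary)``: intervals has columns contig, start,
    end, n_snps, sample; summary has sample, n_roh, total_bp, froh.
    """
    params = params or ROHParams()
    rows = []
    summary = []
    contigs = pd.unique(matrix.contig) if matrix.contig is not None else [None]
    for i, s in enumerate(matrix.samples):
        total = 0
        n_roh = 0
        for c in contigs:
            sel = slice(None) if c is None else (matrix.contig == c)
            pos = matrix.pos[sel]
            order = np.argsort(pos)
            g = matrix.dosage[i, sel][order]
            for start, end, n_snps in detect_roh(g, pos[order], params):
                rows.append(
                    {"contig": c, "start": start, "end": end,
                     "n_snps": n_snps, "sample": s}
                )
                total += end - start + 1
                n_roh += 1
        summary.append(
            {"sample": s, "n_roh": n_roh, "total_bp": total,
             "froh": total / genome_size}
        )
    cols = ["contig", "start", "end", "n_snps", "sample"]
    return (
        pd.DataFrame(rows, columns=cols),
        pd.DataFrame(summary),
    )
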