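"""Reading and writing the pipeline's on-disk formats.

All-sites VCF v4.2 (FORMAT ``GT:DP:AD``, site QUAL), the sample metadata
TSV (sample, population, lat, lon) and per-sample environment TSV.
VCF parsing is delegated to :mod:`cyvcf2` (htslib); writing is plain text
so outputs stay greppable and diff-able.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from popg.variants import MISSING, VariantTable

__all__ = [
    "read_allsites_vcf",
    "write_allsites_vcf",
    "read_popmap",
    "write_popmap",
    "read_env_table",
    "VcfParseError",
    "MultiAllelicError",
]

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _format_field(rec, key):
    """FORMAT field array, or None when absent from record or header."""
    try:
        return rec.format(key)
    except KeyError:
        return None


class VcfParseError(ValueError):
    """Malformed VCF input; message carries the approximate line number."""


class MultiAllelicError(ValueError):
    """A record with more than one ALT allele was encountered."""


def read_allsites_vcf(path: str) -> VariantTable:
    """Load an all-sites VCF into a :class:`VariantTable`.

    Invariant records (ALT ``.``) are retained; multi-allelic records are
    rejected with an error naming the offending site.  GT, and where present
    DP/AD/QUAL, are loaded losslessly.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc

    samples = list(vcf.samples)
    nsamp = len(samples)
    header_lines = str(vcf.raw_header).count("\n")

    contig_idx, pos, ref, alt, qual = [], [], [], [], []
    gt_rows, dp_rows, adr_rows, ada_rows = [], [], [], []
    contigs: dict[str, int] = {}
    contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens or [])) if vcf.seqnames else {}
    any_dp = any_ad = False

    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            alts = [a for a in rec.ALT if a not in (".", "<NON_REF>")]
            if len(alts) > 1:
                raise MultiAllelicError(
                    f"multi-allelic site {rec.CHROM}:{rec.POS} "
                    f"(ALT={','.join(rec.ALT)}) is not supported"
                )
            if rec.CHROM not in contigs:
                contigs[rec.CHROM] = int(contig_lengths.get(rec.CHROM, 0))
            contig_idx.append(list(contigs).index(rec.CHROM))
            pos.append(rec.POS)
            ref.append(rec.REF)
            alt.append(alts[0] if alts else "")
            qual.append(np.nan if rec.QUAL is None else float(rec.QUAL))

            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
            g = rec.gt_types.astype(np.int8)
            g[g == 3] = MISSING
            gt_rows.append(g)

            dp = _format_field(rec, "DP")
            if dp is not None:
                any_dp = True
                d = dp.reshape(nsamp).astype(np.int64)
                d[d < 0] = -1
                dp_rows.append(d.astype(np.int32))
            else:
                dp_rows.append(np.full(nsamp, -1, dtype=np.int32))

            ad = _format_field(rec, "AD")
            if ad is not None and ad.shape[1] >= 1:
                any_ad = True
                a = ad.astype(np.int64)
                a[a < 0] = -1
                adr_rows.append(a[:, 0].astype(np.int32))
                if a.shape[1] >= 2:
                    ada_rows.append(a[:, 1].astype(np.int32))
                else:
                    ada_rows.append(np.zeros(nsamp, dtype=np.int32))
            else:
                adr_rows.append(np.full(nsamp, -1, dtype=np.int32))
                ada_rows.append(np.full(nsamp, -1, dtype=np.int32))
    except MultiAllelicError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"{path}: parse error near line {header_lines + record_no + 1} "
            f"(record {record_no + 1}): {exc}"
        ) from exc

    if record_no == 0:
        raise VcfParseError(f"{path}: VCF contains no records")

    # fall back to max observed position when header lacks contig lengths
    contig_idx = np.asarray(contig_idx, dtype=np.int32)
    pos_arr = np.asarray(pos, dtype=np.int64)
    for i, name in enumerate(contigs):
        if contigs[name] == 0:
            contigs[name] = int(pos_arr[contig_idx == i].max())

    table = VariantTable(
        samples=samples,
        contigs=contigs,
        contig_idx=contig_idx,
        pos=pos_arr,
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        qual=np.asarray(qual, dtype=np.float64),
        gt=np.vstack(gt_rows),
        dp=np.vstack(dp_rows) if any_dp else None,
        ad_ref=np.vstack(adr_rows) if any_ad else None,
        ad_alt=np.vstack(ada_rows) if any_ad else None,
    )
    table.validate()
    return table


def write_allsites_vcf(table: VariantTable, path: str) -> None:
    """Write a :class:`VariantTable` as VCF v4.2 with FORMAT ``GT:DP:AD``."""
    has_dp = table.dp is not None
    has_ad = table.ad_ref is not None
    fmt_keys = ["GT"] + (["DP"] if has_dp else []) + (["AD"] if has_ad else [])
    fmt = ":".join(fmt_keys)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popg\n")
        for name, length in table.contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_ad:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths (ref,alt)">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        names = table.contig_names
        for i in range(table.n_sites):
            q = table.qual[i]
            qs = "." if np.isnan(q) else f"{q:g}"
            alt = table.alt[i] or "."
            cols = [
                names[table.contig_idx[i]],
                str(table.pos[i]),
                ".",
                str(table.ref[i]),
                str(alt),
                qs,
                ".",
                ".",
                fmt,
            ]
            row = []
            for j in range(table.n_samples):
                parts = [_GT_STR[int(table.gt[i, j])]]
                if has_dp:
                    d = int(table.dp[i, j])
                    parts.append("." if d < 0 else str(d))
                if has_ad:
                    ar, aa = int(table.ad_ref[i, j]), int(table.ad_alt[i, j])
                    parts.append("." if ar < 0 else f"{ar},{max(aa, 0)}")
                row.append(":".join(parts))
            fh.write("\t".join(cols) + "\t" + "\t".join(row) + "\n")


def read_popmap(path: str) -> pd.DataFrame:
    """Read the sample metadata TSV (sample, population[, lat, lon])."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: popmap must have columns {sorted(required)}")
    return df


def write_popmap(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_env_table(path: str) -> pd.DataFrame:
    """Read the per-sample environment TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError(f"{path}: environment table must have a 'sample' column")
    return df.set_index("sample")
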