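"""Plain-text readers/writers for the toolkit's tabular formats.

SEG-like TSV for copy-number profiles, MAF-like TSV and minimal VCF for
variants, plain TSV for covariates and truth tables. MAF/VCF positions are
1-based; SEG intervals are written 1-based inclusive (converted from the
internal 0-based half-open representation).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import CNProfile, CNSegment, SampleMeta, VariantCall

MAF_COLUMNS = [
    "sample_id", "case_id", "dataset", "chrom", "pos", "ref", "alt",
    "variant_class", "consequence", "gene", "alt_reads", "depth", "vaf",
    "alt_fwd", "alt_rev", "mean_base_quality", "mean_mapq", "callers",
    "oncokb_driver", "cosmic_count", "trinucleotide",
]


def write_maf(variants: list[VariantCall], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                **{c: getattr(v, c) for c in MAF_COLUMNS if c not in ("callers",)},
                "callers": ",".join(sorted(v.callers)),
            }
        )
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_maf(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False,
                     na_values=[""], float_precision="round_trip")
    calls = []
    for r in df.itertuples(index=False):
        calls.append(
            VariantCall(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=r.ref,
                alt=r.alt,
                variant_class=r.variant_class,
                consequence=r.consequence,
                gene=r.gene,
                alt_reads=int(r.alt_reads),
                depth=int(r.depth),
                vaf=float(r.vaf),
                alt_fwd=int(r.alt_fwd),
                alt_rev=int(r.alt_rev),
                mean_base_quality=float(r.mean_base_quality),
                mean_mapq=float(r.mean_mapq),
                callers=(
                    frozenset(str(r.callers).split(","))
                    if not pd.isna(r.callers) and str(r.callers)
                    else frozenset()
                ),
                oncokb_driver=bool(r.oncokb_driver),
                cosmic_count=int(r.cosmic_count),
                trinucleotide=None if pd.isna(r.trinucleotide) else r.trinucleotide,
                sample_id=r.sample_id,
                case_id=r.case_id,
                dataset=r.dataset,
            )
        )
    return calls


def write_vcf(variants: list[VariantCall], path: str | Path) -> None:
    """Minimal single-column VCF 4.2 with read evidence in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt depth">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.sample_id)):
        info = f"DP={v.depth};AD={v.alt_reads};VAF={v.vaf:.4f};SAMPLE={v.sample_id}"
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "major", "minor", "total",
               "purity", "ploidy"]


def write_seg(profiles: list[CNProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for s in p.segments:
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "chrom": s.chrom,
                    "start": s.start + 1,  # 1-based inclusive on disk
                    "end": s.end,
                    "major": s.major,
                    "minor": s.minor,
                    "total": s.total,
                    "purity": p.purity,
                    "ploidy": p.ploidy,
                }
            )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_seg(path: str | Path) -> list[CNProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    profiles = []
    for sid, g in df.groupby("sample_id", sort=True):
        segs = [
            CNSegment(str(r.chrom), int(r.start) - 1, int(r.end), float(r.major),
                      float(r.minor))
            for r in g.itertuples(index=False)
        ]
        profiles.append(
            CNProfile(str(sid), segs, float(g["purity"].iloc[0]), float(g["ploidy"].iloc[0]))
        )
    return profiles


def write_covariates(samples: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in samples]).to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
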