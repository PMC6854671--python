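"""Readers/writers for the formats the pipeline exchanges.

FASTA is read through pyfaidx (indexed access); VCF through pysam.  InDel
records travel as VCF 4.2 with symbolic ``<DEL>`` ALTs and INFO keys END,
SVLEN, MHLEN, INSLEN, BPTYPE, and INSSEQ for the non-homologous inserted
fragment; the deleted sequence and flanks are recovered from the reference
FASTA.  Coordinates are 0-based half-open internally and 1-based only in
VCF.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import pyfaidx
import pysam

from .breakpoints import BreakpointClass, InDelVariant, ProbeCandidate
from .calling import SignalMatrix
from .kmers import PARInterval


# --- FASTA -----------------------------------------------------------------

def write_fasta(path: str, sequences: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    fa = pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# --- VCF -------------------------------------------------------------------

_VCF_INFO_LINES = [
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the deleted interval (1-based inclusive)">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Deleted length">',
    '##INFO=<ID=MHLEN,Number=1,Type=Integer,Description="Microhomology length">',
    '##INFO=<ID=INSLEN,Number=1,Type=Integer,Description="Inserted fragment length">',
    '##INFO=<ID=BPTYPE,Number=1,Type=String,Description="Breakpoint type I-IV">',
    '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Non-homologous inserted fragment">',
    '##INFO=<ID=KIND,Number=1,Type=String,Description="deletion_vs_ref or insertion_vs_ref">',
    '##INFO=<ID=LINE,Number=1,Type=String,Description="Source line">',
]


def write_indel_vcf(
    path: str,
    variants: Sequence[InDelVariant],
    classes: Optional[Sequence[BreakpointClass]] = None,
    reference: Optional[Dict[str, str]] = None,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write InDel records as VCF 4.2 with symbolic <DEL> ALT alleles."""
    if classes is None:
        classes = [None] * len(variants)
    contigs = contig_lengths or {}
    if reference:
        contigs = {**{k: len(v) for k, v in reference.items()}, **contigs}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_INFO_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v, bc in zip(variants, classes):
            if v.start < 1:
                raise ValueError(f"{v.id}: symbolic DEL needs an anchor base before start")
            # POS is the 1-based anchor base preceding the deleted interval
            ref_base = reference[v.chrom][v.start - 1] if reference else "N"
            info = [
                f"END={v.end}",
                f"SVLEN={-len(v.deleted_seq)}",
                f"KIND={v.kind}",
            ]
            if v.inserted_fragment:
                info.append(f"INSLEN={len(v.inserted_fragment)}")
                info.append(f"INSSEQ={v.inserted_fragment}")
            if v.source_line:
                info.append(f"LINE={v.source_line}")
            if bc is not None:
                info += [f"MHLEN={bc.microhomology_len}", f"BPTYPE={bc.type_code}"]
            fh.write(
                f"{v.chrom}\t{v.start}\t{v.id}\t{ref_base}\t<DEL>\t.\tPASS\t"
                + ";".join(info)
                + "\n"
            )


def read_indel_vcf(
    path: str, reference: Dict[str, str], flank: int = 50
) -> List[InDelVariant]:
    """Read symbolic-DEL VCF records back into InDelVariant objects.

    Deleted sequence and flanks are sliced out of the reference FASTA
    (the VCF POS is the first deleted base, matching :func:`write_indel_vcf`).
    """
    out: List[InDelVariant] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            start = rec.pos      # POS is the anchor; first deleted base is POS+1 (1-based)
            end = int(rec.stop)  # INFO/END (1-based inclusive == 0-based exclusive)
            chrom_seq = reference[rec.chrom]
            out.append(
                InDelVariant(
                    id=rec.id,
                    kind=str(rec.info.get("KIND", "deletion_vs_ref")),
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    deleted_seq=chrom_seq[start:end],
                    inserted_fragment=str(rec.info.get("INSSEQ", "") or ""),
                    left_flank=chrom_seq[max(0, start - flank) : start],
                    right_flank=chrom_seq[end : end + flank],
                    source_line=str(rec.info.get("LINE", "") or ""),
                )
            )
    return out


# --- BED / GFF3 ------------------------------------------------------------

def write_bed(path: str, intervals: Sequence[Tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv[3] if len(iv) > 3 else "."
            fh.write(f"{iv[0]}\t{iv[1]}\t{iv[2]}\t{name}\n")


def read_bed(path: str) -> List[Tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_pars_gff3(path: str, pars: Sequence[PARInterval], source: str = "indelchip") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in pars:
            fh.write(
                f"{p.seq_id}\t{source}\tregion\t{p.start + 1}\t{p.end}\t.\t.\t.\t"
                f"ID=PAR_{p.seq_id}_{p.start}\n"
            )


def read_gff3_intervals(path: str) -> List[Tuple[str, int, int]]:
    """Minimal GFF3 interval reader: (seqid, 0-based start, end)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[3]) - 1, int(f[4])))
    return out


# --- tables ----------------------------------------------------------------

MANIFEST_COLUMNS = [
    "probe_id", "indel_id", "ptype", "strand", "seq", "position",
    "score", "classification", "genome_hits", "hit16", "par_overlap_frac",
]


def write_manifest(path: str, probes: Sequence[ProbeCandidate]) -> None:
    rows = [{c: getattr(p, c) for c in MANIFEST_COLUMNS} for p in probes]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str) -> List[ProbeCandidate]:
    df = pd.read_csv(path, sep="\t")
    return [
        ProbeCandidate(
            probe_id=r.probe_id, indel_id=r.indel_id, ptype=r.ptype,
            strand=r.strand, seq=r.seq, position=int(r.position),
            par_overlap_frac=float(r.par_overlap_frac),
            genome_hits=int(r.genome_hits), hit16=int(r.hit16),
            score=float(r.score), classification=r.classification,
        )
        for r in df.itertuples()
    ]


def write_signals(path: str, sm: SignalMatrix) -> None:
    """Long-format signal TSV: probe_id, sample_id, contrast, intensity."""
    rows = []
    for i, probe in enumerate(sm.probes):
        for j, sample in enumerate(sm.samples):
            rows.append((probe, sample, sm.contrast[i, j], sm.intensity[i, j]))
    pd.DataFrame(rows, columns=["probe_id", "sample_id", "contrast", "intensity"]).to_csv(
        path, sep="\t", index=False
    )


def read_signals(path: str) -> SignalMatrix:
    df = pd.read_csv(path, sep="\t")
    contrast = df.pivot(index="probe_id", columns="sample_id", values="contrast")
    intensity = df.pivot(index="probe_id", columns="sample_id", values="intensity")
    intensity = intensity.loc[contrast.index, contrast.columns]
    return SignalMatrix(
        probes=list(contrast.index),
        samples=list(contrast.columns),
        contrast=contrast.to_numpy(),
        intensity=intensity.to_numpy(),
    )


def write_calls(path: str, calls: pd.DataFrame) -> None:
    calls.to_csv(path, sep="\t", index_label="probe_id")


def read_calls(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")
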