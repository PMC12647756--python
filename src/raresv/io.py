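"""Format adapters: VCF 4.2 SV callsets, FAI chrom tables, BED/bedGraph.

Internal coordinates are 0-based half-open. VCF records are emitted with POS
at the base before the event per convention (1-based POS = internal start),
symbolic ALT alleles, and INFO keys SVTYPE/SVLEN/END/SUPPORT/RNAMES.
Deletions carry negative SVLEN on output and either sign is accepted on
input (absolute value stored). Externally produced SV VCFs are importable:
common support tags (SUPPORT, RE, DV) are mapped onto ``support``.

Writing is plain text for byte-determinism; reading goes through pysam.
"""

from __future__ import annotations

import pysam

from .caller import SVCall, SVCallSet

__all__ = ["write_vcf", "read_vcf", "read_fai", "write_bed", "write_bedgraph"]

_SUPPORT_TAGS = ("SUPPORT", "RE", "DV")


def write_vcf(cs: SVCallSet, chrom_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=raresv\n")
        for name, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##ALT=<ID=INS,Description="Insertion">\n')
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">\n')
        fh.write('##INFO=<ID=RNAMES,Number=.,Type=String,Description="Supporting read names">\n')
        fh.write('##INFO=<ID=MATECHROM,Number=1,Type=String,Description="BND mate chromosome">\n')
        fh.write('##INFO=<ID=MATEPOS,Number=1,Type=Integer,Description="BND mate position (1-based)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(cs.calls):
            pos = max(c.start, 1)  # POS anchors the base before the event
            rnames = ",".join(sorted(c.supporting_reads))
            if c.sv_type == "BND":
                alt = f"N[{c.mate_chrom}:{c.mate_pos + 1}["
                info = (
                    f"SVTYPE=BND;SUPPORT={c.support}"
                    f";MATECHROM={c.mate_chrom};MATEPOS={c.mate_pos + 1}"
                )
            else:
                alt = f"<{c.sv_type}>"
                svlen = -c.svlen if c.sv_type == "DEL" else c.svlen
                info = (
                    f"SVTYPE={c.sv_type};SVLEN={svlen};END={c.end}"
                    f";SUPPORT={c.support}"
                )
            if rnames:
                info += f";RNAMES={rnames}"
            fh.write(
                f"{c.chrom}\t{pos}\tsv{i:05d}\tN\t{alt}\t.\tPASS\t{info}\n"
            )


def _info_get(rec, key):
    try:  # pysam raises on keys missing from the header
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _info_int(rec, key):
    val = _info_get(rec, key)
    if val is None:
        return None
    if isinstance(val, (tuple, list)):
        val = val[0]
    return int(val)


def read_vcf(path, label: str | None = None) -> tuple[SVCallSet, dict[str, int]]:
    """Read an SV VCF into an SVCallSet plus the contig-length table."""
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        chrom_lengths = {
            name: ctg.length for name, ctg in vf.header.contigs.items()
        }
        for rec in vf:
            svtype = _info_get(rec, "SVTYPE")
            if svtype is None:
                alt = rec.alts[0] if rec.alts else ""
                svtype = alt.strip("<>") if alt.startswith("<") else None
            if svtype is None:
                continue
            support = None
            for tag in _SUPPORT_TAGS:
                v = _info_int(rec, tag)
                if v is not None:
                    support = v
                    break
            if support is None:
                support = 1
            rnames = _info_get(rec, "RNAMES")
            if rnames:
                if isinstance(rnames, str):
                    rnames = rnames.split(",")
                reads = frozenset(rnames)
                if len(reads) != support:  # tag wins; pad synthetic ids
                    reads = frozenset(
                        list(reads)
                        + [f"{rec.id}_r{k}" for k in range(support - len(reads))]
                    ) if len(reads) < support else frozenset(sorted(reads)[:support])
            else:
                reads = frozenset(f"{rec.id or rec.pos}_r{k}" for k in range(support))
            start = rec.pos  # pysam rec.pos is 0-based start; our POS = start
            if svtype == "BND":
                mc = _info_get(rec, "MATECHROM")
                mp = _info_int(rec, "MATEPOS")
                if mc is None and rec.alts:
                    alt = rec.alts[0]
                    core = alt.strip("NACGT[]")
                    if ":" in core:
                        mc, mp_s = core.rsplit(":", 1)
                        mp = int(mp_s)
                if mc is None or mp is None:
                    continue
                calls.append(
                    SVCall("BND", rec.chrom, start, start, 0, support, reads,
                           mate_chrom=mc, mate_pos=mp - 1)
                )
                continue
            svlen = _info_int(rec, "SVLEN")
            # pysam folds INFO/END into rec.stop; detect a genuinely absent
            # END by comparing against the REF-allele default.
            end = rec.stop
            if end == rec.start + len(rec.ref or "N"):
                end = None
            if svlen is None and end is not None:
                svlen = end - start
            if svlen is None:
                continue
            svlen = abs(svlen)
            if svtype == "INS":
                end = start
            elif end is None:
                end = start + svlen
            calls.append(
                SVCall(svtype, rec.chrom, start, end, svlen, support, reads)
            )
    return SVCallSet(calls, {"source": label or str(path)}), chrom_lengths


def read_fai(path) -> dict[str, int]:
    """Chromosome-length table from a samtools .fai (first two columns)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: malformed FAI line")
            out[parts[0]] = int(parts[1])
    return out


def write_bed(df, path, score_col: str | None = None) -> None:
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fields = [str(r["chrom"]), str(int(r["start"])), str(int(r["end"]))]
            if score_col is not None:
                fields += [str(r.get("sv_type", ".")), str(r[score_col])]
            fh.write("\t".join(fields) + "\n")


def write_bedgraph(df, value_col: str, path) -> None:
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{r[value_col]}\n"
            )
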