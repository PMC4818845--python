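"""Readers and writers for the file dialects the pipeline consumes.

Supported dialects
------------------
``bed``          BED3/BED6 -> GenomicInterval
``narrowPeak``   ENCODE 10-column narrowPeak -> Peak
``rmsk_out``     RepeatMasker .out (15 columns, 3 header lines) -> TEAnnotation
``binpair_tsv``  tab-delimited chrom/start_i/start_j/frequency -> BinPair
``domain_bed``   BED3 -> Domain
``cpg_tsv``      tab-delimited chrom/pos/methylated(0|1) -> CpGSite
``genes_tsv``    tab-delimited chrom/start/end/strand/symbol/tss,tss -> GeneLocus

RepeatMasker coordinates (1-based inclusive) are converted to the package's
0-based half-open convention on read; every writer/reader pair round-trips
records field for field.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .types import (
    TE_CLASSES,
    BinPair,
    CpGSite,
    Domain,
    GeneLocus,
    GenomicInterval,
    Peak,
    TEAnnotation,
)

logger = logging.getLogger(__name__)

RMSK_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)     ID\n"
    "\n"
)


def _fail(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# per-dialect parsers (line -> record) and formatters (record -> line)
# ---------------------------------------------------------------------------

def _parse_bed(fields, path, lineno):
    if len(fields) < 3:
        raise _fail(path, lineno, "BED line needs >= 3 columns")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = score = None
    strand = "."
    if len(fields) >= 4 and fields[3] != ".":
        name = fields[3]
    if len(fields) >= 5 and fields[4] != ".":
        score = float(fields[4])
    if len(fields) >= 6:
        strand = fields[5]
    return GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)


def _format_bed(iv: GenomicInterval) -> str:
    name = iv.name if iv.name is not None else "."
    score = repr(iv.score) if iv.score is not None else "."
    return f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}"


def _parse_narrowpeak(fields, path, lineno):
    if len(fields) != 10:
        raise _fail(path, lineno, "narrowPeak needs 10 columns")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = None if fields[3] == "." else fields[3]
    strand = fields[5]
    signal = float(fields[6])
    summit = int(fields[9])
    iv = GenomicInterval(chrom, start, end, strand=strand, name=name)
    return Peak(iv, summit_offset=None if summit == -1 else summit, signal=signal)


def _format_narrowpeak(p: Peak) -> str:
    iv = p.interval
    name = iv.name if iv.name is not None else "."
    summit = -1 if p.summit_offset is None else p.summit_offset
    return (
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
        f"\t{p.signal!r}\t-1\t-1\t{summit}"
    )


def _parse_rmsk(fields, path, lineno):
    if len(fields) < 14:
        raise _fail(path, lineno, "RepeatMasker row needs >= 14 columns")
    divergence = float(fields[1])
    chrom = fields[4]
    begin_1based, end_incl = int(fields[5]), int(fields[6])
    strand = "-" if fields[8] == "C" else fields[8]
    subfamily = fields[9]
    class_family = fields[10]
    parts = class_family.split("/", 1)
    te_class = parts[0]
    if te_class not in TE_CLASSES:
        return None  # caller logs skipped count
    family = parts[1] if len(parts) > 1 else te_class
    iv = GenomicInterval(chrom, begin_1based - 1, end_incl, strand=strand)
    return TEAnnotation(iv, te_class, family, subfamily, divergence=divergence)


def _format_rmsk(te: TEAnnotation, idx: int) -> str:
    iv = te.interval
    strand = "C" if iv.strand == "-" else "+"
    div = 0.0 if te.divergence is None else te.divergence
    cls = te.te_class if te.family == te.te_class else f"{te.te_class}/{te.family}"
    length = len(iv)
    return (
        f"  500 {div:5.1f}  0.0  0.0  {iv.chrom} {iv.start + 1} {iv.end} (0) "
        f"{strand} {te.subfamily} {cls} 1 {length} (0) {idx}"
    )


def _parse_binpair(fields, path, lineno):
    if len(fields) != 4:
        raise _fail(path, lineno, "binpair_tsv needs 4 columns")
    return BinPair(fields[0], int(fields[1]), int(fields[2]), float(fields[3]))


def _format_binpair(p: BinPair) -> str:
    return f"{p.chrom}\t{p.start_i}\t{p.start_j}\t{p.frequency!r}"


def _parse_domain(fields, path, lineno):
    if len(fields) < 3:
        raise _fail(path, lineno, "domain BED line needs >= 3 columns")
    return Domain(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))


def _format_domain(d: Domain) -> str:
    return f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}"


def _parse_cpg(fields, path, lineno):
    if len(fields) != 3:
        raise _fail(path, lineno, "cpg_tsv needs 3 columns")
    meth = fields[2]
    if meth not in {"0", "1"}:
        raise _fail(path, lineno, "methylated flag must be 0 or 1")
    return CpGSite(fields[0], int(fields[1]), meth == "1")


def _format_cpg(s: CpGSite) -> str:
    return f"{s.chrom}\t{s.pos}\t{int(s.methylated)}"


def _parse_gene(fields, path, lineno):
    if len(fields) != 6:
        raise _fail(path, lineno, "genes_tsv needs 6 columns")
    chrom, start, end, strand, symbol = (
        fields[0], int(fields[1]), int(fields[2]), fields[3], fields[4],
    )
    tss = tuple(int(x) for x in fields[5].split(",") if x)
    return GeneLocus(
        GenomicInterval(chrom, start, end, strand=strand),
        symbol=symbol,
        strand=strand,
        tss_positions=tss,
    )


def _format_gene(g: GeneLocus) -> str:
    tss = ",".join(str(t) for t in g.tss_positions)
    iv = g.interval
    return f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.strand}\t{g.symbol}\t{tss}"


_DIALECTS = {
    "bed": (_parse_bed, _format_bed, None),
    "narrowPeak": (_parse_narrowpeak, _format_narrowpeak, None),
    "rmsk_out": (_parse_rmsk, None, RMSK_HEADER),
    "binpair_tsv": (_parse_binpair, _format_binpair, "#chrom\tstart_i\tstart_j\tfrequency\n"),
    "domain_bed": (_parse_domain, _format_domain, None),
    "cpg_tsv": (_parse_cpg, _format_cpg, "#chrom\tpos\tmethylated\n"),
    "genes_tsv": (_parse_gene, _format_gene, "#chrom\tstart\tend\tstrand\tsymbol\ttss_positions\n"),
}


def read_records(path, dialect: str) -> list:
    """Read one file of the given dialect into a list of typed records.

    Malformed lines raise with the offending line number; RepeatMasker rows
    whose class is outside {SINE, LINE, LTR, DNA} are skipped (count logged).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    parse, _, _ = _DIALECTS[dialect]
    records = []
    skipped = 0
    with open(path) as fh:
        lines = fh.readlines()
    start_at = 3 if dialect == "rmsk_out" else 0
    for lineno, line in enumerate(lines, start=1):
        if lineno <= start_at:
            continue
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t") if dialect != "rmsk_out" else stripped.split()
        try:
            rec = parse(fields, path, lineno)
        except Exception as exc:  # conversion/validation errors
            if isinstance(exc, ValueError) and str(exc).startswith(f"{path}:"):
                raise
            raise _fail(path, lineno, str(exc)) from exc
        if rec is None:
            skipped += 1
            continue
        records.append(rec)
    if skipped:
        logger.info("%s: skipped %d records with classes outside %s",
                    path, skipped, sorted(TE_CLASSES))
    return records


def write_records(records, path, dialect: str) -> None:
    """Write records of a single type; round-trips with :func:`read_records`."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    _, fmt, header = _DIALECTS[dialect]
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        if dialect == "rmsk_out":
            for i, rec in enumerate(records, start=1):
                fh.write(_format_rmsk(rec, i) + "\n")
        else:
            for rec in records:
                fh.write(fmt(rec) + "\n")


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    """Write a small genome as uncompressed FASTA (fixed line width)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a small genome into memory as {chrom: sequence}."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
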