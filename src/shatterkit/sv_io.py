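"""Readers/writers for SV junctions and copy-number segments, plus junction
orientation classification.

Coordinate dialects
-------------------
Internally everything is 0-based half-open.  BEDPE input/output is 0-based
(the breakend position is the ``start`` of its 1-bp interval); VCF breakend
records are 1-based and converted on the fly.

BEDPE strand semantics follow the convention used by most SV callers: a
deletion-type junction is ``(+,-)`` with ``pos1 < pos2``, a tandem
duplication is ``(-,+)``, and inverted junctions are ``(+,+)`` (head-to-head)
or ``(-,-)`` (tail-to-tail).  Tools disagree on this; the convention here is
fixed and documented so round trips are unambiguous.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

ORIENTATION_CLASSES = ("D", "TD", "HH", "TT", "TRA")

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class BreakpointJunction:
    """One SV junction: two oriented breakends plus junction insertion length.

    ``pos1``/``pos2`` are 0-based.  A ``+`` strand means the joined segment
    lies to the *left* of the breakend (the breakend is the right end of the
    retained piece); ``-`` means it lies to the right.
    """

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    insertion_len: int = 0
    sample_id: str | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if self.strand1 not in _STRANDS or self.strand2 not in _STRANDS:
            raise ValueError(f"strands must be '+' or '-', got "
                             f"({self.strand1!r}, {self.strand2!r})")
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError("breakend positions must be non-negative")
        if self.insertion_len < 0:
            raise ValueError("insertion_len must be >= 0")

    def normalized(self) -> "BreakpointJunction":
        """Return an equivalent junction with breakends in genome order."""
        if (self.chrom2, self.pos2) < (self.chrom1, self.pos1):
            return replace(
                self,
                chrom1=self.chrom2, pos1=self.pos2, strand1=self.strand2,
                chrom2=self.chrom1, pos2=self.pos1, strand2=self.strand1,
            )
        return self

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def span(self) -> tuple[int, int]:
        """(min, max) breakend positions; only meaningful intrachromosomally."""
        if not self.is_intrachromosomal:
            raise ValueError("span undefined for interchromosomal junction")
        return (min(self.pos1, self.pos2), max(self.pos1, self.pos2))


def classify_orientation(junction: BreakpointJunction) -> str:
    """Classify a junction as D / TD / HH / TT / TRA.

    TRA iff the breakends are on different chromosomes; otherwise, after
    normalization, ``(+,-)`` is a deletion-type join, ``(-,+)`` a tandem
    duplication, ``(+,+)`` head-to-head inverted, ``(-,-)`` tail-to-tail.
    """
    j = junction.normalized()
    if not j.is_intrachromosomal:
        return "TRA"
    return {("+", "-"): "D", ("-", "+"): "TD",
            ("+", "+"): "HH", ("-", "-"): "TT"}[(j.strand1, j.strand2)]


@dataclass(frozen=True)
class CNSegment:
    """Genomic interval with total copy number and an optional LOH flag.

    ``loh`` is ``True``/``False`` when assayed and ``None`` when unknown;
    unknown is deliberately distinct from ``False`` so that CNN-LOH calling
    can tell "no LOH" apart from "not assayed".
    """

    chrom: str
    start: int
    end: int
    total_cn: float
    loh: bool | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.total_cn < 0:
            raise ValueError("total_cn must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# BEDPE

def _parse_bedpe_line(line: str, lineno: int) -> BreakpointJunction:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 10:
        raise ValueError(f"line {lineno}: BEDPE needs >=10 columns, got {len(fields)}")
    try:
        c1, s1, _e1, c2, s2, _e2, name, _score, st1, st2 = fields[:10]
        ins = int(fields[10]) if len(fields) > 10 and fields[10] not in (".", "") else 0
        sample = fields[11] if len(fields) > 11 and fields[11] != "." else None
        return BreakpointJunction(
            chrom1=c1, pos1=int(s1), strand1=st1,
            chrom2=c2, pos2=int(s2), strand2=st2,
            insertion_len=ins, sample_id=sample,
            id=None if name == "." else name,
        ).normalized()
    except (ValueError, KeyError) as exc:
        raise ValueError(f"line {lineno}: malformed BEDPE record: {exc}") from exc


def _read_bedpe(path: Path) -> list[BreakpointJunction]:
    junctions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            junctions.append(_parse_bedpe_line(line, lineno))
    return junctions


def _write_bedpe(path: Path, junctions: Sequence[BreakpointJunction]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\t"
                 "name\tscore\tstrand1\tstrand2\tinsertion_len\tsample\n")
        for i, j in enumerate(_sorted_normalized(junctions)):
            fh.write("\t".join(map(str, [
                j.chrom1, j.pos1, j.pos1 + 1,
                j.chrom2, j.pos2, j.pos2 + 1,
                j.id if j.id is not None else f"J{i}", ".",
                j.strand1, j.strand2,
                j.insertion_len,
                j.sample_id if j.sample_id is not None else ".",
            ])) + "\n")


def _sorted_normalized(junctions: Iterable[BreakpointJunction]
                       ) -> list[BreakpointJunction]:
    norm = [j.normalized() for j in junctions]
    return sorted(norm, key=lambda j: (j.chrom1, j.pos1, j.chrom2, j.pos2,
                                       j.strand1, j.strand2, j.id or ""))


# ---------------------------------------------------------------------------
# VCF 4.2 breakend (BND) subset

# the four bracket forms; `t` may carry inserted sequence after the ref base
_BND_RE = re.compile(
    r"^(?P<t5>[A-Za-z]*)(?P<b1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)"
    r"(?P<b2>[\[\]])(?P<t3>[A-Za-z]*)$")

# (alt-seq-first?, bracket) -> (strand at this record, strand at mate)
_BND_STRANDS = {
    (True, "["): ("+", "-"),   # t[p[
    (True, "]"): ("+", "+"),   # t]p]
    (False, "["): ("-", "-"),  # [p[t
    (False, "]"): ("-", "+"),  # ]p]t
}


def _decode_bnd_alt(alt: str) -> tuple[str, int, str, str, int]:
    """Decode a BND ALT string.

    Returns (mate_chrom, mate_pos0, strand_here, strand_mate, inserted_len).
    """
    m = _BND_RE.match(alt)
    if m is None or m.group("b1") != m.group("b2"):
        raise ValueError(f"unparseable BND ALT {alt!r}")
    t5, t3 = m.group("t5"), m.group("t3")
    seq_first = bool(t5)
    if seq_first == bool(t3):
        raise ValueError(f"BND ALT {alt!r} must carry sequence on exactly one side")
    strand_here, strand_mate = _BND_STRANDS[(seq_first, m.group("b1"))]
    # the ref base is included in the adjacent sequence; anything beyond it
    # is untemplated inserted sequence
    ins = max(len(t5) - 1, 0) if seq_first else max(len(t3) - 1, 0)
    return m.group("chrom"), int(m.group("pos")) - 1, strand_here, strand_mate, ins


def _read_vcf_bnd(path: Path) -> list[BreakpointJunction]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_default = None
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None:
                continue
            if rec.info.get("SVTYPE") not in (None, "BND"):
                continue
            alt = rec.alts[0]
            if "[" not in alt and "]" not in alt:
                continue
            records.append(rec)
        ids = {rec.id for rec in records if rec.id}
        junctions: dict[tuple, BreakpointJunction] = {}
        for rec in records:
            mateid = rec.info.get("MATEID")
            if isinstance(mateid, tuple):
                mateid = mateid[0]
            if mateid is not None and mateid not in ids:
                warnings.warn(f"unmated BND record {rec.id!r} (mate {mateid!r} "
                              f"absent); skipping")
                continue
            chrom2, pos2, s1, s2, alt_ins = _decode_bnd_alt(rec.alts[0])
            ins = rec.info.get("INSLEN", alt_ins)
            base_id = re.sub(r"_[12]$", "", rec.id) if rec.id else None
            j = BreakpointJunction(
                chrom1=rec.chrom, pos1=rec.pos - 1, strand1=s1,
                chrom2=chrom2, pos2=pos2, strand2=s2,
                insertion_len=int(ins), id=base_id,
                sample_id=sample_default,
            ).normalized()
            key = (j.chrom1, j.pos1, j.strand1, j.chrom2, j.pos2, j.strand2, j.id)
            junctions.setdefault(key, j)
    return sorted(junctions.values(),
                  key=lambda j: (j.chrom1, j.pos1, j.chrom2, j.pos2, j.id or ""))


def _bnd_alt(chrom_mate: str, pos_mate0: int, strand_here: str,
             strand_mate: str, insertion_len: int) -> str:
    p = f"{chrom_mate}:{pos_mate0 + 1}"
    t = "N" + "N" * insertion_len
    if strand_here == "+":
        return f"{t}[{p}[" if strand_mate == "-" else f"{t}]{p}]"
    return f"[{p}[{t}" if strand_mate == "-" else f"]{p}]{t}"


def _write_vcf_bnd(path: Path, junctions: Sequence[BreakpointJunction]) -> None:
    norm = _sorted_normalized(junctions)
    chroms = sorted({c for j in norm for c in (j.chrom1, j.chrom2)})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">\n')
        fh.write('##INFO=<ID=INSLEN,Number=1,Type=Integer,'
                 'Description="Junction insertion length">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = []
        for i, j in enumerate(norm):
            base = j.id if j.id is not None else f"J{i}"
            info = f"SVTYPE=BND;INSLEN={j.insertion_len}"
            rows.append((j.chrom1, j.pos1 + 1, f"{base}_1",
                         _bnd_alt(j.chrom2, j.pos2, j.strand1, j.strand2,
                                  j.insertion_len),
                         f"{info};MATEID={base}_2"))
            rows.append((j.chrom2, j.pos2 + 1, f"{base}_2",
                         _bnd_alt(j.chrom1, j.pos1, j.strand2, j.strand1,
                                  j.insertion_len),
                         f"{info};MATEID={base}_1"))
        for chrom, pos, rid, alt, info in sorted(rows, key=lambda r: (r[0], r[1], r[2])):
            fh.write(f"{chrom}\t{pos}\t{rid}\tN\t{alt}\t.\t.\t{info}\n")


# ---------------------------------------------------------------------------
# public junction API

def read_junctions(path: str | Path, format: str = "bedpe"
                   ) -> list[BreakpointJunction]:
    """Read SV junctions from ``bedpe`` or ``vcf_bnd`` files, normalized."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bedpe":
        return _read_bedpe(path)
    if format == "vcf_bnd":
        return _read_vcf_bnd(path)
    raise ValueError(f"unknown junction format {format!r}")


def write_junctions(path: str | Path, junctions: Sequence[BreakpointJunction],
                    format: str = "bedpe") -> None:
    path = Path(path)
    if format == "bedpe":
        _write_bedpe(path, junctions)
    elif format == "vcf_bnd":
        _write_vcf_bnd(path, junctions)
    else:
        raise ValueError(f"unknown junction format {format!r}")


# ---------------------------------------------------------------------------
# CN segment TSV

_LOH_ENC = {True: "1", False: "0", None: "NA"}
_LOH_DEC = {"1": True, "true": True, "0": False, "false": False,
            "na": None, ".": None, "": None}


def read_segments(path: str | Path) -> list[CNSegment]:
    """Read a BED-like segment TSV: chrom, start, end, total_cn, [loh], [sample].

    Output is sorted by (sample, chrom, start); overlapping segments within
    one sample are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: segment rows need >=4 columns")
            try:
                loh = _LOH_DEC[fields[4].lower()] if len(fields) > 4 else None
                sample = (fields[5] if len(fields) > 5 and fields[5] != "."
                          else None)
                segments.append(CNSegment(
                    chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                    total_cn=float(fields[3]), loh=loh, sample_id=sample))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"line {lineno}: malformed segment: {exc}") from exc
    segments.sort(key=lambda s: (s.sample_id or "", s.chrom, s.start, s.end))
    for a, b in zip(segments, segments[1:]):
        if (a.sample_id == b.sample_id and a.chrom == b.chrom
                and b.start < a.end):
            raise ValueError(
                f"overlapping segments for sample {a.sample_id!r}: "
                f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}")
    return segments


def write_segments(path: str | Path, segments: Sequence[CNSegment]) -> None:
    rows = sorted(segments, key=lambda s: (s.sample_id or "", s.chrom,
                                           s.start, s.end))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttotal_cn\tloh\tsample\n")
        for s in rows:
            cn = f"{s.total_cn:g}"
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{cn}\t"
                     f"{_LOH_ENC[s.loh]}\t{s.sample_id or '.'}\n")
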