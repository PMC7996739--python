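"""Readers and writers for every on-disk format the pipeline touches.

Internal coordinates are 0-based half-open throughout; conversion to the
1-based inclusive conventions of GFF3 and the engine reports happens only
here.  Minus-strand engine hits (reported with from > to) are flipped at
parse time, so downstream code never sees reversed coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .homology import HomologyHit
from .intervals import GenomicInterval

DIALECTS = ("blast-tab6", "nhmmer-tblout", "cmsearch-tblout")


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, rna: bool = False) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs.

    Ids are the first whitespace-delimited token of the header.  With
    ``rna=False`` (genomic context) U is normalized to T; with
    ``rna=True`` T is normalized to U.  Sequences are upper-cased.
    """
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        name: str | None = None
        chunks: list[str] = []
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, _normalize_seq("".join(chunks), rna, path)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if name is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
        if name is not None:
            records.append((name, _normalize_seq("".join(chunks), rna, path)))
    return records


def _normalize_seq(seq: str, rna: bool, path) -> str:
    seq = seq.upper()
    allowed = set("ACGTUN-")
    bad = set(seq) - allowed
    if bad:
        raise ParseError(f"{path}: unexpected characters in sequence: {sorted(bad)}")
    return seq.replace("T", "U") if rna else seq.replace("U", "T")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Stockholm alignments

@dataclass
class StockholmAlignment:
    """A family alignment with its consensus structure line (SS_cons).

    All rows and the consensus structure have identical length; the
    consensus structure is balanced dot-bracket (WUSS characters are
    normalized to ``(``, ``)``, ``.``).
    """

    family_id: str
    rows: dict[str, str]
    consensus_structure: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()} | {len(self.consensus_structure)}
        if len(lengths) > 1:
            raise ValueError("alignment rows and SS_cons must have equal length")
        _check_balanced(self.consensus_structure)

    @property
    def length(self) -> int:
        return len(self.consensus_structure)


_WUSS_OPEN = set("(<[{")
_WUSS_CLOSE = set(")>]}")


def normalize_wuss(ss: str) -> str:
    """Map WUSS consensus-structure characters onto plain dot-bracket."""
    out = []
    for c in ss:
        if c in _WUSS_OPEN:
            out.append("(")
        elif c in _WUSS_CLOSE:
            out.append(")")
        else:
            out.append(".")
    return "".join(out)


def _check_balanced(ss: str) -> None:
    depth = 0
    for i, c in enumerate(ss):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced structure string at position {i}")
    if depth != 0:
        raise ValueError("unbalanced structure string: unclosed '('")


def read_stockholm(path: str | Path, family_id: str | None = None) -> StockholmAlignment:
    """Read a Stockholm alignment; requires sequence rows and #=GC SS_cons.

    Both single-block and interleaved files are accepted (delegated to
    Biopython); other annotations are preserved opaquely.
    """
    aln = AlignIO.read(str(path), "stockholm")
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise ParseError(f"{path}: missing #=GC SS_cons line")
    rows = {rec.id: str(rec.seq).upper().replace(".", "-") for rec in aln}
    fam = family_id or _stockholm_gf_id(path) or Path(path).stem
    return StockholmAlignment(
        family_id=fam,
        rows=rows,
        consensus_structure=normalize_wuss(ss),
        annotations=dict(aln.column_annotations),
    )


def _stockholm_gf_id(path: str | Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#=GF ID"):
                return line.split(None, 2)[2].strip()
    return None


def write_stockholm(aln: StockholmAlignment, path: str | Path) -> None:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in aln.rows.items()]
    )
    msa.column_annotations["secondary_structure"] = aln.consensus_structure
    with open(path, "w") as fh:
        fh.write(f"# STOCKHOLM 1.0\n#=GF ID {aln.family_id}\n")
        body = io.StringIO()
        AlignIO.write(msa, body, "stockholm")
        # drop Biopython's own header line, keep rows + GC/GR annotations
        for line in body.getvalue().splitlines()[1:]:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Engine tabular outputs

def read_tabular_hits(
    path: str | Path,
    dialect: str,
    query_lengths: Mapping[str, int] | None = None,
) -> list[HomologyHit]:
    """Parse blast outfmt-6 / nhmmer --tblout / cmsearch --tblout hits.

    All engines report 1-based inclusive coordinates with from > to on
    the minus strand; intervals are flipped and converted to 0-based
    half-open here.  ``query_lengths`` maps query/model ids to their
    lengths for coverage computation; hits of unknown queries get
    ``coverage=None``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "blast-tab6":
                    hits.append(_parse_blast6(fields, query_lengths))
                elif dialect == "nhmmer-tblout":
                    hits.append(_parse_nhmmer(fields, query_lengths))
                else:
                    hits.append(_parse_cmsearch(fields, query_lengths))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def _engine_interval(seq_id: str, start_1: int, end_1: int) -> GenomicInterval:
    """1-based inclusive engine coordinates -> internal; from > to means minus."""
    if start_1 <= end_1:
        return GenomicInterval(seq_id, start_1 - 1, end_1, "+")
    return GenomicInterval(seq_id, end_1 - 1, start_1, "-")


def _parse_blast6(f: list[str], qlens: Mapping[str, int] | None) -> HomologyHit:
    if len(f) < 12:
        raise ValueError(f"expected >= 12 tab fields, got {len(f)}")
    qseqid, sseqid = f[0], f[1]
    length = int(f[3])
    qstart, qend = int(f[6]), int(f[7])
    sstart, send = int(f[8]), int(f[9])
    evalue, bitscore = float(f[10]), float(f[11])
    coverage = None
    if qlens and qseqid in qlens:
        coverage = min(1.0, (abs(qend - qstart) + 1) / qlens[qseqid])
    return HomologyHit(
        interval=_engine_interval(sseqid, sstart, send),
        family_id=qseqid,
        engine="blast",
        evalue=evalue,
        bitscore=bitscore,
        hsp_length=length,
        coverage=coverage,
    )


def _parse_nhmmer(f: list[str], qlens: Mapping[str, int] | None) -> HomologyHit:
    if len(f) < 15:
        raise ValueError(f"expected >= 15 fields, got {len(f)}")
    target, query = f[0], f[2]
    hmmfrom, hmmto = int(f[4]), int(f[5])
    alifrom, alito = int(f[6]), int(f[7])
    evalue, score = float(f[12]), float(f[13])
    span = abs(hmmto - hmmfrom) + 1
    coverage = None
    if qlens and query in qlens:
        coverage = min(1.0, span / qlens[query])
    return HomologyHit(
        interval=_engine_interval(target, alifrom, alito),
        family_id=query,
        engine="hmm",
        evalue=evalue,
        bitscore=score,
        hsp_length=span,
        coverage=coverage,
    )


def _parse_cmsearch(f: list[str], qlens: Mapping[str, int] | None) -> HomologyHit:
    if len(f) < 17:
        raise ValueError(f"expected >= 17 fields, got {len(f)}")
    target, query = f[0], f[2]
    mdlfrom, mdlto = int(f[5]), int(f[6])
    seqfrom, seqto = int(f[7]), int(f[8])
    score, evalue = float(f[14]), float(f[15])
    span = abs(mdlto - mdlfrom) + 1
    coverage = None
    if qlens and query in qlens:
        coverage = min(1.0, span / qlens[query])
    return HomologyHit(
        interval=_engine_interval(target, seqfrom, seqto),
        family_id=query,
        engine="cm",
        evalue=evalue,
        bitscore=score,
        hsp_length=span,
        coverage=coverage,
    )


# ---------------------------------------------------------------------------
# Annotation features (GFF3 / BED)

@dataclass
class Feature:
    """A generic annotation record used for GFF3/BED round-trips."""

    interval: GenomicInterval
    feature_id: str
    feature_type: str = "pre_miRNA"
    family: str | None = None
    confidence: str | None = None
    status: str | None = None
    score: float | None = None
    attributes: dict = field(default_factory=dict)


def write_gff3(
    features: Iterable[Feature],
    path: str | Path,
    sequence_lengths: Mapping[str, int] | None = None,
    source: str = "mirscout",
) -> None:
    """Write GFF3 (1-based inclusive); refuses intervals beyond the target
    sequence length when ``sequence_lengths`` is given."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ft in features:
            iv = ft.interval
            if sequence_lengths is not None:
                limit = sequence_lengths.get(iv.sequence_id)
                if limit is not None and iv.end > limit:
                    raise ValueError(
                        f"feature {ft.feature_id}: interval end {iv.end} exceeds "
                        f"length {limit} of {iv.sequence_id}"
                    )
            attrs = {"ID": ft.feature_id}
            if ft.family:
                attrs["family"] = ft.family
            if ft.confidence:
                attrs["confidence"] = ft.confidence
            if ft.status:
                attrs["status"] = ft.status
            attrs.update(ft.attributes)
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            score = f"{ft.score:g}" if ft.score is not None else "."
            fh.write(
                "\t".join(
                    [
                        iv.sequence_id,
                        source,
                        ft.feature_type,
                        str(iv.start + 1),
                        str(iv.end),
                        score,
                        iv.strand,
                        ".",
                        attr_str,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, source, ftype, start, end, score, strand, _phase, attr_str = cols
            attrs = {}
            for part in attr_str.split(";"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    attrs[k.strip()] = v.strip()
            strand = strand if strand in "+-" else "+"
            features.append(
                Feature(
                    interval=GenomicInterval(seqid, int(start) - 1, int(end), strand),
                    feature_id=attrs.pop("ID", f"{seqid}:{start}-{end}"),
                    feature_type=ftype,
                    family=attrs.pop("family", None),
                    confidence=attrs.pop("confidence", None),
                    status=attrs.pop("status", None),
                    score=None if score == "." else float(score),
                    attributes=attrs,
                )
            )
    return features


def write_bed(features: Iterable[Feature], path: str | Path) -> None:
    """BED6: 0-based half-open, matching the internal convention directly."""
    with open(path, "w") as fh:
        for ft in features:
            iv = ft.interval
            name = ft.feature_id
            score = f"{ft.score:g}" if ft.score is not None else "0"
            fh.write(
                f"{iv.sequence_id}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[Feature]:
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            seqid, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"{seqid}:{start}-{end}"
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else None
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            features.append(
                Feature(
                    interval=GenomicInterval(seqid, start, end, strand),
                    feature_id=name,
                    score=score,
                )
            )
    return features


def extract_sequence(
    genome: Mapping[str, str], interval: GenomicInterval, rna: bool = False
) -> str:
    """Excise an interval from the genome; minus-strand intervals are
    reverse-complemented so the result always reads 5'->3'."""
    seq = genome[interval.sequence_id][interval.start : interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq.replace("T", "U") if rna else seq


_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
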